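"""First-trimester competing-risks screening for small-for-gestational-age
neonates: risk computation, synthetic cohorts, and validation statistics."""

from .charts import WeightChart, default_chart, percentile_to_z
from .params import (
    CompetingRisksParams,
    LikelihoodPlane,
    MaternalProfile,
    MomRegression,
    PriorComponent,
    PriorSpec,
)
from .engine import (
    PosteriorGrid,
    posterior_update,
    prior_density,
    screen_cohort,
    screen_record,
    sga_risk,
)
from .cohort import (
    GeneratorConfig,
    calibrate_generator,
    default_generator_config,
    sample_maternal,
    simulate_cohort,
)

__version__ = "0.1.0"

__all__ = [
    "WeightChart", "default_chart", "percentile_to_z",
    "CompetingRisksParams", "LikelihoodPlane", "MaternalProfile",
    "MomRegression", "PriorComponent", "PriorSpec",
    "PosteriorGrid", "prior_density", "posterior_update", "sga_risk",
    "screen_record", "screen_cohort",
    "GeneratorConfig", "calibrate_generator", "default_generator_config",
    "sample_maternal", "simulate_cohort",
    "CompetingRisksModel", "ScreeningValidation",
    "__version__",
]


def __getattr__(name):
    # model layer imported lazily to keep light imports fast
    if name in ("CompetingRisksModel", "ScreeningValidation"):
        from . import model

        return getattr(model, name)
    raise AttributeError(f"module {__name__!r} has no attribute {name!r}")
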