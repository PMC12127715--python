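import numpy as np
import pytest

from sgascreen.params import (
    DEFAULT_LIKELIHOOD_PLANES,
    DEFAULT_MOM_REGRESSIONS,
    CompetingRisksParams,
    PriorComponent,
    PriorSpec,
)


@pytest.fixture(scope="session")
def default_config():
    from sgascreen.cohort import default_generator_config

    return default_generator_config()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    from sgascreen.cohort import simulate_cohort

    return simulate_cohort(400, 7, default_config)


@pytest.fixture(scope="session")
def toy_params():
    """Single-pathway prior with no maternal effects: analytic test bed."""
    prior = PriorSpec(
        components=[PriorComponent(weight=1.0, mean_g=39.5, mean_z=0.0,
                                   sd_g=2.0, sd_z=1.0, rho=0.4)],
        effects_g={}, effects_z={},
    )
    return CompetingRisksParams(
        prior=prior,
        mom_regressions=DEFAULT_MOM_REGRESSIONS,
        likelihood_planes=DEFAULT_LIKELIHOOD_PLANES,
    )


@pytest.fixture(scope="session")
def reference_profile():
    from sgascreen.params import MaternalProfile

    return MaternalProfile(age=32.7, weight=69.0, height=164.0, ga_at_screen=12.5)


def sample_truncated_mixture(params, shift, n, rng):
    """Rejection sampler from the prior mixture truncated to the box (oracle)."""
    comps = params.prior.components
    weights = np.array([c.weight for c in comps])
    dg, dz = shift
    out_g = np.empty(0)
    out_z = np.empty(0)
    while out_g.size < n:
        k = max(n - out_g.size, 1000)
        ci = rng.choice(len(comps), p=weights, size=k)
        mg = np.array([comps[i].mean_g for i in ci]) + dg
        mz = np.array([comps[i].mean_z for i in ci]) + dz
        sg = np.array([comps[i].sd_g for i in ci])
        sz = np.array([comps[i].sd_z for i in ci])
        rho = np.array([comps[i].rho for i in ci])
        e1 = rng.standard_normal(k)
        e2 = rng.standard_normal(k)
        g = mg + sg * e1
        z = mz + sz * (rho * e1 + np.sqrt(1 - rho ** 2) * e2)
        ok = ((g >= params.box_g[0]) & (g <= params.box_g[1])
              & (z >= params.box_z[0]) & (z <= params.box_z[1]))
        out_g = np.concatenate([out_g, g[ok]])
        out_z = np.concatenate([out_z, z[ok]])
    return out_g[:n], out_z[:n]
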