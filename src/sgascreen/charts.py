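"""Birth-weight charts: Z-scores and percentile cut-offs by gestational age.

Weight is modelled on the natural-log scale: for a delivery at gestational age
``ga`` (decimal weeks), ``log(weight)`` is Gaussian with a GA-dependent median
and SD, so the Z-score of an observed weight is

    Z = (log(w) - mean_log_weight(ga)) / sd_log_weight(ga)

and a birth-weight percentile ``p`` is the constant-Z contour at the standard
normal quantile of ``p``.  The default chart shipped here is a documented
stand-in parameterisation (monotone-cubic interpolation through published-style
median/SD knots); it is a config object, so a site can load its own chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

__all__ = [
    "WeightChart",
    "default_chart",
    "percentile_to_z",
]

GA_SUPPORT = (24.0, 43.0)

# Stand-in chart knots: GA (weeks) -> median birth weight (g) and SD of log weight.
# Shapes follow standard neonatal charts (steep mid-gestation growth flattening at
# term; relative spread narrowing with maturity); synthetic, not transcribed from
# any published chart.
_DEFAULT_GA_KNOTS = (24.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0, 38.0, 40.0, 42.0, 43.0)
_DEFAULT_MEDIAN_WEIGHT = (680.0, 900.0, 1180.0, 1530.0, 1950.0, 2400.0, 2840.0, 3170.0, 3480.0, 3680.0, 3740.0)
_DEFAULT_SD_LOG = (0.20, 0.19, 0.18, 0.17, 0.16, 0.15, 0.14, 0.132, 0.125, 0.121, 0.12)


def percentile_to_z(p: float) -> float:
    """Standard-normal quantile of a birth-weight percentile ``p`` in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"percentile must lie strictly in (0, 1), got {p!r}")
    return float(norm.ppf(p))


@dataclass(frozen=True)
class WeightChart:
    """Log-normal birth-weight chart over a closed GA support.

    Parameters
    ----------
    ga_knots, median_weight_knots, sd_log_knots
        Knot arrays interpolated with a shape-preserving monotone cubic
        (PCHIP), so a strictly increasing median at the knots yields a
        strictly increasing median everywhere.
    scale
        Multiplicative factor applied to the median weights (log-additive);
        used to anchor the chart to a cohort's median birth weight.
    """

    ga_knots: tuple = _DEFAULT_GA_KNOTS
    median_weight_knots: tuple = _DEFAULT_MEDIAN_WEIGHT
    sd_log_knots: tuple = _DEFAULT_SD_LOG
    scale: float = 1.0
    ga_support: tuple = GA_SUPPORT
    _mean_log: PchipInterpolator = field(init=False, repr=False, compare=False)
    _sd_log: PchipInterpolator = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ga = np.asarray(self.ga_knots, dtype=float)
        med = np.asarray(self.median_weight_knots, dtype=float)
        sd = np.asarray(self.sd_log_knots, dtype=float)
        if ga.ndim != 1 or ga.size < 2 or np.any(np.diff(ga) <= 0):
            raise ValueError("ga_knots must be strictly increasing with >= 2 knots")
        if med.shape != ga.shape or sd.shape != ga.shape:
            raise ValueError("knot arrays must share the GA grid")
        if np.any(np.diff(med) <= 0):
            raise ValueError("median weight must be strictly increasing in GA")
        if np.any(med <= 0) or np.any(sd <= 0):
            raise ValueError("median weights and log-SDs must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        lo, hi = self.ga_support
        if not (ga[0] <= lo < hi <= ga[-1]):
            raise ValueError("ga_support must lie within the knot range")
        object.__setattr__(self, "_mean_log", PchipInterpolator(ga, np.log(med) + np.log(self.scale)))
        object.__setattr__(self, "_sd_log", PchipInterpolator(ga, sd))

    # -- chart functions ---------------------------------------------------
    def _check_ga(self, ga):
        ga = np.asarray(ga, dtype=float)
        lo, hi = self.ga_support
        if np.any(ga < lo):
            raise ValueError(f"gestational age below chart support lower bound {lo}")
        if np.any(ga > hi):
            raise ValueError(f"gestational age above chart support upper bound {hi}")
        return ga

    def mean_log_weight(self, ga):
        """Expected log birth weight (natural log of the median) at ``ga`` weeks."""
        return self._mean_log(self._check_ga(ga))

    def sd_log_weight(self, ga):
        """SD of log birth weight at ``ga`` weeks."""
        return self._sd_log(self._check_ga(ga))

    def bw_zscore(self, weight_g, ga):
        """Birth-weight Z-score of ``weight_g`` grams delivered at ``ga`` weeks."""
        weight_g = np.asarray(weight_g, dtype=float)
        if np.any(weight_g <= 0):
            raise ValueError("birth weight must be positive")
        z = (np.log(weight_g) - self.mean_log_weight(ga)) / self.sd_log_weight(ga)
        return float(z) if z.ndim == 0 else z

    def inverse_weight(self, z, ga):
        """Quantile function: the weight (g) at Z-score ``z`` for delivery at ``ga``."""
        w = np.exp(self.mean_log_weight(ga) + np.asarray(z, dtype=float) * self.sd_log_weight(ga))
        return float(w) if w.ndim == 0 else w

    def sga_label(self, weight_g, ga, p: float):
        """True iff the birth weight falls strictly below the ``p``-th percentile."""
        out = self.bw_zscore(weight_g, ga) < percentile_to_z(p)
        return bool(out) if np.ndim(out) == 0 else out

    def rescaled(self, scale: float) -> "WeightChart":
        """A copy of the chart with its medians multiplied by ``scale``."""
        return WeightChart(self.ga_knots, self.median_weight_knots, self.sd_log_knots,
                           scale=self.scale * scale, ga_support=self.ga_support)

    # -- config ------------------------------------------------------------
    def to_config(self) -> dict:
        return {
            "ga_knots": list(self.ga_knots),
            "median_weight_knots": list(self.median_weight_knots),
            "sd_log_knots": list(self.sd_log_knots),
            "scale": self.scale,
            "ga_support": list(self.ga_support),
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "WeightChart":
        known = {"ga_knots", "median_weight_knots", "sd_log_knots", "scale", "ga_support"}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown chart config keys: {sorted(unknown)}")
        return cls(
            ga_knots=tuple(cfg["ga_knots"]),
            median_weight_knots=tuple(cfg["median_weight_knots"]),
            sd_log_knots=tuple(cfg["sd_log_knots"]),
            scale=float(cfg.get("scale", 1.0)),
            ga_support=tuple(cfg.get("ga_support", GA_SUPPORT)),
        )


def default_chart(scale: float = 1.0) -> WeightChart:
    """The package's stand-in neonatal weight chart (optionally rescaled)."""
    return WeightChart(scale=scale)


def bw_zscore(weight_g, ga, chart: WeightChart):
    """Functional alias for :meth:`WeightChart.bw_zscore`."""
    return chart.bw_zscore(weight_g, ga)


def sga_label(weight_g, ga, p, chart: WeightChart):
    """Functional alias for :meth:`WeightChart.sga_label`."""
    return chart.sga_label(weight_g, ga, p)
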