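"""Competing-risks Bayes machinery on a discretised (g, z) grid.

The prior joint density of gestational age at delivery ``g`` and birth-weight
Z-score ``z`` is a mixture of bivariate-Gaussian pathways translated by the
woman's maternal-factor effects, restricted to the delivery box
``[24, 43] x [-5, 5]``.  Biomarker log10 MoM values enter through Gaussian
likelihoods whose means are folded planes over (g, z); the posterior is the
renormalised product, and a risk for any (percentile, GA cut-off) pair is the
trapezoidal integral of the posterior over the corresponding lower-left
rectangle.

Likelihood products are accumulated in log space and normalised by their
maximum before exponentiation, so extreme MoM values cannot underflow the
posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np

from .charts import percentile_to_z
from .params import (
    CompetingRisksParams,
    MaternalProfile,
    profile_features,
)

__all__ = [
    "PosteriorGrid",
    "GridResolutionError",
    "PosteriorUnderflowError",
    "build_axis",
    "grid_axes",
    "prior_density",
    "posterior_update",
    "sga_risk",
    "screen_record",
    "screen_cohort",
]

DEFAULT_G_STEP = 0.05
DEFAULT_Z_STEP = 0.02


class GridResolutionError(RuntimeError):
    """The grid is too coarse (or the density too degenerate) to normalise."""


class PosteriorUnderflowError(RuntimeError):
    """All posterior mass underflowed; accumulate likelihoods in log space."""


# ---------------------------------------------------------------------------
# axes and trapezoid helpers
# ---------------------------------------------------------------------------

def build_axis(lo: float, hi: float, step: float, extra: Iterable[float] = ()) -> np.ndarray:
    """Uniform grid over [lo, hi] with ``extra`` cut points inserted as nodes."""
    n = int(round((hi - lo) / step))
    axis = lo + step * np.arange(n + 1)
    axis[-1] = hi
    pts = [p for p in extra if lo < p < hi]
    if pts:
        axis = np.union1d(axis, np.asarray(pts, dtype=float))
        # merge nodes closer than 1e-9 (an extra point hitting a grid node)
        keep = np.concatenate([[True], np.diff(axis) > 1e-9])
        axis = axis[keep]
    return axis


def grid_axes(params: CompetingRisksParams,
              targets: Sequence[Tuple[float, float]] = (),
              g_step: float = DEFAULT_G_STEP,
              z_step: float = DEFAULT_Z_STEP) -> Tuple[np.ndarray, np.ndarray]:
    """Grid axes with plane knots and target cut-offs inserted as nodes."""
    g_extra = [pl.knot_g for pl in params.likelihood_planes.values()]
    z_extra = [pl.knot_z for pl in params.likelihood_planes.values()]
    for p, gc in targets:
        if np.isfinite(gc):
            g_extra.append(float(gc))
        z_extra.append(percentile_to_z(p))
    g = build_axis(params.box_g[0], params.box_g[1], g_step, g_extra)
    z = build_axis(params.box_z[0], params.box_z[1], z_step, z_extra)
    return g, z


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    w = np.zeros_like(x)
    d = np.diff(x)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def _integrate_upto(x: np.ndarray, y: np.ndarray, hi: float, axis: int) -> np.ndarray:
    """Trapezoidal integral of ``y`` over ``x <= hi`` with a partial last cell."""
    y = np.moveaxis(y, axis, -1)
    if hi <= x[0]:
        return np.zeros(y.shape[:-1])
    if hi >= x[-1]:
        return np.trapezoid(y, x, axis=-1)
    k = int(np.searchsorted(x, hi, side="right") - 1)
    total = np.trapezoid(y[..., :k + 1], x[:k + 1], axis=-1) if k >= 1 else np.zeros(y.shape[:-1])
    if hi > x[k]:
        frac = (hi - x[k]) / (x[k + 1] - x[k])
        y_hi = y[..., k] + frac * (y[..., k + 1] - y[..., k])
        total = total + (hi - x[k]) * (y[..., k] + y_hi) / 2.0
    return total


@dataclass
class PosteriorGrid:
    """Discretised joint density over (GA at delivery, birth-weight Z).

    ``density`` has shape ``(len(z), len(g))`` and integrates to one over the
    grid box by the trapezoid rule.
    """

    g: np.ndarray
    z: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        if self.density.shape != (self.z.size, self.g.size):
            raise ValueError("density shape must be (len(z), len(g))")

    def integral(self) -> float:
        return float(np.trapezoid(np.trapezoid(self.density, self.g, axis=1), self.z))

    def normalized(self) -> "PosteriorGrid":
        total = self.integral()
        if not np.isfinite(total) or total <= 0:
            raise GridResolutionError("cannot normalise density on this grid")
        return PosteriorGrid(self.g, self.z, self.density / total)

    def rect_prob(self, z_hi: float, g_hi: float) -> float:
        """Mass of the region {z < z_hi} x {g < g_hi} (trapezoid rule)."""
        over_g = _integrate_upto(self.g, self.density, g_hi, axis=1)
        return float(_integrate_upto(self.z, over_g, z_hi, axis=0))

    def mode(self) -> Tuple[float, float]:
        iz, ig = np.unravel_index(int(np.argmax(self.density)), self.density.shape)
        return float(self.g[ig]), float(self.z[iz])


# ---------------------------------------------------------------------------
# prior / posterior / risks (reference path)
# ---------------------------------------------------------------------------

ShiftLike = Union[MaternalProfile, Tuple[float, float], None]


def _resolve_shift(profile: ShiftLike, params: CompetingRisksParams) -> Tuple[float, float]:
    if profile is None:
        return 0.0, 0.0
    if isinstance(profile, MaternalProfile):
        return params.prior.shift(profile_features(profile))
    dg, dz = profile
    return float(dg), float(dz)


def _prior_log_density(g: np.ndarray, z: np.ndarray,
                       params: CompetingRisksParams,
                       shift: Tuple[float, float]) -> np.ndarray:
    """Unnormalised log prior density on the grid (nz, ng)."""
    dg, dz = shift
    gg = g[None, :]
    zz = z[:, None]
    parts = []
    for c in params.prior.components:
        one_m_r2 = 1.0 - c.rho ** 2
        xg = (gg - (c.mean_g + dg)) / c.sd_g
        xz = (zz - (c.mean_z + dz)) / c.sd_z
        quad = (xg ** 2 - 2.0 * c.rho * xg * xz + xz ** 2) / one_m_r2
        log_norm = -np.log(2.0 * np.pi * c.sd_g * c.sd_z * np.sqrt(one_m_r2))
        parts.append(np.log(c.weight) + log_norm - 0.5 * quad)
    stacked = np.stack(parts)
    m = stacked.max(axis=0)
    return m + np.log(np.exp(stacked - m).sum(axis=0))


def prior_density(profile: ShiftLike, params: CompetingRisksParams,
                  g_axis: np.ndarray = None, z_axis: np.ndarray = None,
                  targets: Sequence[Tuple[float, float]] = ()) -> PosteriorGrid:
    """Maternal-factors-only joint density of (g, z), normalised on the grid."""
    if g_axis is None or z_axis is None:
        g_axis, z_axis = grid_axes(params, targets)
    shift = _resolve_shift(profile, params)
    log_d = _prior_log_density(g_axis, z_axis, params, shift)
    density = np.exp(log_d - log_d.max())
    return PosteriorGrid(g_axis, z_axis, density).normalized()


def posterior_update(prior: PosteriorGrid,
                     log10_moms: Mapping[str, float],
                     planes: Mapping[str, "LikelihoodPlane"]) -> PosteriorGrid:  # noqa: F821
    """Bayes update of the prior grid with the available biomarker MoMs.

    Biomarkers absent from ``log10_moms`` are simply left out of the product,
    which is how the nested biomarker combinations (maternal factors alone,
    +UtA-PI, +PAPP-A, +PlGF) arise.
    """
    if not log10_moms:
        return PosteriorGrid(prior.g, prior.z, prior.density.copy())
    with np.errstate(divide="ignore"):
        log_post = np.log(prior.density)
    gg = prior.g[None, :]
    zz = prior.z[:, None]
    for name, value in log10_moms.items():
        if name not in planes:
            raise KeyError(f"no likelihood plane configured for biomarker {name!r}")
        pl = planes[name]
        resid = float(value) - pl.mu(gg, zz)
        log_post = log_post - 0.5 * (resid / pl.sigma) ** 2
    m = log_post.max()
    if not np.isfinite(m):
        raise PosteriorUnderflowError(
            "posterior vanished everywhere; accumulate likelihoods in log space")
    density = np.exp(log_post - m)
    total = PosteriorGrid(prior.g, prior.z, density).integral()
    if total <= 0 or not np.isfinite(total):
        raise PosteriorUnderflowError(
            "posterior mass underflowed during normalisation")
    return PosteriorGrid(prior.g, prior.z, density / total)


def sga_risk(post: PosteriorGrid, p: float, ga_cutoff: float) -> float:
    """P(birth weight < p-th percentile and delivery < ga_cutoff)."""
    if not 0.0 < p < 1.0:
        raise ValueError("percentile must lie strictly in (0, 1)")
    gc = post.g[-1] if not np.isfinite(ga_cutoff) else float(ga_cutoff)
    if gc < post.g[0]:
        raise ValueError(f"ga_cutoff {ga_cutoff} below grid support {post.g[0]}")
    return post.rect_prob(percentile_to_z(p), gc)


def screen_record(profile: MaternalProfile,
                  raw_biomarkers: Mapping[str, float],
                  params: CompetingRisksParams,
                  targets: Sequence[Tuple[float, float]],
                  g_step: float = DEFAULT_G_STEP,
                  z_step: float = DEFAULT_Z_STEP) -> Dict[Tuple[float, float], float]:
    """Risks for one pregnancy: MoM conversion, Bayes update, rectangle risks.

    ``raw_biomarkers`` maps biomarker name to the raw measured value; entries
    that are ``None``/NaN are treated as not measured.
    """
    feats = profile_features(profile)
    log10_moms = {}
    for name, raw in raw_biomarkers.items():
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        reg = params.mom_regressions[name]
        log10_moms[name] = float(np.log10(reg.to_mom(float(raw), feats)))
    g_axis, z_axis = grid_axes(params, targets, g_step, z_step)
    prior = prior_density(profile, params, g_axis, z_axis)
    post = posterior_update(prior, log10_moms, params.likelihood_planes)
    return {(p, gc): sga_risk(post, p, gc) for p, gc in targets}


def screen_cohort(cohort, params: CompetingRisksParams,
                  targets: Sequence[Tuple[float, float]],
                  biomarkers: Union[str, Sequence[str]] = "available",
                  g_step: float = DEFAULT_G_STEP,
                  z_step: float = DEFAULT_Z_STEP):
    """Vectorised risks for a cohort table; see :mod:`sgascreen.fastscreen`."""
    from .fastscreen import screen_cohort_fast

    return screen_cohort_fast(cohort, params, targets, biomarkers=biomarkers,
                              g_step=g_step, z_step=z_step)
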