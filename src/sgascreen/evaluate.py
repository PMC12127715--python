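"""Discrimination, calibration and paired-comparison statistics.

Implements the validation toolkit of a screening study: detection rate at a
fixed false-positive rate with Wilson confidence intervals, ROC AUC with a
DeLong interval, the calibration slope/intercept (logistic regression of the
outcome on the logit of predicted risk, so perfect calibration gives slope 1
and intercept 0), and McNemar's paired test for detection rates of two
models thresholded at the same FPR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationError",
    "ScreenEval",
    "CalibrationFit",
    "McNemarResult",
    "detection_rate_at_fpr",
    "fixed_fpr_threshold",
    "roc_auc",
    "calibration_fit",
    "mcnemar_fixed_fpr",
]


class EvaluationError(ValueError):
    pass


def _split(risks, labels):
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if risks.shape != labels.shape or risks.ndim != 1:
        raise EvaluationError("risks and labels must be matching 1-D arrays")
    if not np.all(np.isfinite(risks)):
        raise EvaluationError("risks must be finite")
    cases = risks[labels]
    controls = risks[~labels]
    if cases.size == 0 or controls.size == 0:
        raise EvaluationError("both cases and controls are required")
    return cases, controls


@dataclass
class ScreenEval:
    """Detection-rate-at-fixed-FPR summary for one risk column."""

    dr_at_fpr: float
    dr_ci: Tuple[float, float]
    threshold: float
    fpr_target: float
    fpr_realized: float
    n_cases: int
    n_controls: int
    auc: Optional[float] = None
    auc_ci: Optional[Tuple[float, float]] = None


def fixed_fpr_threshold(controls: np.ndarray, fpr: float,
                        extra_candidates=()) -> float:
    """Smallest observed risk value t with P(control >= t) <= fpr.

    Candidate thresholds are the observed risk values (controls plus any
    ``extra_candidates``, typically the case risks).  Ties are broken toward
    a lower realised FPR (screening flags at most the top ``fpr`` fraction of
    unaffected pregnancies); +inf when no candidate qualifies, so that
    nothing is flagged.
    """
    if not 0.0 < fpr < 1.0:
        raise EvaluationError("fpr must lie strictly in (0, 1)")
    c = np.sort(np.asarray(controls, dtype=float))
    n = c.size
    candidates = np.unique(np.concatenate([c, np.asarray(extra_candidates, dtype=float)]))
    # fraction of controls >= t for each candidate threshold t
    frac = (n - np.searchsorted(c, candidates, side="left")) / n
    ok = frac <= fpr
    if not np.any(ok):
        return np.inf
    return float(candidates[np.argmax(ok)])


def _wilson_ci(count: int, nobs: int, alpha: float = 0.05) -> Tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    # guard float fuzz at the boundaries
    lo = 0.0 if count == 0 else float(lo)
    hi = 1.0 if count == nobs else float(hi)
    return lo, hi


def detection_rate_at_fpr(risks, labels, fpr: float = 0.10) -> ScreenEval:
    """Detection rate (sensitivity) at a fixed false-positive rate.

    The threshold is set on the control (unaffected) risk distribution; cases
    at or above the threshold count as detected.  The DR confidence interval
    is a Wilson score interval.
    """
    cases, controls = _split(risks, labels)
    t = fixed_fpr_threshold(controls, fpr, extra_candidates=cases)
    detected = int(np.sum(cases >= t))
    dr = detected / cases.size
    return ScreenEval(
        dr_at_fpr=dr,
        dr_ci=_wilson_ci(detected, cases.size),
        threshold=t,
        fpr_target=fpr,
        fpr_realized=float(np.mean(controls >= t)),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = (i + j + 1) / 2.0
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def roc_auc(risks, labels, alpha: float = 0.05) -> Tuple[float, Tuple[float, float]]:
    """Mann-Whitney AUC (ties counted 1/2) with a DeLong confidence interval."""
    from scipy.stats import norm

    cases, controls = _split(risks, labels)
    m, n = cases.size, controls.size
    all_r = _midranks(np.concatenate([cases, controls]))
    tx = _midranks(cases)
    ty = _midranks(controls)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components
    v10 = (all_r[:m] - tx) / n
    v01 = 1.0 - (all_r[m:] - ty) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    zq = norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, auc - zq * se)
    hi = min(1.0, auc + zq * se)
    return float(auc), (float(lo), float(hi))


@dataclass
class CalibrationFit:
    """Calibration slope/intercept with decile observed-vs-expected table.

    ``slope`` and ``intercept`` come from the joint logistic recalibration
    model (outcome on logit risk).  ``intercept_in_large`` is the
    calibration-in-the-large intercept: the same regression with the slope
    fixed at 1 (logit risk as an offset), which is the standard summary of
    overall over/under-prediction and the quantity usually reported as "the
    calibration intercept" in validation studies.
    """

    slope: float
    intercept: float
    slope_ci: Tuple[float, float]
    intercept_ci: Tuple[float, float]
    intercept_in_large: float
    intercept_in_large_ci: Tuple[float, float]
    bin_table: pd.DataFrame = field(repr=False)
    degenerate: bool = False


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def calibration_fit(risks, labels, n_bins: int = 10, clip: float = 1e-9) -> CalibrationFit:
    """Logistic regression of observed outcomes on logit predicted risk.

    Perfect calibration (observed incidence equal to predicted risk at every
    risk level) gives slope 1 and intercept 0.  Risks at exactly 0 or 1 are
    clipped into (0, 1) with a logged warning; a constant risk column leaves
    the slope unidentifiable and is flagged as a degenerate fit.
    """
    import statsmodels.api as sm

    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels).astype(float)
    _split(risks, labels)  # validates shapes and both classes present
    if np.any(risks <= 0.0) or np.any(risks >= 1.0):
        logger.warning("clipping %d risks at the [%g, 1-%g] boundary",
                       int(np.sum((risks <= 0) | (risks >= 1))), clip, clip)
    risks = np.clip(risks, clip, 1.0 - clip)
    x = _logit(risks)

    bins = pd.qcut(risks, n_bins, duplicates="drop")
    bin_table = (pd.DataFrame({"risk": risks, "observed": labels, "bin": bins})
                 .groupby("bin", observed=True)
                 .agg(n=("observed", "size"), observed=("observed", "mean"),
                      expected=("risk", "mean"))
                 .reset_index())

    ones = np.ones_like(x)
    large = sm.GLM(labels, ones, family=sm.families.Binomial(), offset=x).fit()
    ci_l = np.asarray(large.conf_int())

    if np.ptp(x) < 1e-12:
        return CalibrationFit(np.nan, np.nan, (np.nan, np.nan), (np.nan, np.nan),
                              float(large.params[0]), (float(ci_l[0, 0]), float(ci_l[0, 1])),
                              bin_table, degenerate=True)

    design = sm.add_constant(x)
    fit = sm.GLM(labels, design, family=sm.families.Binomial()).fit()
    ci = np.asarray(fit.conf_int())
    return CalibrationFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        intercept_in_large=float(large.params[0]),
        intercept_in_large_ci=(float(ci_l[0, 0]), float(ci_l[0, 1])),
        bin_table=bin_table,
    )


def plot_calibration(fit: CalibrationFit, ax=None):
    """Observed-vs-expected decile calibration plot (requires matplotlib).

    The diagonal is perfect calibration; each point is one decile of
    predicted risk with its observed outcome rate.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    tab = fit.bin_table
    lim = max(tab["expected"].max(), tab["observed"].max()) * 1.1
    ax.plot([0, lim], [0, lim], ls="--", c="grey", lw=1)
    ax.plot(tab["expected"], tab["observed"], "o-", c="k", ms=4)
    ax.set_xlabel("predicted risk (decile mean)")
    ax.set_ylabel("observed incidence")
    if not fit.degenerate:
        ax.set_title(f"slope {fit.slope:.2f}, intercept {fit.intercept_in_large:+.2f}")
    return ax


@dataclass
class McNemarResult:
    """Paired comparison of two screens at the same fixed FPR."""

    detected_a: int
    detected_b: int
    discordant_a_only: int
    discordant_b_only: int
    p_value: float
    exact: bool
    n_cases: int


def mcnemar_fixed_fpr(risks_a, risks_b, labels, fpr: float = 0.10,
                      exact_cutoff: int = 25) -> McNemarResult:
    """McNemar's test comparing detection among cases when both models are
    thresholded at their own fixed-FPR cut-off.

    Uses the exact binomial form when the discordant count is below
    ``exact_cutoff`` and the continuity-corrected chi-square otherwise.
    """
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    risks_a = np.asarray(risks_a, dtype=float)
    risks_b = np.asarray(risks_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if risks_a.shape != risks_b.shape or risks_a.shape != labels.shape:
        raise EvaluationError("both models must score the same records")
    if not labels.any():
        raise EvaluationError("no cases present")
    if labels.all():
        raise EvaluationError("no controls present")

    ta = fixed_fpr_threshold(risks_a[~labels], fpr, extra_candidates=risks_a[labels])
    tb = fixed_fpr_threshold(risks_b[~labels], fpr, extra_candidates=risks_b[labels])
    fa = risks_a[labels] >= ta
    fb = risks_b[labels] >= tb
    b = int(np.sum(fa & ~fb))
    c = int(np.sum(~fa & fb))
    table = [[int(np.sum(fa & fb)), b], [c, int(np.sum(~fa & ~fb))]]
    exact = (b + c) < exact_cutoff
    if b + c == 0:
        p = 1.0
    else:
        p = float(sm_mcnemar(table, exact=exact, correction=True).pvalue)
    return McNemarResult(
        detected_a=int(fa.sum()), detected_b=int(fb.sum()),
        discordant_a_only=b, discordant_b_only=c,
        p_value=p, exact=exact, n_cases=int(labels.sum()),
    )
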