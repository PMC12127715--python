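"""Model/Results layer: the competing-risks predictor and the validation fit.

:class:`CompetingRisksModel` wraps a fixed, published-style parameter set and
produces per-pregnancy risks; it has no ``fit`` because applying (not
estimating) the model is the point.  :class:`ScreeningValidation` is the
statsmodels-style model object: built from a cohort with known outcomes, its
``fit()`` evaluates discrimination and calibration for every biomarker
combination and outcome definition and returns a results object with a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .engine import screen_cohort, screen_record
from .evaluate import (
    CalibrationFit,
    calibration_fit,
    detection_rate_at_fpr,
    roc_auc,
)
from .fastscreen import target_column
from .params import BIOMARKERS, CompetingRisksParams, MaternalProfile

__all__ = [
    "CompetingRisksModel",
    "ScreeningValidation",
    "ScreeningValidationResults",
    "DEFAULT_TARGETS",
    "BIOMARKER_COMBOS",
]

#: the four outcome definitions of the validation design
DEFAULT_TARGETS: Tuple[Tuple[float, float], ...] = (
    (0.10, 37.0), (0.10, 32.0), (0.03, 37.0), (0.03, 32.0))

#: screening methods compared in the validation (nested biomarker additions)
BIOMARKER_COMBOS: Dict[str, Tuple[str, ...]] = {
    "MF": (),
    "MF+UtA-PI": ("uta_pi",),
    "MF+UtA-PI+PAPP-A": ("uta_pi", "pappa"),
    "MF+UtA-PI+PlGF": ("uta_pi", "plgf"),
    "MF+PlGF+PAPP-A": ("plgf", "pappa"),
    "MF+UtA-PI+PAPP-A+PlGF": ("uta_pi", "pappa", "plgf"),
}


class CompetingRisksModel:
    """First-trimester competing-risks SGA screen with fixed parameters."""

    def __init__(self, params: CompetingRisksParams):
        self.params = params

    @classmethod
    def default(cls) -> "CompetingRisksModel":
        from .cohort import default_generator_config

        return cls(default_generator_config().params)

    @classmethod
    def from_json(cls, path) -> "CompetingRisksModel":
        return cls(CompetingRisksParams.from_json(path))

    def predict(self, cohort: pd.DataFrame,
                targets: Sequence[Tuple[float, float]] = DEFAULT_TARGETS,
                biomarkers="available") -> pd.DataFrame:
        """Risk table (one column per target) for a cohort DataFrame."""
        return screen_cohort(cohort, self.params, list(targets), biomarkers=biomarkers)

    def predict_record(self, profile: MaternalProfile,
                       raw_biomarkers: Mapping[str, float],
                       targets: Sequence[Tuple[float, float]] = DEFAULT_TARGETS):
        """Risks for a single pregnancy (reference, non-vectorised path)."""
        return screen_record(profile, raw_biomarkers, self.params, list(targets))


def _ordinal(x: float) -> str:
    n = int(round(x))
    if n % 10 == 1 and n % 100 != 11:
        return f"{x:g}st"
    if n % 10 == 2 and n % 100 != 12:
        return f"{x:g}nd"
    if n % 10 == 3 and n % 100 != 13:
        return f"{x:g}rd"
    return f"{x:g}th"


def _outcome_labels(cohort: pd.DataFrame, p: float, ga_cutoff: float) -> np.ndarray:
    col = {0.10: "sga10", 0.03: "sga3"}.get(round(p, 6))
    if col is None or col not in cohort.columns:
        raise ValueError(
            f"cohort lacks an SGA label column for percentile {p}; expected 'sga10'/'sga3'")
    sga = cohort[col].astype(bool).to_numpy()
    return sga & (cohort["ga_delivery"].to_numpy(dtype=float) < ga_cutoff)


@dataclass
class ScreeningValidationResults:
    """Discrimination and calibration of the screen on a validation cohort."""

    discrimination: pd.DataFrame
    calibration: pd.DataFrame
    calibration_fits: Dict[Tuple[str, str, str], CalibrationFit] = field(repr=False)
    fpr: float = 0.10
    n_records: int = 0

    def summary(self) -> str:
        lines = []
        lines.append("Competing-risks SGA screen: validation summary")
        lines.append("=" * 78)
        lines.append(f"records: {self.n_records}    fixed FPR: {self.fpr:.0%}")
        lines.append("")
        lines.append("Discrimination (AUC and DR at fixed FPR)")
        lines.append("-" * 78)
        disc = self.discrimination.copy()
        disc["AUC (95% CI)"] = disc.apply(
            lambda r: f"{r.auc:.3f} ({r.auc_lo:.3f}-{r.auc_hi:.3f})", axis=1)
        disc["DR % (95% CI)"] = disc.apply(
            lambda r: f"{100 * r.dr:.1f} ({100 * r.dr_lo:.1f}-{100 * r.dr_hi:.1f})", axis=1)
        cols = ["method", "outcome", "case_def", "n_cases", "AUC (95% CI)", "DR % (95% CI)"]
        lines.append(disc[cols].to_string(index=False))
        lines.append("")
        lines.append("Calibration (slope; intercept is calibration-in-the-large)")
        lines.append("-" * 78)
        cal = self.calibration.copy()
        cal["slope (95% CI)"] = cal.apply(
            lambda r: f"{r.slope:.3f} ({r.slope_lo:.3f}-{r.slope_hi:.3f})", axis=1)
        cal["intercept (95% CI)"] = cal.apply(
            lambda r: f"{r.intercept:+.3f} ({r.intercept_lo:+.3f}-{r.intercept_hi:+.3f})", axis=1)
        lines.append(cal[["method", "outcome", "slope (95% CI)", "intercept (95% CI)"]]
                     .to_string(index=False))
        return "\n".join(lines)


class ScreeningValidation:
    """Validation study of the competing-risks screen on an outcome-labelled cohort.

    Parameters
    ----------
    cohort
        Table with maternal covariates, raw biomarkers, ``ga_delivery`` and
        SGA label columns (``sga10``/``sga3``), optionally ``pe``.
    model
        The :class:`CompetingRisksModel` to validate.
    targets
        Outcome definitions as (percentile, GA cut-off) pairs.
    combos
        Screening methods: name -> biomarker tuple; records missing a
        required biomarker are excluded from that method's evaluation.
    """

    def __init__(self, cohort: pd.DataFrame, model: CompetingRisksModel,
                 targets: Sequence[Tuple[float, float]] = DEFAULT_TARGETS,
                 combos: Optional[Mapping[str, Sequence[str]]] = None,
                 fpr: float = 0.10,
                 exclude_pe_variant: bool = True):
        self.cohort = cohort.reset_index(drop=True)
        self.model = model
        self.targets = list(targets)
        self.combos = dict(combos) if combos is not None else dict(BIOMARKER_COMBOS)
        self.fpr = fpr
        self.exclude_pe_variant = exclude_pe_variant and "pe" in cohort.columns

    def fit(self) -> ScreeningValidationResults:
        disc_rows = []
        cal_rows = []
        fits: Dict[Tuple[str, str, str], CalibrationFit] = {}
        for method, combo in self.combos.items():
            have = np.ones(len(self.cohort), dtype=bool)
            for b in combo:
                if b not in self.cohort.columns:
                    have &= False
                else:
                    have &= self.cohort[b].notna().to_numpy()
            sub = self.cohort.loc[have]
            if len(sub) == 0:
                continue
            risks = self.model.predict(sub, self.targets, biomarkers=tuple(combo))
            for p, gc in self.targets:
                outcome = f"SGA<{_ordinal(100 * p)} <{gc:g}w"
                r = risks[target_column(p, gc)].to_numpy()
                labels = _outcome_labels(sub, p, gc)
                case_defs = {"SGA": (r, labels)}
                if self.exclude_pe_variant:
                    pe = sub["pe"].astype(bool).to_numpy()
                    keep = ~(labels & pe)  # drop PE+SGA cases entirely
                    case_defs["SGA without PE"] = (r[keep], labels[keep])
                for case_def, (rr, yy) in case_defs.items():
                    if yy.sum() == 0 or yy.all():
                        continue
                    auc, auc_ci = roc_auc(rr, yy)
                    ev = detection_rate_at_fpr(rr, yy, self.fpr)
                    disc_rows.append({
                        "method": method, "outcome": outcome, "case_def": case_def,
                        "n": int(yy.size), "n_cases": int(yy.sum()),
                        "auc": auc, "auc_lo": auc_ci[0], "auc_hi": auc_ci[1],
                        "dr": ev.dr_at_fpr, "dr_lo": ev.dr_ci[0], "dr_hi": ev.dr_ci[1],
                        "threshold": ev.threshold,
                    })
                    if case_def == "SGA":
                        fit = calibration_fit(rr, yy)
                        fits[(method, outcome, case_def)] = fit
                        cal_rows.append({
                            "method": method, "outcome": outcome,
                            "slope": fit.slope, "slope_lo": fit.slope_ci[0],
                            "slope_hi": fit.slope_ci[1],
                            "intercept": fit.intercept_in_large,
                            "intercept_lo": fit.intercept_in_large_ci[0],
                            "intercept_hi": fit.intercept_in_large_ci[1],
                            "intercept_joint": fit.intercept,
                            "degenerate": fit.degenerate,
                        })
        return ScreeningValidationResults(
            discrimination=pd.DataFrame(disc_rows),
            calibration=pd.DataFrame(cal_rows),
            calibration_fits=fits,
            fpr=self.fpr,
            n_records=len(self.cohort),
        )
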