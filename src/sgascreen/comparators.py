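"""Pluggable logistic-regression comparator models.

Published first-trimester SGA prediction equations are plain logistic
regressions on maternal factors and biomarker log10 MoMs.  They are loaded
from an editable JSON file so the exact published coefficients can be
transcribed by the user; the stubs shipped here carry synthetic placeholder
coefficients (sensible signs, arbitrary magnitudes) so the comparison
machinery is fully exercised without asserting anyone's published equation.
"""

from __future__ import annotations

import json
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .params import BIOMARKERS, CompetingRisksParams, cohort_features

__all__ = [
    "LogisticModel",
    "logistic_risk",
    "comparator_features",
    "load_comparators",
    "default_comparators",
]

#: feature names a comparator may reference, beyond the maternal features:
#: log10 MoM of each biomarker and of mean arterial pressure (MAP).
MOM_FEATURES = ("log10_uta_pi_mom", "log10_pappa_mom", "log10_plgf_mom", "log10_map_mom")


def _unit_open(p):
    """Keep probabilities strictly inside (0, 1) despite float saturation."""
    return np.clip(p, 5e-324, np.nextafter(1.0, 0.0))


class LogisticModel(BaseModel):
    """``risk = inv_logit(intercept + sum coef * feature)``."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    name: str
    intercept: float
    terms: Dict[str, float] = Field(default_factory=dict)

    def predict(self, features: Mapping[str, float]) -> float:
        eta = self.intercept
        for term, coef in self.terms.items():
            if term not in features or features[term] is None:
                raise KeyError(f"comparator {self.name!r} requires missing feature {term!r}")
            val = float(features[term])
            if np.isnan(val):
                raise KeyError(f"comparator {self.name!r} requires missing feature {term!r}")
            eta += coef * val
        return float(_unit_open(1.0 / (1.0 + np.exp(-eta))))

    def predict_frame(self, features: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(features), self.intercept)
        for term, coef in self.terms.items():
            if term not in features.columns:
                raise KeyError(f"comparator {self.name!r} requires missing feature {term!r}")
            eta += coef * features[term].to_numpy(dtype=float)
        return _unit_open(1.0 / (1.0 + np.exp(-eta)))


def logistic_risk(features: Mapping[str, float], model: LogisticModel) -> float:
    """Functional alias for :meth:`LogisticModel.predict`."""
    return model.predict(features)


def comparator_features(cohort: pd.DataFrame, params: CompetingRisksParams) -> pd.DataFrame:
    """Maternal features plus biomarker log10 MoMs (NaN where unmeasured)."""
    feats = cohort_features(cohort)
    for b in BIOMARKERS:
        col = f"log10_{b}_mom"
        if b in cohort.columns and b in params.mom_regressions:
            reg = params.mom_regressions[b]
            expected = np.full(len(cohort), reg.reference_log10)
            for term, coef in reg.coefficients.items():
                expected += coef * feats[term].to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                feats[col] = np.log10(cohort[b].to_numpy(dtype=float)) - expected
        else:
            feats[col] = np.nan
    if "map_mom" in cohort.columns:
        with np.errstate(invalid="ignore"):
            feats["log10_map_mom"] = np.log10(cohort["map_mom"].to_numpy(dtype=float))
    else:
        feats["log10_map_mom"] = np.nan
    return feats


def load_comparators(path) -> Dict[str, LogisticModel]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return {name: LogisticModel.model_validate({"name": name, **spec})
            for name, spec in payload.items()}


def save_comparators(models: Mapping[str, LogisticModel], path) -> None:
    payload = {name: {"intercept": m.intercept, "terms": m.terms}
               for name, m in models.items()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_comparators() -> Dict[str, LogisticModel]:
    """Synthetic comparator stubs (placeholders, not published coefficients)."""
    return {
        "synthetic_logistic_a": LogisticModel(
            name="synthetic_logistic_a", intercept=-4.0,
            terms={"log10_uta_pi_mom": 4.0, "log10_pappa_mom": -1.5,
                   "smoker": 0.5, "weight_c": -0.01}),
        "synthetic_logistic_b": LogisticModel(
            name="synthetic_logistic_b", intercept=-4.2,
            terms={"log10_uta_pi_mom": 3.0, "log10_pappa_mom": -1.0,
                   "log10_map_mom": 2.0, "nulliparous": 0.3}),
        "synthetic_logistic_c": LogisticModel(
            name="synthetic_logistic_c", intercept=-3.8,
            terms={"log10_uta_pi_mom": 3.5, "prev_sga": 1.0, "smoker": 0.6}),
    }


def compare_at_fixed_fpr(risks_main: Sequence[float],
                         comparator_risks: Mapping[str, Sequence[float]],
                         labels: Sequence[bool], fpr: float = 0.10) -> pd.DataFrame:
    """Head-to-head detection rates and McNemar p-values vs the main model."""
    from .evaluate import detection_rate_at_fpr, mcnemar_fixed_fpr

    rows = []
    main_eval = detection_rate_at_fpr(risks_main, labels, fpr)
    rows.append({"model": "competing_risks", "dr_at_fpr": main_eval.dr_at_fpr,
                 "dr_lo": main_eval.dr_ci[0], "dr_hi": main_eval.dr_ci[1],
                 "p_vs_main": np.nan, "discordant": ""})
    for name, risks in comparator_risks.items():
        ev = detection_rate_at_fpr(risks, labels, fpr)
        mc = mcnemar_fixed_fpr(risks_main, risks, labels, fpr)
        rows.append({"model": name, "dr_at_fpr": ev.dr_at_fpr,
                     "dr_lo": ev.dr_ci[0], "dr_hi": ev.dr_ci[1],
                     "p_vs_main": mc.p_value,
                     "discordant": f"{mc.discordant_a_only}/{mc.discordant_b_only}"})
    return pd.DataFrame(rows)
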