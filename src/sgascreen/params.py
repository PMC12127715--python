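"""Domain types and parameter containers for the competing-risks screen.

The model parameters (prior joint density of gestational age at delivery and
birth-weight Z, biomarker log10-MoM regression equations, and biomarker
likelihood "folded planes") live in a versioned JSON file.  The default set
shipped with the package is a documented stand-in whose signs and rough
magnitudes follow the screening literature; it is not a transcription of any
published coefficient set.
"""

from __future__ import annotations

import json
import math
from typing import Dict, List, Literal, Mapping, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "MaternalProfile",
    "MomRegression",
    "LikelihoodPlane",
    "PriorComponent",
    "PriorSpec",
    "CompetingRisksParams",
    "MissingCovariateError",
    "profile_features",
    "cohort_features",
    "BIOMARKERS",
    "FEATURE_NAMES",
]

BIOMARKERS = ("uta_pi", "pappa", "plgf")

# Centring constants for continuous covariates entering MoM regressions and
# prior shifts; "reference covariates" means all features exactly zero.
WEIGHT_REFERENCE_KG = 69.0
GA_SCREEN_REFERENCE = 12.5

GA_SCREEN_WINDOW = (11.0, 13.0 + 6.0 / 7.0)

FEATURE_NAMES = (
    "weight_c", "height_c", "age_c", "ga_c", "smoker",
    "race_black", "race_south_asian", "race_east_asian", "race_mixed_other",
    "ivf", "ovulation_induction",
    "chronic_hypertension", "diabetes", "sle_aps",
    "nulliparous", "prev_sga", "prev_pe", "prev_stillbirth",
)


class MissingCovariateError(KeyError):
    """A regression/effect term names a covariate the profile does not provide."""


class MaternalProfile(BaseModel):
    """Maternal characteristics entering the prior shift and MoM regressions."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    age: float = Field(gt=10, lt=65)
    weight: float = Field(gt=30, lt=250)
    height: float = Field(gt=120, lt=220)
    race: Literal["White", "Black", "South Asian", "East Asian", "Mixed/other"] = "White"
    smoker: bool = False
    conception: Literal["natural", "ovulation induction", "IVF"] = "natural"
    chronic_hypertension: bool = False
    diabetes: bool = False
    sle_aps: bool = False
    parity: Literal["nulliparous", "parous"] = "nulliparous"
    prev_sga: bool = False
    prev_pe: bool = False
    prev_stillbirth: bool = False
    interpregnancy_interval: Optional[float] = None
    ga_last_delivery: Optional[float] = None
    ga_at_screen: float = 12.5

    @model_validator(mode="after")
    def _check(self):
        lo, hi = GA_SCREEN_WINDOW
        if not lo <= self.ga_at_screen <= hi:
            raise ValueError(
                f"ga_at_screen={self.ga_at_screen} outside the screening window [{lo}, {hi:.4f}]")
        parous_only = {
            "prev_sga": self.prev_sga, "prev_pe": self.prev_pe,
            "prev_stillbirth": self.prev_stillbirth,
        }
        if self.parity == "nulliparous":
            bad = [k for k, v in parous_only.items() if v]
            if self.interpregnancy_interval is not None or self.ga_last_delivery is not None:
                bad.append("interpregnancy_interval/ga_last_delivery")
            if bad:
                raise ValueError(f"nulliparous profile carries parous-only fields: {bad}")
        return self


def profile_features(profile: MaternalProfile) -> Dict[str, float]:
    """Numeric feature map used by MoM regressions and prior effect maps."""
    return {
        "weight_c": profile.weight - WEIGHT_REFERENCE_KG,
        "height_c": profile.height - 164.0,
        "age_c": profile.age - 32.7,
        "ga_c": profile.ga_at_screen - GA_SCREEN_REFERENCE,
        "smoker": float(profile.smoker),
        "race_black": float(profile.race == "Black"),
        "race_south_asian": float(profile.race == "South Asian"),
        "race_east_asian": float(profile.race == "East Asian"),
        "race_mixed_other": float(profile.race == "Mixed/other"),
        "ivf": float(profile.conception == "IVF"),
        "ovulation_induction": float(profile.conception == "ovulation induction"),
        "chronic_hypertension": float(profile.chronic_hypertension),
        "diabetes": float(profile.diabetes),
        "sle_aps": float(profile.sle_aps),
        "nulliparous": float(profile.parity == "nulliparous"),
        "prev_sga": float(profile.prev_sga),
        "prev_pe": float(profile.prev_pe),
        "prev_stillbirth": float(profile.prev_stillbirth),
    }


def cohort_features(df) -> "pd.DataFrame":  # noqa: F821 - pandas imported lazily
    """Vectorised :func:`profile_features` over a cohort table."""
    import pandas as pd

    out = pd.DataFrame(index=df.index)
    out["weight_c"] = df["weight"].astype(float) - WEIGHT_REFERENCE_KG
    out["height_c"] = df["height"].astype(float) - 164.0
    out["age_c"] = df["age"].astype(float) - 32.7
    out["ga_c"] = df["ga_at_screen"].astype(float) - GA_SCREEN_REFERENCE
    out["smoker"] = df["smoker"].astype(float)
    race = df["race"].astype(str)
    out["race_black"] = (race == "Black").astype(float)
    out["race_south_asian"] = (race == "South Asian").astype(float)
    out["race_east_asian"] = (race == "East Asian").astype(float)
    out["race_mixed_other"] = (race == "Mixed/other").astype(float)
    conc = df["conception"].astype(str)
    out["ivf"] = (conc == "IVF").astype(float)
    out["ovulation_induction"] = (conc == "ovulation induction").astype(float)
    for col in ("chronic_hypertension", "diabetes", "sle_aps",
                "prev_sga", "prev_pe", "prev_stillbirth"):
        out[col] = df[col].astype(float)
    out["nulliparous"] = (df["parity"].astype(str) == "nulliparous").astype(float)
    return out


class MomRegression(BaseModel):
    """log10 expected biomarker value as an additive regression on covariates."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    biomarker: str
    reference_log10: float
    coefficients: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_terms(self):
        unknown = set(self.coefficients) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown covariate terms in MoM regression: {sorted(unknown)}")
        return self

    def expected_log10(self, features: Mapping[str, float]) -> float:
        """reference_log10 plus the sum of coefficient terms on this profile."""
        total = self.reference_log10
        missing = [t for t in self.coefficients if t not in features]
        if missing:
            raise MissingCovariateError(
                f"profile lacks covariates required by {self.biomarker} MoM regression: {missing}")
        for term, coef in self.coefficients.items():
            total += coef * float(features[term])
        return total

    def to_mom(self, raw_value: float, features: Mapping[str, float]) -> float:
        """Observed value divided by the covariate-specific expected median."""
        if raw_value <= 0:
            raise ValueError(f"{self.biomarker} raw value must be positive, got {raw_value}")
        return raw_value / 10.0 ** self.expected_log10(features)


class LikelihoodPlane(BaseModel):
    """Folded-plane mean log10 MoM over (GA at delivery, birth-weight Z).

    ``mu(g, z) = slope_g * min(g - knot_g, 0) + slope_z * min(z - knot_z, 0)``:
    continuous, planar on each side of the knot, and identically zero for
    unaffected pregnancies (``g >= knot_g`` and ``z >= knot_z``), whose
    expected MoM is therefore 1.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    biomarker: str
    knot_g: float = 40.0
    knot_z: float = 0.0
    slope_g: float
    slope_z: float
    sigma: float = Field(gt=0)

    def mu(self, g, z):
        g = np.asarray(g, dtype=float)
        z = np.asarray(z, dtype=float)
        out = self.slope_g * np.minimum(g - self.knot_g, 0.0) \
            + self.slope_z * np.minimum(z - self.knot_z, 0.0)
        return float(out) if out.ndim == 0 else out

    def log_likelihood(self, log10_mom, g, z):
        """Gaussian log density of the observed log10 MoM at mean mu(g, z)."""
        resid = np.asarray(log10_mom, dtype=float) - self.mu(g, z)
        out = -0.5 * (resid / self.sigma) ** 2 - math.log(self.sigma * math.sqrt(2.0 * math.pi))
        return float(out) if np.ndim(out) == 0 else out


class PriorComponent(BaseModel):
    """One bivariate-Gaussian pathway of the prior over (g, z)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    weight: float = Field(gt=0, le=1)
    mean_g: float
    mean_z: float
    sd_g: float = Field(gt=0)
    sd_z: float = Field(gt=0)
    rho: float = Field(gt=-1, lt=1)


class PriorSpec(BaseModel):
    """Prior joint density: mixture of pathways translated by maternal effects.

    The maternal-factor effect maps shift the means of *every* component by the
    same amount, so the prior density of an individual woman is a translation
    of the baseline density.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    components: List[PriorComponent]
    effects_g: Dict[str, float] = Field(default_factory=dict)
    effects_z: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self):
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        for name, eff in (("effects_g", self.effects_g), ("effects_z", self.effects_z)):
            unknown = set(eff) - set(FEATURE_NAMES)
            if unknown:
                raise ValueError(f"unknown covariate terms in {name}: {sorted(unknown)}")
        return self

    def shift(self, features: Mapping[str, float]) -> Tuple[float, float]:
        """Additive (delta_g, delta_z) for one profile's feature map."""
        dg = dz = 0.0
        for term, coef in self.effects_g.items():
            if term not in features:
                raise MissingCovariateError(f"profile lacks covariate {term} required by prior effects")
            dg += coef * float(features[term])
        for term, coef in self.effects_z.items():
            if term not in features:
                raise MissingCovariateError(f"profile lacks covariate {term} required by prior effects")
            dz += coef * float(features[term])
        return dg, dz


class CompetingRisksParams(BaseModel):
    """Full parameter set: prior pathways, MoM regressions, likelihood planes."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    prior: PriorSpec
    mom_regressions: Dict[str, MomRegression]
    likelihood_planes: Dict[str, LikelihoodPlane]
    box_g: Tuple[float, float] = (24.0, 43.0)
    box_z: Tuple[float, float] = (-5.0, 5.0)

    @model_validator(mode="after")
    def _check(self):
        if self.box_g[0] >= self.box_g[1] or self.box_z[0] >= self.box_z[1]:
            raise ValueError("box bounds must be increasing")
        for name, reg in self.mom_regressions.items():
            if reg.biomarker != name:
                raise ValueError(f"mom_regressions key {name!r} != biomarker {reg.biomarker!r}")
        for name, plane in self.likelihood_planes.items():
            if plane.biomarker != name:
                raise ValueError(f"likelihood_planes key {name!r} != biomarker {plane.biomarker!r}")
        return self

    # -- serialisation -------------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.model_dump(mode="json"), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "CompetingRisksParams":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls.model_validate(payload)


# ---------------------------------------------------------------------------
# Stand-in default MoM regressions and likelihood planes.  Directionality:
# in placentally-dysfunctional pregnancies (early delivery, small baby)
# UtA-PI MoM rises while PAPP-A and PlGF MoMs fall.
# ---------------------------------------------------------------------------

DEFAULT_MOM_REGRESSIONS: Dict[str, MomRegression] = {
    "uta_pi": MomRegression(
        biomarker="uta_pi",
        reference_log10=math.log10(1.70),
        coefficients={"ga_c": -0.030, "weight_c": -0.0008, "smoker": -0.010, "race_black": 0.020},
    ),
    "pappa": MomRegression(
        biomarker="pappa",
        reference_log10=math.log10(2.50),
        coefficients={"ga_c": 0.060, "weight_c": -0.0040, "smoker": -0.080,
                      "race_black": 0.150, "ivf": -0.080},
    ),
    "plgf": MomRegression(
        biomarker="plgf",
        reference_log10=math.log10(35.0),
        coefficients={"ga_c": 0.050, "weight_c": -0.0030, "smoker": 0.100,
                      "race_black": 0.200, "ivf": -0.050},
    ),
}

# Knots at 38 weeks and Z = -1: only pregnancies delivering clearly early
# and/or with clearly small babies carry deviant expected MoMs, so the
# population median MoM of each biomarker stays near 1 (term, non-small
# pregnancies dominate the cohort).
DEFAULT_LIKELIHOOD_PLANES: Dict[str, LikelihoodPlane] = {
    "uta_pi": LikelihoodPlane(biomarker="uta_pi", knot_g=38.0, knot_z=-1.0,
                              slope_g=-0.015, slope_z=-0.050, sigma=0.12),
    "pappa": LikelihoodPlane(biomarker="pappa", knot_g=38.0, knot_z=-1.0,
                             slope_g=0.010, slope_z=0.040, sigma=0.25),
    "plgf": LikelihoodPlane(biomarker="plgf", knot_g=38.0, knot_z=-1.0,
                            slope_g=0.025, slope_z=0.060, sigma=0.18),
}

# Maternal-history effects on the prior means (weeks for g, Z units for z).
# Signs follow the risk-factor literature: smoking, chronic hypertension,
# SLE/APS and a previous SGA baby lower the expected birth-weight Z; vascular
# disease and a previous preterm/PE delivery shorten expected gestation.
DEFAULT_EFFECTS_G: Dict[str, float] = {
    "chronic_hypertension": -0.50, "sle_aps": -0.50, "prev_pe": -0.40,
    "prev_stillbirth": -0.50, "diabetes": -0.30, "ivf": -0.25,
    "smoker": -0.10, "nulliparous": -0.10, "prev_sga": -0.20,
}
DEFAULT_EFFECTS_Z: Dict[str, float] = {
    "smoker": -0.35, "chronic_hypertension": -0.35, "sle_aps": -0.35,
    "prev_sga": -0.55, "prev_pe": -0.15, "prev_stillbirth": -0.20,
    "nulliparous": -0.12, "ivf": -0.12, "diabetes": 0.10,
}
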