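"""Cohort CSV readers/writers, config loading and the end-to-end runner.

CSV dialect: comma-separated UTF-8, '.' decimal point, empty cell = missing;
gestational ages are decimal weeks (37 weeks + 3 days = 37.4286).  Risks are
serialised with 10 significant digits so byte-level determinism checks are
meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .params import GA_SCREEN_WINDOW, CompetingRisksParams

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSchemaError",
    "read_cohort",
    "write_cohort",
    "write_risks",
    "load_config",
    "generator_config_from_file",
    "run_end_to_end",
]

REQUIRED_MATERNAL = (
    "age", "weight", "height", "race", "conception", "smoker",
    "chronic_hypertension", "diabetes", "sle_aps", "parity",
    "prev_sga", "prev_pe", "prev_stillbirth", "ga_at_screen",
)
OPTIONAL_NUMERIC = (
    "interpregnancy_interval", "ga_last_delivery",
    "uta_pi", "pappa", "plgf", "map_mom",
    "ga_delivery", "birth_weight", "z",
)
OPTIONAL_FLAGS = ("pe", "sga10", "sga3")
NUMERIC_REQUIRED = ("age", "weight", "height", "ga_at_screen")
KNOWN_COLUMNS = set(REQUIRED_MATERNAL) | set(OPTIONAL_NUMERIC) | set(OPTIONAL_FLAGS)


class CohortSchemaError(ValueError):
    pass


def _coerce_numeric(df: pd.DataFrame, col: str, problems: list) -> None:
    raw = df[col]
    converted = pd.to_numeric(raw, errors="coerce").astype(float)
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    for idx in df.index[bad]:
        problems.append({"line": int(idx) + 2, "column": col,
                         "reason": f"malformed number {raw.loc[idx]!r}"})
    df[col] = converted


def read_cohort(path) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a cohort CSV.

    Returns ``(cohort, excluded)``: typed valid rows, and a side report of
    rejected rows with 1-based file line numbers and reasons (malformed
    numbers, screening GA outside 11+0 to 13+6 weeks, delivery before 24+0).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_MATERNAL if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"cohort file lacks required columns: {missing}")
    unknown = [c for c in df.columns if c not in KNOWN_COLUMNS]
    if unknown:
        logger.warning("ignoring unknown cohort columns: %s", unknown)
        df = df.drop(columns=unknown)

    problems: list = []
    for col in df.columns:
        if col in ("race", "conception", "parity"):
            continue
        _coerce_numeric(df, col, problems)

    bad_rows = {p["line"] - 2 for p in problems}
    lo, hi = GA_SCREEN_WINDOW
    ga_screen = df["ga_at_screen"]
    out_of_window = ga_screen.notna() & ((ga_screen < lo) | (ga_screen > hi + 1e-9))
    for idx in df.index[out_of_window]:
        problems.append({"line": int(idx) + 2, "column": "ga_at_screen",
                         "reason": f"screen GA {ga_screen.loc[idx]} outside 11+0 to 13+6 weeks"})
    bad_rows |= set(np.flatnonzero(out_of_window.to_numpy()))

    if "ga_delivery" in df.columns:
        gd = df["ga_delivery"]
        early = gd.notna() & (gd < 24.0)
        for idx in df.index[early]:
            problems.append({"line": int(idx) + 2, "column": "ga_delivery",
                             "reason": "delivery before 24+0"})
        bad_rows |= set(np.flatnonzero(early.to_numpy()))
        if "birth_weight" in df.columns:
            mismatch = gd.notna() != df["birth_weight"].notna()
            for idx in df.index[mismatch]:
                problems.append({"line": int(idx) + 2, "column": "ga_delivery",
                                 "reason": "birth weight and GA at delivery must be jointly present"})
            bad_rows |= set(np.flatnonzero(mismatch.to_numpy()))

    for col in NUMERIC_REQUIRED:
        absent = df[col].isna()
        for idx in df.index[absent]:
            if int(idx) not in bad_rows:
                problems.append({"line": int(idx) + 2, "column": col,
                                 "reason": "required value missing"})
        bad_rows |= set(np.flatnonzero(absent.to_numpy()))

    excluded = pd.DataFrame(problems, columns=["line", "column", "reason"])
    good = df.drop(index=[df.index[i] for i in sorted(bad_rows)])
    for col in ("smoker", "chronic_hypertension", "diabetes", "sle_aps",
                "prev_sga", "prev_pe", "prev_stillbirth", *OPTIONAL_FLAGS):
        if col in good.columns:
            good[col] = good[col].fillna(0).astype(int)
    return good.reset_index(drop=True), excluded


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_risks(risks: pd.DataFrame, path) -> None:
    risks.to_csv(path, index=False, float_format="%.10g")


def load_config(path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def generator_config_from_file(path):
    """Generator configuration from a YAML/JSON file.

    Recognised top-level blocks (each optional; calibrated defaults fill the
    rest): ``chart``, ``missingness``, ``pe_rates``, ``marginals``, ``params``.
    Unknown blocks are rejected.
    """
    from .charts import WeightChart
    from .cohort import (GeneratorConfig, MaternalMarginals, Missingness,
                         PERates, default_generator_config)

    payload = load_config(path) or {}
    known = {"chart", "missingness", "pe_rates", "marginals", "params"}
    unknown = set(payload) - known
    if unknown:
        raise CohortSchemaError(f"unknown generator config blocks: {sorted(unknown)}")
    base = default_generator_config()
    return GeneratorConfig(
        marginals=(MaternalMarginals.model_validate(payload["marginals"])
                   if "marginals" in payload else base.marginals),
        params=(CompetingRisksParams.model_validate(payload["params"])
                if "params" in payload else base.params),
        chart=(WeightChart.from_config(payload["chart"])
               if "chart" in payload else base.chart),
        pe_rates=(PERates.model_validate(payload["pe_rates"])
                  if "pe_rates" in payload else base.pe_rates),
        missingness=(Missingness.model_validate(payload["missingness"])
                     if "missingness" in payload else base.missingness),
    )


def _params_hash(params: CompetingRisksParams) -> str:
    payload = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_end_to_end(n: int, seed: int, outdir,
                   config=None, fpr: float = 0.10) -> Dict:
    """simulate -> screen -> validate -> compare with one seed.

    Writes cohort/risks CSVs, a validation report JSON mirroring the
    (method x outcome) layout, a comparison block, and a manifest with
    parameter hashes.  Returns the report dict.
    """
    from . import __version__
    from .cohort import default_generator_config, simulate_cohort
    from .comparators import (compare_at_fixed_fpr, comparator_features,
                              default_comparators)
    from .model import (BIOMARKER_COMBOS, DEFAULT_TARGETS, CompetingRisksModel,
                        ScreeningValidation)
    from .fastscreen import target_column
    from .model import _outcome_labels

    if n < 1:
        raise ValueError("n must be >= 1")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or default_generator_config()

    cohort = simulate_cohort(n, seed, cfg)
    write_cohort(cohort, outdir / "cohort.csv")

    model = CompetingRisksModel(cfg.params)
    risks = model.predict(cohort)
    write_risks(pd.concat([risks], axis=1), outdir / "risks.csv")

    results = ScreeningValidation(cohort, model, fpr=fpr).fit()
    report = {
        "n": n, "seed": seed, "fpr": fpr,
        "discrimination": results.discrimination.to_dict(orient="records"),
        "calibration": results.calibration.to_dict(orient="records"),
    }

    # head-to-head against the logistic comparators on preterm SGA<10th,
    # complete-case for UtA-PI (all comparator stubs use it)
    comps = default_comparators()
    feats = comparator_features(cohort, cfg.params)
    needed = sorted({t for m in comps.values() for t in m.terms})
    ok = np.ones(len(cohort), dtype=bool)
    for t in needed:
        if t in feats.columns:
            ok &= ~feats[t].isna().to_numpy()
    if ok.sum() > 50:
        sub = cohort.loc[ok]
        sub_feats = feats.loc[ok]
        labels = _outcome_labels(sub, 0.10, 37.0)
        if 0 < labels.sum() < labels.size:
            main = model.predict(sub, [(0.10, 37.0)])[target_column(0.10, 37.0)].to_numpy()
            comp_risks = {name: m.predict_frame(sub_feats) for name, m in comps.items()}
            report["comparison"] = compare_at_fixed_fpr(
                main, comp_risks, labels, fpr).to_dict(orient="records")

    manifest = {
        "version": __version__,
        "seed": seed,
        "n": n,
        "params_sha256": _params_hash(cfg.params),
        "chart": cfg.chart.to_config(),
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
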