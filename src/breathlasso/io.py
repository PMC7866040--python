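"""Readers/writers and the reproducible end-to-end pipeline runner.

Cohorts are delimited text (CSV, header row, compound names quoted where
needed): metadata columns ``subject_id, group, age, sex, co2_percent``
followed by one ``alv_<compound>`` and one ``env_<compound>`` column per
panel compound.  Models and reports serialize to JSON; pipeline
configuration to YAML.  Every written artifact embeds the seed and a hash
of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc as qc_mod
from .cohort import generate_cohort, reference_cohort_spec
from .evaluate import performance_table, roc_curve
from .pipeline import (
    CONTRASTS,
    IteratedModel,
    PipelineConfig,
    bootstrap_cis,
    design_matrix,
    fit_iterated,
    outcome_vector,
    subset_contrast,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("subject_id", "group", "age", "sex", "co2_percent")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load and validate a cohort CSV.

    Malformed rows (non-numeric or negative concentrations) are reported
    with their 0-based row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    alv = sorted(c[4:] for c in df.columns if c.startswith("alv_"))
    env = sorted(c[4:] for c in df.columns if c.startswith("env_"))
    if not alv:
        raise ValueError("no alv_<compound> columns found")
    if alv != env:
        raise ValueError("alveolar and environmental compound sets differ")
    for c in df.columns:
        if not (c.startswith("alv_") or c.startswith("env_")):
            continue
        values = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[values.isna() & df[c].notna()]
        if len(bad):
            raise ValueError(f"non-numeric value in column {c!r}, row {bad[0]}")
        neg = df.index[values < 0]
        if len(neg):
            raise ValueError(f"negative concentration in column {c!r}, row {neg[0]}")
        df[c] = values
    return df


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _stamp(config: PipelineConfig) -> dict:
    return {"seed": config.seed, "config_hash": config_hash(config),
            "config": asdict(config)}


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)


def load_model(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def predict_from_model_dict(model: dict, cohort: pd.DataFrame) -> np.ndarray:
    """Case probabilities from a serialized model applied to cohort rows."""
    final = model["final_fit"]
    variables = final["variables"] or []
    center = model["standardization"]["center"]
    scale = model["standardization"]["scale"]
    X = design_matrix(cohort, [v for v in variables if v not in ("age", "sex")])
    eta = np.full(len(cohort), final["intercept"], dtype=float)
    for v, b in zip(variables, final["coef"]):
        eta += b * (X[v].to_numpy(float) - center[v]) / scale[v]
    return 1.0 / (1.0 + np.exp(-eta))


def run_pipeline(
    config: PipelineConfig,
    cohort: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
    min_sensitivity: float = 85.0,
) -> dict:
    """simulate/ingest -> QC -> iterated fit -> evaluation, reproducibly.

    Returns a dict of artifacts (cohort, qc report, model, evaluation); if
    ``outdir`` is given they are also written to disk, each stamped with
    the seed and config hash.
    """
    if config.contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {config.contrast!r}")
    if cohort is None:
        contrast_arg = None if config.contrast in ("lung_any", "adk_vs_sqcc") else config.contrast
        spec = reference_cohort_spec(contrast_arg, seed=config.seed)
        cohort = generate_cohort(spec)
        logger.info("simulated cohort: %d subjects", len(cohort))

    sample_qc = qc_mod.filter_co2(cohort, config.co2_threshold)
    clean = cohort[cohort["subject_id"].isin(sample_qc.retained_samples)]
    clean = clean.reset_index(drop=True)
    compound_qc = qc_mod.environmental_exclusion(clean, config.alpha)
    logger.info(
        "QC: %d samples retained, %d discarded; %d compounds retained, %d excluded",
        len(sample_qc.retained_samples), len(sample_qc.discarded_samples),
        len(compound_qc.retained_compounds), len(compound_qc.excluded_compounds),
    )

    data = subset_contrast(clean, config.contrast)
    X = design_matrix(data, compound_qc.retained_compounds)
    y = outcome_vector(data, config.contrast)

    model = fit_iterated(X, y, config)
    bootstrap_cis(X, y, model, B=config.bootstrap, seed=config.seed,
                  tol=config.tol, max_iter=config.max_iter)

    probs = model.predict(X)
    roc = roc_curve(probs, y)
    table = performance_table(roc, min_sensitivity)
    lo, hi = roc.auc_ci()
    logger.info("%s: in-sample AUC %.4f (95%% CI %.4f-%.4f)",
                config.contrast, roc.auc, lo, hi)

    stamp = _stamp(config)
    qc_report = {
        **stamp,
        "samples": sample_qc.to_dict(),
        "compounds": compound_qc.to_dict(),
    }
    evaluation = {
        **stamp,
        "auc": roc.auc,
        "auc_se": roc.auc_se,
        "auc_ci95": [lo, hi],
        "n_cases": roc.n_cases,
        "n_controls": roc.n_controls,
        "performance_table": table.to_dict(orient="records"),
    }
    model_report = {**stamp, **model.to_dict()}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, outdir / "cohort.csv")
        save_json(qc_report, outdir / "qc_report.json")
        save_json(model_report, outdir / "model.json")
        save_json(evaluation, outdir / "evaluation.json")

    return {
        "cohort": cohort,
        "qc_report": qc_report,
        "model": model,
        "model_report": model_report,
        "evaluation": evaluation,
    }
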