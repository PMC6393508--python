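"""End-to-end analysis pipeline: exclusion -> scoring -> capacity fitting ->
measures table -> correlation/Bayes-factor report -> latent-variable models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import correlation_table, render_correlation_matrix
from .mft import DEFAULT_BOUNDS, fit_ccc_table
from .scoring import (
    EXCLUSION_THRESHOLDS,
    apply_exclusion_criteria,
    build_measures_table,
)
from .sem import SemModel, battery_model_specs, compare_models

__all__ = ["PipelineConfig", "run_full_analysis", "render_table1", "exclusion_summaries"]


class SchemaError(ValueError):
    """An input table is missing required columns."""


REQUIRED_COLUMNS = {
    "mft_trials": [
        "subject_id", "block", "majority_count", "minority_count",
        "exposure_time_ms", "responded", "correct",
    ],
    "ant_trials": ["subject_id", "cue", "congruency", "correct", "rt_ms"],
    "nback_summary": ["subject_id", "task", "level", "accuracy"],
    "span_trials": [
        "subject_id", "task", "set_size", "fully_correct",
        "distractor_correct", "distractor_total",
    ],
    "composites": [
        "subject_id", "fsiq", "vci", "pri", "wmi", "psi", "education_years_us",
    ],
}


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "results"
    ccc_objective: str = "binomial"
    ccc_bounds: tuple = DEFAULT_BOUNDS
    bf_one_sided: bool = False
    sem_models: tuple = ("iq_cc_wm", "gc_gf_cc", "gc_gf_wm", "cc_wm")
    apply_exclusions: bool = True
    seed: int = 0
    exclusion_thresholds: dict = field(default_factory=dict)


def _read(indir: Path, name: str) -> pd.DataFrame:
    path = indir / f"{name}.csv"
    if not path.exists():
        raise FileNotFoundError(f"missing input table {path}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def exclusion_summaries(
    mft_trials: pd.DataFrame,
    ant_trials: pd.DataFrame,
    nback_summary: pd.DataFrame,
    span_trials: pd.DataFrame,
    composites: pd.DataFrame,
) -> pd.DataFrame:
    """Per-subject criterion fields feeding the exclusion filter."""
    valid = mft_trials.groupby("subject_id")["responded"].mean()
    ant_acc = ant_trials.groupby("subject_id")["correct"].mean()
    nb0 = (
        nback_summary[nback_summary["level"] == 0]
        .groupby("subject_id")["accuracy"]
        .min()
    )
    span = span_trials.assign(
        acc=lambda d: d["distractor_correct"] / d["distractor_total"]
    )
    dist = span.groupby(["subject_id", "task"])["acc"].mean().groupby("subject_id").min()
    out = composites.set_index("subject_id")[["education_years_us"]].copy()
    out["mft_valid_prop"] = valid
    out["ant_overall_acc"] = ant_acc
    out["nback0_acc"] = nb0
    out["span_distractor_acc"] = dist
    return out.reset_index()


def render_table1(measures: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/min/max per index, one row per measure."""
    cols = [c for c in measures.columns if c not in ("subject_id", "education_years_us")]
    rows = []
    for c in cols:
        v = measures[c].dropna()
        rows.append(
            {
                "index": c,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "min": v.min(),
                "max": v.max(),
            }
        )
    return pd.DataFrame(rows)


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the full analysis sequence; returns the artifact paths."""
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    tables = {name: _read(indir, name) for name in REQUIRED_COLUMNS}

    # 1. exclusion
    summaries = exclusion_summaries(**tables)
    if config.apply_exclusions:
        kept, report = apply_exclusion_criteria(
            summaries, thresholds=config.exclusion_thresholds or None
        )
        report.to_frame().to_csv(outdir / "exclusion_report.csv", index=False)
    else:
        kept = summaries
    if len(kept) == 0:
        raise RuntimeError("no subjects remain after exclusion")
    keep_ids = set(kept["subject_id"])
    tables = {
        name: df[df["subject_id"].isin(keep_ids)] for name, df in tables.items()
    }

    # 2. capacity fitting
    ccc = fit_ccc_table(
        tables["mft_trials"],
        objective=config.ccc_objective,
        bounds=config.ccc_bounds,
    )
    ccc.to_csv(outdir / "ccc_estimates.csv", index=False)

    # 3. measures table
    measures = build_measures_table(
        tables["composites"], ccc, tables["ant_trials"],
        tables["nback_summary"], tables["span_trials"],
    )
    measures.to_csv(outdir / "measures.csv", index=False)
    render_table1(measures).to_csv(outdir / "table1.csv", index=False)

    # 4. correlations + Bayes factors
    corr = correlation_table(measures, one_sided_bf=config.bf_one_sided)
    corr.to_csv(outdir / "correlations.csv", index=False)
    (outdir / "correlation_matrix.txt").write_text(render_correlation_matrix(corr))

    # 5. latent-variable models
    specs = battery_model_specs()
    complete = measures.dropna()
    fits = {}
    sem_rows = []
    for name in config.sem_models:
        spec = specs[name]
        model = SemModel.from_dataframe(spec, complete)
        fit = model.fit(seed=config.seed)
        fits[name] = fit
        fit.standardized_estimates().to_csv(
            outdir / f"sem_{name}_estimates.csv", index=False
        )
        sem_rows.append(
            {
                "model": name,
                "chi_square": fit.chi_square,
                "df": fit.df,
                "chi_sq_over_df": fit.chi_sq_over_df,
                "rmsea": fit.rmsea,
                "tli": fit.tli,
                "cfi": fit.cfi,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    pd.DataFrame(sem_rows).to_csv(outdir / "sem_fit_indices.csv", index=False)

    comparisons = []
    if "gc_gf_cc" in fits and "gc_gf_wm" in fits:
        comparisons.append(
            {"pair": "gc_gf_cc vs gc_gf_wm",
             **compare_models(fits["gc_gf_cc"], fits["gc_gf_wm"])}
        )
    (outdir / "model_comparisons.json").write_text(
        json.dumps(comparisons, indent=2, default=str)
    )

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_subjects_in": int(summaries.shape[0]),
        "n_subjects_kept": int(len(keep_ids)),
        "ccc_objective": config.ccc_objective,
        "sem_models": list(config.sem_models),
        "exclusion_thresholds": {**EXCLUSION_THRESHOLDS, **config.exclusion_thresholds},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "output_dir": str(outdir),
        "n_kept": len(keep_ids),
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
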