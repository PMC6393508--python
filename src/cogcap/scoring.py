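"""Scoring rules for the behavioural battery and the cohort exclusion filter.

Flanker (ANT-R) conflict effect, N-back difference indices, all-or-nothing
load (ANL) span scores, and the participant exclusion criteria.  Everything
operates on plain pandas DataFrames using the trial CSV schemas documented in
each function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "trim_rt_trials",
    "conflict_effect",
    "nback_index",
    "anl_score",
    "apply_exclusion_criteria",
    "build_measures_table",
    "ExclusionReport",
    "MEASURES_COLUMNS",
    "NBACK_LEVELS",
    "EXCLUSION_THRESHOLDS",
]

#: required N-back levels and the hardest level per task
NBACK_LEVELS = {"spatial": (0, 1, 2), "verbal": (0, 1, 2, 3)}
NBACK_HARDEST = {"spatial": 2, "verbal": 3}

#: exclusion thresholds; all comparisons are strict ("less than" excludes)
EXCLUSION_THRESHOLDS = {
    "mft_valid_prop": 0.95,
    "ant_overall_acc": 0.90,
    "nback0_acc": 0.90,
    "span_distractor_acc": 0.85,
    "education_years_us": 15.0,
}

MEASURES_COLUMNS = [
    "subject_id",
    "fsiq",
    "vci",
    "pri",
    "wmi",
    "psi",
    "ccc",
    "ec",
    "spatial_nback",
    "verbal_nback",
    "ospan",
    "rotspan",
    "symspan",
    "education_years_us",
]


def trim_rt_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Remove error trials, then RT outliers beyond +/- 3 SD per congruency.

    The mean and SD are computed over each congruency condition's correct
    trials in a single pass (no iterative re-trimming).  Input schema:
    ``subject_id, cue, congruency, correct, rt_ms``.

    Returns the surviving trials and the proportion of input trials removed
    (errors plus outliers).  A congruency condition with fewer than two
    correct trials passes through untrimmed with a warning.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    correct = trials[trials["correct"].astype(bool)]
    kept_parts = []
    for cong, grp in correct.groupby("congruency", sort=False):
        if len(grp) < 2:
            warnings.warn(
                f"condition {cong!r} has <2 correct trials; left untrimmed",
                stacklevel=2,
            )
            kept_parts.append(grp)
            continue
        rt = grp["rt_ms"].astype(float)
        mu, sd = rt.mean(), rt.std(ddof=1)
        kept_parts.append(grp[(rt - mu).abs() <= 3.0 * sd])
    kept = (
        pd.concat(kept_parts).sort_index()
        if kept_parts
        else correct.iloc[0:0]
    )
    excluded_prop = 1.0 - len(kept) / len(trials)
    if len(kept) == 0:
        warnings.warn("no trials survive trimming", stacklevel=2)
    return kept, excluded_prop


def conflict_effect(trials: pd.DataFrame) -> float:
    """Reverse-coded flanker conflict effect, in milliseconds.

    ``mean RT(congruent) - mean RT(incongruent)``; typically negative, with
    values closer to zero indicating more efficient executive control.
    Expects trimmed trials (see :func:`trim_rt_trials`).
    """
    by_cong = trials.groupby("congruency")["rt_ms"].mean()
    for cond in ("congruent", "incongruent"):
        if cond not in by_cong.index or np.isnan(by_cong[cond]):
            raise ValueError(f"missing {cond} trials: conflict effect undefined")
    return float(by_cong["congruent"] - by_cong["incongruent"])


def nback_index(accuracy_by_level: dict[int, float], task: str) -> float:
    """N-back performance index: hardest-level accuracy minus 0-back accuracy.

    Spatial uses 2-back, verbal uses 3-back as the hardest level.  Negative
    values are expected; closer to zero means better performance.
    """
    if task not in NBACK_LEVELS:
        raise ValueError(f"unknown N-back task {task!r}")
    for level in NBACK_LEVELS[task]:
        if level not in accuracy_by_level:
            raise ValueError(f"{task} N-back missing level {level}")
    for level, acc in accuracy_by_level.items():
        if not (0.0 <= acc <= 1.0):
            raise ValueError(f"accuracy at level {level} outside [0, 1]")
    return float(accuracy_by_level[NBACK_HARDEST[task]] - accuracy_by_level[0])


def anl_score(trials: pd.DataFrame) -> float:
    """All-or-nothing load span score in [0, 1].

    A trial contributes its full set size when every element was recalled in
    correct serial order, and nothing otherwise; the sum is normalised by the
    total number of to-be-recalled elements.  Schema: ``subject_id, task,
    set_size, fully_correct, distractor_correct, distractor_total``.
    """
    if len(trials) == 0:
        raise ValueError("no span trials")
    if trials["task"].nunique() > 1:
        raise ValueError("anl_score expects trials from a single task")
    sizes = trials["set_size"].astype(float)
    hits = trials["fully_correct"].astype(bool)
    return float((sizes * hits).sum() / sizes.sum())


@dataclass
class ExclusionReport:
    """Per-rule record of who was excluded and why."""

    removed: dict[str, list] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return len({sid for sids in self.removed.values() for sid in sids})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "subject_id": sid}
            for rule, sids in self.removed.items()
            for sid in sids
        ]
        return pd.DataFrame(rows, columns=["rule", "subject_id"])


def apply_exclusion_criteria(
    cohort: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the battery's performance and education exclusion rules.

    ``cohort`` needs one row per subject with columns ``subject_id,
    mft_valid_prop, ant_overall_acc, nback0_acc, span_distractor_acc,
    education_years_us`` (``nback0_acc`` and ``span_distractor_acc`` are the
    minima across the relevant tasks).  A subject is removed when a value is
    strictly below its threshold — a subject exactly at a threshold is kept.
    Removal is the union over rules; the report lists removals per rule.
    """
    th = dict(EXCLUSION_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    missing = [c for c in th if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing criterion fields: {missing}")
    for col in th:
        bad = cohort[cohort[col].isna()]
        if len(bad):
            sid = bad["subject_id"].iloc[0]
            raise ValueError(f"subject {sid!r}: missing value for {col}")

    report = ExclusionReport()
    drop: set = set()
    for col, cut in th.items():
        failed = cohort.loc[cohort[col] < cut, "subject_id"].tolist()
        report.removed[col] = failed
        drop.update(failed)
    kept = cohort[~cohort["subject_id"].isin(drop)].reset_index(drop=True)
    return kept, report


def build_measures_table(
    composites: pd.DataFrame,
    ccc: pd.DataFrame,
    ant_trials: pd.DataFrame,
    nback_summary: pd.DataFrame,
    span_trials: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-subject measures table feeding correlation and SEM.

    Inputs use the task CSV schemas; output columns are
    :data:`MEASURES_COLUMNS`.  Subjects missing from an input get NaN for the
    affected measures.
    """
    out = composites.set_index("subject_id")[
        ["fsiq", "vci", "pri", "wmi", "psi", "education_years_us"]
    ].copy()

    out["ccc"] = ccc.set_index("subject_id")["ccc_bps"]

    ec = {}
    for sid, grp in ant_trials.groupby("subject_id"):
        trimmed, _ = trim_rt_trials(grp)
        ec[sid] = conflict_effect(trimmed)
    out["ec"] = pd.Series(ec)

    for task in ("spatial", "verbal"):
        vals = {}
        sub = nback_summary[nback_summary["task"] == task]
        for sid, grp in sub.groupby("subject_id"):
            acc = dict(zip(grp["level"].astype(int), grp["accuracy"].astype(float)))
            vals[sid] = nback_index(acc, task)
        out[f"{task}_nback"] = pd.Series(vals)

    for task in ("ospan", "rotspan", "symspan"):
        vals = {}
        sub = span_trials[span_trials["task"] == task]
        for sid, grp in sub.groupby("subject_id"):
            vals[sid] = anl_score(grp)
        out[task] = pd.Series(vals)

    return out.reset_index()[MEASURES_COLUMNS]
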