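"""Synthetic cohort generator for the full battery.

Subjects are drawn from a three-factor population model (IQ, CC, WM with a
configurable correlation matrix).  Each behavioural measure gets a true
parameter from ``loading * factor + unique noise`` mapped into its task's
parameter space, and trial-level data are then emitted per task:

* MFT-M: the voluntary/forced-termination process of the capacity model —
  a trial terminates voluntarily with probability
  ``1 - (1 - P_group)**(2**C * ET / group_size)`` and is then correct with
  probability p0, otherwise it is a guess (correct with probability 0.5);
* ANT-R: positive-shifted normal RTs with a conflict shift on incongruent
  trials, accuracy near ceiling with a lapse rate;
* N-back: binomial accuracy per level;
* complex span: all-or-nothing recall, correct with probability
  ``q**set_size`` for per-element recall probability q, plus near-ceiling
  distractor accuracy.

Only the MFT-M generator is a process model; the other tasks use simple
parametric forms chosen for testability, not cognitive realism.  One global
seed fans out to per-task substreams so adding a task does not perturb the
existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mft import MftCondition, default_design, group_success_probability

__all__ = [
    "PopulationConfig",
    "simulate_mft_subject",
    "simulate_ant_subject",
    "simulate_nback_subject",
    "simulate_span_subject",
    "simulate_cohort",
    "CohortData",
]

#: default latent correlation matrix for (IQ, CC, WM)
DEFAULT_LATENT_CORR = ((1.0, 0.84, 0.87), (0.84, 1.0, 0.96), (0.87, 0.96, 1.0))

#: per-measure (factor, loading); unique variance is 1 - loading^2
DEFAULT_LOADINGS = {
    "fsiq": ("IQ", 0.95),
    "vci": ("IQ", 0.55),
    "pri": ("IQ", 0.75),
    "wmi": ("IQ", 0.65),
    "psi": ("IQ", 0.55),
    "ccc": ("CC", 0.75),
    "ec": ("CC", 0.45),
    "spatial_nback": ("WM", 0.55),
    "verbal_nback": ("WM", 0.30),
    "ospan": ("WM", 0.65),
    "rotspan": ("WM", 0.65),
    "symspan": ("WM", 0.70),
}

SPAN_DESIGNS = {
    "ospan": (2, 3, 4, 5, 6, 7, 2, 3, 4, 5),       # 10 trials, sizes 2-7
    "rotspan": (3, 4, 5, 6, 7, 3, 4, 5),           # 8 trials, sizes 3-7
    "symspan": (2, 3, 4, 5, 2, 3, 4, 5),           # 8 trials, sizes 2-5
}

NBACK_TRIALS = {"spatial": {0: 80, 1: 80, 2: 80}, "verbal": {0: 18, 1: 18, 2: 18, 3: 18}}


@dataclass
class PopulationConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_subjects: int = 88
    latent_corr: tuple = DEFAULT_LATENT_CORR
    loading_map: dict = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    seed: int = 0

    # MFT-M design: 12 blocks x 36 trials, 3 congruencies x 4 exposure times
    mft_blocks: int = 12
    mft_trials_per_block: int = 36
    mft_exposure_times: tuple = (0.25, 0.5, 1.0, 2.0)
    mft_ratios: tuple = ((5, 0), (4, 1), (3, 2))
    group_size: int = 3

    # population location/scale of the true capacity (bps) and baseline
    ccc_mean: float = 3.82
    ccc_sd: float = 0.62
    ccc_clip: tuple = (0.5, 8.0)
    p0_mean: float = 0.99

    # ANT-R: 4 blocks x 72 trials; conflict shift distribution (ms)
    ant_blocks: int = 4
    ant_trials_per_block: int = 72
    ant_base_rt: float = 520.0
    ant_rt_sd: float = 90.0
    ant_conflict_mean: float = 144.0
    ant_conflict_sd: float = 42.0
    ant_lapse: float = 0.02

    # true 0-back accuracies; kept high so the 90% exclusion rule bites only
    # deliberately injected violators (18 verbal trials make a 0.95 true
    # accuracy fail the cut through sampling noise alone in ~1 of 4 subjects)
    nback0_spatial: float = 0.99
    nback0_verbal: float = 0.99

    # span: per-element recall probability logistic intercept/slope
    span_strength_mean: float = 1.66
    span_strength_sd: float = 0.55
    distractor_acc_mean: float = 0.97
    distractor_acc_sd: float = 0.02

    education_years: float = 16.0

    #: per-rule counts of deliberately injected exclusion violators
    inject_violations: dict = field(default_factory=dict)

    def validate(self) -> None:
        m = np.asarray(self.latent_corr, dtype=float)
        if m.shape != (3, 3) or not np.allclose(m, m.T):
            raise ValueError("latent_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ValueError("latent_corr is not positive semidefinite")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, stable per-task substream from the global seed."""
    import zlib

    tag = zlib.crc32(name.encode())  # stable across processes, unlike hash()
    return np.random.default_rng(np.random.SeedSequence([seed, tag]))


def simulate_trial_outcomes(
    condition: MftCondition,
    capacity: float,
    p0: float,
    n_trials: int,
    rng: np.random.Generator,
    p_guess: float = 0.5,
    integer_attempts: bool = False,
) -> np.ndarray:
    """Vectorised correct/incorrect outcomes for one design cell.

    Default mode terminates voluntarily with probability
    ``1 - (1 - P_group)**k`` for the real-valued attempt budget
    ``k = 2**C * ET / group_size`` (exactly the closed-form accuracy model).
    ``integer_attempts=True`` instead draws ``floor(k)`` independent group
    samples per trial — the brute-force process the closed form idealises.
    """
    p_group = group_success_probability(condition)
    k = (2.0**capacity) * condition.exposure_time / condition.group_size
    if integer_attempts:
        draws = rng.random((n_trials, max(int(np.floor(k)), 0)))
        vt = (draws < p_group).any(axis=1)
    else:
        p_vt = 1.0 - (1.0 - p_group) ** k
        vt = rng.random(n_trials) < p_vt
    p_correct = np.where(vt, p0, p_guess)
    return (rng.random(n_trials) < p_correct).astype(int)


def simulate_mft_subject(
    subject_id: str,
    capacity: float,
    p0: float,
    rng: np.random.Generator,
    config: PopulationConfig | None = None,
    respond_prob: float = 1.0,
) -> pd.DataFrame:
    """Trial table for one subject under the voluntary/forced-termination
    process.  Blocks each hold one exposure time with the three congruency
    conditions interleaved (12 trials each for the default 36-trial block)."""
    cfg = config or PopulationConfig()
    rows = []
    ets = list(cfg.mft_exposure_times)
    blocks_per_et = cfg.mft_blocks // len(ets)
    per_cong = cfg.mft_trials_per_block // len(cfg.mft_ratios)
    block = 0
    for et in ets:
        for _ in range(blocks_per_et):
            for (maj, mino) in cfg.mft_ratios:
                cond = MftCondition(maj, mino, et, group_size=cfg.group_size)
                p_group = group_success_probability(cond)
                k = (2.0**capacity) * et / cfg.group_size
                p_vt = 1.0 - (1.0 - p_group) ** k
                for _ in range(per_cong):
                    responded = bool(rng.random() < respond_prob)
                    if not responded:
                        rows.append((subject_id, block, maj, mino, et * 1000, 0, 0, np.nan))
                        continue
                    vt = rng.random() < p_vt
                    p_corr = p0 if vt else 0.5
                    correct = int(rng.random() < p_corr)
                    rt = rng.uniform(300, 2500)
                    rows.append((subject_id, block, maj, mino, et * 1000, 1, correct, rt))
            block += 1
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "block", "majority_count", "minority_count",
            "exposure_time_ms", "responded", "correct", "rt_ms",
        ],
    )


def simulate_ant_subject(
    subject_id: str,
    conflict_shift: float,
    rng: np.random.Generator,
    config: PopulationConfig | None = None,
    accuracy: float | None = None,
) -> pd.DataFrame:
    """Flanker trial table: 4 cue conditions x 2 congruencies, RTs from a
    positive-shifted normal with the conflict shift on incongruent trials."""
    cfg = config or PopulationConfig()
    n = cfg.ant_blocks * cfg.ant_trials_per_block
    cues = np.tile(["none", "double", "valid", "invalid"], n // 4)
    congruency = np.tile(["congruent", "incongruent"], n // 2)
    rt = rng.normal(cfg.ant_base_rt, cfg.ant_rt_sd, size=n)
    rt = np.clip(rt, 120.0, None)
    rt = np.where(congruency == "incongruent", rt + conflict_shift, rt)
    acc = 1.0 - cfg.ant_lapse if accuracy is None else accuracy
    correct = (rng.random(n) < acc).astype(int)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "cue": cues,
            "congruency": congruency,
            "correct": correct,
            "rt_ms": rt,
        }
    )


def simulate_nback_subject(
    subject_id: str,
    true_acc: dict[str, dict[int, float]],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-level binomial accuracies; spatial 80 trials/level (240 total),
    verbal 18 trials/level."""
    rows = []
    for task, levels in true_acc.items():
        for level, p in levels.items():
            n = NBACK_TRIALS[task][level]
            hits = rng.binomial(n, p)
            rows.append((subject_id, task, level, hits / n))
    return pd.DataFrame(rows, columns=["subject_id", "task", "level", "accuracy"])


def simulate_span_subject(
    subject_id: str,
    recall_prob: float,
    distractor_acc: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """All-or-nothing recall: a trial of set size s is fully correct with
    probability recall_prob**s; distractor performance is binomial."""
    rows = []
    for task, sizes in SPAN_DESIGNS.items():
        for s in sizes:
            hit = int(rng.random() < recall_prob**s)
            d_total = s  # one distractor per element
            d_correct = rng.binomial(d_total, distractor_acc)
            rows.append((subject_id, task, s, hit, d_correct, d_total))
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "task", "set_size", "fully_correct",
            "distractor_correct", "distractor_total",
        ],
    )


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class CohortData:
    """All simulated tables plus the ground truth behind them."""

    mft_trials: pd.DataFrame
    ant_trials: pd.DataFrame
    nback_summary: pd.DataFrame
    span_trials: pd.DataFrame
    composites: pd.DataFrame
    truth: pd.DataFrame
    config: PopulationConfig

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.mft_trials.to_csv(out / "mft_trials.csv", index=False)
        self.ant_trials.to_csv(out / "ant_trials.csv", index=False)
        self.nback_summary.to_csv(out / "nback_summary.csv", index=False)
        self.span_trials.to_csv(out / "span_trials.csv", index=False)
        self.composites.to_csv(out / "composites.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        cfg = asdict(self.config)
        cfg["latent_corr"] = [list(r) for r in np.asarray(cfg["latent_corr"])]
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))


def simulate_cohort(config: PopulationConfig | None = None) -> CohortData:
    """Generate a full synthetic cohort from the latent-factor model."""
    cfg = config or PopulationConfig()
    cfg.validate()
    n = cfg.n_subjects
    corr = np.asarray(cfg.latent_corr, dtype=float)

    rng_lat = substream(cfg.seed, "latents")
    z = rng_lat.multivariate_normal(np.zeros(3), corr, size=n)  # IQ, CC, WM
    factor_idx = {"IQ": 0, "CC": 1, "WM": 2}

    # standardized measure-level scores: loading * factor + unique noise
    rng_meas = substream(cfg.seed, "measures")
    measure_z: dict[str, np.ndarray] = {}
    for name, (factor, lam) in cfg.loading_map.items():
        noise = rng_meas.normal(size=n)
        measure_z[name] = lam * z[:, factor_idx[factor]] + np.sqrt(1 - lam**2) * noise

    ids = [f"S{i:04d}" for i in range(1, n + 1)]

    # --- ground-truth task parameters ----------------------------------
    true_c = np.clip(cfg.ccc_mean + cfg.ccc_sd * measure_z["ccc"], *cfg.ccc_clip)
    true_p0 = np.clip(cfg.p0_mean + 0.005 * substream(cfg.seed, "p0").normal(size=n), 0.9, 1.0)
    true_shift = np.clip(
        cfg.ant_conflict_mean - cfg.ant_conflict_sd * measure_z["ec"], 10.0, 400.0
    )
    sp2 = np.clip(0.51 + 0.21 * measure_z["spatial_nback"], 0.05, 0.995)
    vb3 = np.clip(0.87 + 0.12 * measure_z["verbal_nback"], 0.40, 0.995)
    recall_q = _logistic(cfg.span_strength_mean + cfg.span_strength_sd * measure_z["ospan"])
    recall_q_rot = _logistic(
        cfg.span_strength_mean + cfg.span_strength_sd * measure_z["rotspan"]
    )
    recall_q_sym = _logistic(
        cfg.span_strength_mean + cfg.span_strength_sd * measure_z["symspan"]
    )
    rng_distr = substream(cfg.seed, "distractor")
    distractor = np.clip(
        rng_distr.normal(cfg.distractor_acc_mean, cfg.distractor_acc_sd, size=n),
        0.5, 1.0,
    )

    education = np.full(n, cfg.education_years)
    respond_prob = np.full(n, 0.995)

    # --- deliberate exclusion violators (from the end of the roster) ----
    violators: dict[str, list[str]] = {}
    cursor = n - 1
    for rule, count in cfg.inject_violations.items():
        chosen = []
        for _ in range(count):
            if cursor < 0:
                raise ValueError("more injected violators than subjects")
            chosen.append(cursor)
            cursor -= 1
        violators[rule] = [ids[i] for i in chosen]
        for i in chosen:
            if rule == "mft_valid_prop":
                respond_prob[i] = 0.80
            elif rule == "education_years_us":
                education[i] = 12.0
            elif rule == "span_distractor_acc":
                distractor[i] = 0.70
            elif rule == "nback0_acc":
                pass  # handled via the 0-back accuracy below
            elif rule == "ant_overall_acc":
                pass  # handled via the lapse rate below
            else:
                raise ValueError(f"unknown exclusion rule {rule!r}")

    # --- emit trial tables ----------------------------------------------
    mft_parts, ant_parts, nb_parts, span_parts = [], [], [], []
    for i, sid in enumerate(ids):
        rng_i = substream(cfg.seed, f"subject-{sid}")
        mft_parts.append(
            simulate_mft_subject(
                sid, true_c[i], true_p0[i], rng_i, cfg, respond_prob=respond_prob[i]
            )
        )
        ant_acc = None
        if sid in violators.get("ant_overall_acc", []):
            ant_acc = 0.80
        ant_parts.append(
            simulate_ant_subject(sid, true_shift[i], rng_i, cfg, accuracy=ant_acc)
        )
        violator0 = sid in violators.get("nback0_acc", [])
        acc0_sp = cfg.nback0_spatial if not violator0 else 0.80
        acc0_vb = cfg.nback0_verbal if not violator0 else 0.80
        nb_truth = {
            "spatial": {0: acc0_sp, 1: (acc0_sp + sp2[i]) / 2, 2: sp2[i]},
            "verbal": {
                0: acc0_vb,
                1: min(0.95, vb3[i] + 0.04),
                2: min(0.95, vb3[i] + 0.02),
                3: vb3[i],
            },
        }
        nb_parts.append(simulate_nback_subject(sid, nb_truth, rng_i))
        df = []
        for task, q in (
            ("ospan", recall_q[i]),
            ("rotspan", recall_q_rot[i]),
            ("symspan", recall_q_sym[i]),
        ):
            part = simulate_span_subject(sid, q, distractor[i], rng_i)
            df.append(part[part["task"] == task])
        span_parts.append(pd.concat(df))

    composites = pd.DataFrame(
        {
            "subject_id": ids,
            "fsiq": 100 + 15 * measure_z["fsiq"],
            "vci": 100 + 15 * measure_z["vci"],
            "pri": 100 + 15 * measure_z["pri"],
            "wmi": 100 + 15 * measure_z["wmi"],
            "psi": 100 + 15 * measure_z["psi"],
            "education_years_us": education,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "iq_factor": z[:, 0],
            "cc_factor": z[:, 1],
            "wm_factor": z[:, 2],
            "true_ccc": true_c,
            "true_p0": true_p0,
            "true_conflict_shift_ms": true_shift,
            "true_spatial_2back": sp2,
            "true_verbal_3back": vb3,
            "true_ospan_q": recall_q,
            "true_rotspan_q": recall_q_rot,
            "true_symspan_q": recall_q_sym,
        }
    )
    return CohortData(
        mft_trials=pd.concat(mft_parts, ignore_index=True),
        ant_trials=pd.concat(ant_parts, ignore_index=True),
        nback_summary=pd.concat(nb_parts, ignore_index=True),
        span_trials=pd.concat(span_parts, ignore_index=True),
        composites=composites,
        truth=truth,
        config=cfg,
    )
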