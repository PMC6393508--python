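"""Information-theoretic model of the masked majority-function task (MFT-M).

The task presents a set of arrows (five in the standard design) pointing left
or right; the observer reports the majority direction.  Under the grouping
search strategy, the observer repeatedly samples ``group_size`` arrows at a
time until the sample is congruent (all arrows agree).  The condition's
difficulty is summarised by three derived quantities:

* ``P_group`` — probability that a random sample of ``group_size`` arrows is
  congruent,
* ``N = group_size / P_group`` — expected number of arrows scanned before a
  congruent sample is found,
* entropy ``log2(N)`` (bits) and rate ``log2(N / ET)`` (bits per second) for
  exposure time ``ET``.

Within a trial the search either terminates voluntarily (a congruent sample
found within the exposure time; the response is then correct with baseline
probability ``p0``) or is forced to terminate by the mask (the response is a
guess, correct with probability ``p_guess``).  If the observer transmits
information at ``C`` bits per second, the number of sampling attempts
available is ``k = 2**C * ET / group_size`` and the expected accuracy is

    E[acc] = p0 - (1 - P_group)**k * (p0 - p_guess)

``C`` is the capacity of cognitive control (CCC) and is estimated per subject
by maximum likelihood over the incongruent design cells, with ``p0`` plugged
in from the congruent (5:0) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import comb

__all__ = [
    "MftCondition",
    "CellAccuracy",
    "CapacityModel",
    "CapacityResults",
    "group_success_probability",
    "expected_scanned_arrows",
    "information_entropy_bits",
    "information_rate_bps",
    "expected_accuracy",
    "baseline_accuracy",
    "fit_ccc",
    "default_design",
    "cells_from_trials",
]

#: probability clamp used in the binomial log-likelihood
EPS = 1e-6

#: default search interval for the capacity, bits per second
DEFAULT_BOUNDS = (0.1, 10.0)


@dataclass(frozen=True)
class MftCondition:
    """A design cell: an arrow-ratio x exposure-time combination."""

    majority_count: int
    minority_count: int
    exposure_time: float  # seconds
    total_arrows: int = 5
    group_size: int = 3

    def __post_init__(self) -> None:
        if self.majority_count + self.minority_count != self.total_arrows:
            raise ValueError(
                f"majority {self.majority_count} + minority {self.minority_count} "
                f"!= total {self.total_arrows}"
            )
        if not (self.majority_count >= self.minority_count >= 0):
            raise ValueError("require majority_count >= minority_count >= 0")
        if self.group_size > self.total_arrows:
            raise ValueError("group_size larger than the arrow set")
        if self.group_size < 1:
            raise ValueError("group_size must be positive")
        if self.exposure_time <= 0:
            raise ValueError("exposure_time must be positive")

    @property
    def ratio(self) -> str:
        return f"{self.majority_count}:{self.minority_count}"

    @property
    def congruent(self) -> bool:
        """True for the fully congruent (e.g. 5:0) condition."""
        return self.minority_count == 0


@dataclass(frozen=True)
class CellAccuracy:
    """Observed trial counts for one design cell."""

    condition: MftCondition
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValueError("need 0 <= n_correct <= n_trials")

    @property
    def accuracy(self) -> float:
        if self.n_trials == 0:
            raise ValueError("cell has no trials")
        return self.n_correct / self.n_trials


def group_success_probability(condition: MftCondition) -> float:
    """Probability that a random sample of ``group_size`` arrows is congruent.

    A sample is congruent when all arrows come from the majority set or all
    from the minority set: ``[C(maj,k) + C(min,k)] / C(total,k)``.
    """
    k = condition.group_size
    total = comb(condition.total_arrows, k, exact=True)
    hits = comb(condition.majority_count, k, exact=True) + comb(
        condition.minority_count, k, exact=True
    )
    return hits / total


def expected_scanned_arrows(condition: MftCondition) -> float:
    """Expected number of arrows scanned: N = group_size / P_group."""
    p = group_success_probability(condition)
    if p == 0:
        raise ValueError(f"degenerate condition {condition.ratio}: P_group = 0")
    return condition.group_size / p


def information_entropy_bits(condition: MftCondition) -> float:
    """Information entropy of the condition, log2(N)."""
    return math.log2(expected_scanned_arrows(condition))


def information_rate_bps(condition: MftCondition) -> float:
    """Information rate of the condition, log2(N / ET), in bits per second."""
    return math.log2(expected_scanned_arrows(condition) / condition.exposure_time)


def expected_accuracy(
    capacity: float,
    condition: MftCondition,
    p0: float,
    p_guess: float = 0.5,
) -> float:
    """Expected response accuracy under the grouping-search capacity model.

    ``p0 - (1 - P_group)**(2**C * ET / group_size) * (p0 - p_guess)``.
    Continuous and nondecreasing in ``capacity`` and in exposure time when
    ``p0 >= p_guess``; bounded between ``p_guess`` and ``p0``.
    """
    if not (0.0 <= p0 <= 1.0 and 0.0 <= p_guess <= 1.0):
        raise ValueError("p0 and p_guess must be probabilities")
    p_group = group_success_probability(condition)
    if p_group >= 1.0:
        return p0
    k = (2.0**capacity) * condition.exposure_time / condition.group_size
    return p0 - (1.0 - p_group) ** k * (p0 - p_guess)


def baseline_accuracy(cells: list[CellAccuracy]) -> float:
    """Trial-weighted mean accuracy over the congruent (minority 0) cells."""
    congruent = [c for c in cells if c.condition.congruent]
    if not congruent:
        raise ValueError("no congruent cells: baseline accuracy not estimable")
    n = sum(c.n_trials for c in congruent)
    if n == 0:
        raise ValueError("congruent cells contain no trials")
    return sum(c.n_correct for c in congruent) / n


def default_design(
    exposure_times: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0),
    ratios: tuple[tuple[int, int], ...] = ((5, 0), (4, 1), (3, 2)),
    total_arrows: int = 5,
    group_size: int = 3,
) -> list[MftCondition]:
    """The 3 (congruency) x 4 (exposure time) factorial design."""
    return [
        MftCondition(maj, mino, et, total_arrows, group_size)
        for et in exposure_times
        for (maj, mino) in ratios
    ]


def cells_from_trials(trials: pd.DataFrame) -> list[CellAccuracy]:
    """Aggregate an MFT trial table into per-condition accuracy cells.

    Expects columns ``majority_count, minority_count, exposure_time_ms,
    responded, correct`` (the trial CSV schema).  Only trials with a response
    enter the counts.
    """
    out: list[CellAccuracy] = []
    keys = ["majority_count", "minority_count", "exposure_time_ms"]
    for (maj, mino, et_ms), grp in trials.groupby(keys, sort=True):
        cond = MftCondition(int(maj), int(mino), float(et_ms) / 1000.0)
        resp = grp[grp["responded"].astype(bool)]
        out.append(CellAccuracy(cond, len(resp), int(resp["correct"].astype(bool).sum())))
    return out


class CapacityModel:
    """Maximum-likelihood estimator of the capacity of cognitive control.

    Parameters
    ----------
    cells : list of CellAccuracy
        Per-condition trial counts, congruent cells included.  Congruent
        cells are constant in C and contribute only through the baseline
        accuracy estimate.
    p_guess : float
        Accuracy of a forced-termination guess (chance level, 0.5 for a
        two-alternative response).
    bounds : (float, float)
        Search interval for C in bits per second.
    objective : {"binomial", "least_squares"}
        Binomial per-cell log-likelihood (default) or squared error between
        predicted and observed cell accuracies.
    """

    def __init__(
        self,
        cells: list[CellAccuracy],
        p_guess: float = 0.5,
        bounds: tuple[float, float] = DEFAULT_BOUNDS,
        objective: str = "binomial",
    ) -> None:
        if objective not in ("binomial", "least_squares"):
            raise ValueError(f"unknown objective {objective!r}")
        self.cells = list(cells)
        self.p_guess = float(p_guess)
        self.bounds = (float(bounds[0]), float(bounds[1]))
        self.objective = objective
        self.incongruent = [
            c for c in self.cells if not c.condition.congruent and c.n_trials > 0
        ]
        if not self.incongruent:
            raise ValueError("no incongruent cells with trials: C not estimable")
        self.p0 = baseline_accuracy(self.cells)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, **kwargs) -> "CapacityModel":
        """Build from a trial-level table (MFT trial CSV schema)."""
        return cls(cells_from_trials(trials), **kwargs)

    # -- objective -------------------------------------------------------

    def _predicted(self, capacity: float) -> np.ndarray:
        return np.array(
            [
                expected_accuracy(capacity, c.condition, self.p0, self.p_guess)
                for c in self.incongruent
            ]
        )

    def loglike(self, capacity: float) -> float:
        """Binomial log-likelihood of the incongruent cells at a given C."""
        p = np.clip(self._predicted(capacity), EPS, 1.0 - EPS)
        n = np.array([c.n_trials for c in self.incongruent], dtype=float)
        x = np.array([c.n_correct for c in self.incongruent], dtype=float)
        return float(np.sum(x * np.log(p) + (n - x) * np.log(1.0 - p)))

    def _sse(self, capacity: float) -> float:
        p = self._predicted(capacity)
        obs = np.array([c.accuracy for c in self.incongruent])
        return float(np.sum((obs - p) ** 2))

    def _score(self, capacity: float) -> float:
        """Quantity minimised by fit()."""
        if self.objective == "binomial":
            return -self.loglike(capacity)
        return self._sse(capacity)

    # -- fitting ---------------------------------------------------------

    def fit(self, grid_points: int = 128) -> "CapacityResults":
        """Estimate C by a coarse grid scan followed by bounded refinement.

        The expected-accuracy surface can be nearly flat at the bounds (all
        cells at ceiling or at chance), so the scan guards against local
        stalls before Brent refinement.
        """
        lo, hi = self.bounds
        grid = np.linspace(lo, hi, grid_points)
        scores = np.array([self._score(c) for c in grid])
        i = int(np.argmin(scores))
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, grid_points - 1)]
        converged = True
        if a < b:
            res = optimize.minimize_scalar(
                self._score, bounds=(a, b), method="bounded",
                options={"xatol": 1e-6},
            )
            c_hat = float(res.x)
            converged = bool(res.success)
            if self._score(c_hat) > scores[i]:
                c_hat = float(grid[i])
        else:  # degenerate window (optimum at a bound)
            c_hat = float(grid[i])

        obs = np.array([c.accuracy for c in self.incongruent])
        # data carry no information about C when every incongruent cell sits
        # at or below chance, or at or above the baseline
        non_identifiable = bool(
            np.all(obs <= self.p_guess) or np.all(obs >= self.p0)
        )
        at_bound = bool(
            c_hat - lo < 1e-3 * (hi - lo) or hi - c_hat < 1e-3 * (hi - lo)
        )
        if non_identifiable:
            converged = False
            at_bound = True
            c_hat = lo if np.all(obs <= self.p_guess) else hi

        per_cell = [
            (
                c.condition,
                c.accuracy,
                expected_accuracy(c_hat, c.condition, self.p0, self.p_guess),
            )
            for c in self.incongruent
        ]
        return CapacityResults(
            model=self,
            capacity=c_hat,
            baseline_accuracy=self.p0,
            guess_accuracy=self.p_guess,
            log_likelihood=self.loglike(c_hat),
            per_cell=per_cell,
            converged=converged,
            at_bound=at_bound,
        )


@dataclass
class CapacityResults:
    """Fitted capacity of cognitive control for one subject."""

    model: CapacityModel
    capacity: float  # C, bits per second
    baseline_accuracy: float  # p0
    guess_accuracy: float  # p_guess
    log_likelihood: float
    per_cell: list[tuple[MftCondition, float, float]] = field(repr=False)
    converged: bool = True
    at_bound: bool = False

    def predicted(self, condition: MftCondition) -> float:
        return expected_accuracy(
            self.capacity, condition, self.baseline_accuracy, self.guess_accuracy
        )

    def summary(self) -> str:
        lines = [
            "Capacity of cognitive control (grouping-search ML fit)",
            "-" * 54,
            f"C          {self.capacity:8.3f} bps"
            + ("  [at bound]" if self.at_bound else ""),
            f"p0         {self.baseline_accuracy:8.4f}",
            f"p_guess    {self.guess_accuracy:8.4f}",
            f"logLik     {self.log_likelihood:8.2f}",
            f"converged  {self.converged}",
            "",
            "cell        ET(s)   observed  predicted",
        ]
        for cond, obs, pred in self.per_cell:
            lines.append(
                f"{cond.ratio:>5} {cond.exposure_time:8.2f}   {obs:8.4f}  {pred:9.4f}"
            )
        return "\n".join(lines)


def fit_ccc(
    cells: list[CellAccuracy],
    p_guess: float = 0.5,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    objective: str = "binomial",
) -> CapacityResults:
    """Convenience wrapper: ``CapacityModel(cells, ...).fit()``."""
    return CapacityModel(cells, p_guess=p_guess, bounds=bounds, objective=objective).fit()


def fit_ccc_table(trials: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit the capacity for every subject in an MFT trial table.

    Returns the CCC output table: ``subject_id, ccc_bps, p0, loglik,
    converged, at_bound``.
    """
    rows = []
    for sid, grp in trials.groupby("subject_id", sort=True):
        res = CapacityModel.from_trials(grp, **kwargs).fit()
        rows.append(
            {
                "subject_id": sid,
                "ccc_bps": res.capacity,
                "p0": res.baseline_accuracy,
                "loglik": res.log_likelihood,
                "converged": res.converged,
                "at_bound": res.at_bound,
            }
        )
    return pd.DataFrame(rows)
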