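"""Unit and property tests for the grouping-search capacity model."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cogcap.mft import (
    CapacityModel,
    CellAccuracy,
    MftCondition,
    baseline_accuracy,
    default_design,
    expected_accuracy,
    expected_scanned_arrows,
    fit_ccc,
    group_success_probability,
    information_entropy_bits,
    information_rate_bps,
)
from cogcap.simulate import simulate_trial_outcomes


def cond(maj, mino, et=1.0, **kw):
    return MftCondition(maj, mino, et, **kw)


class TestGroupProbability:
    @pytest.mark.parametrize(
        "maj,mino,expected", [(5, 0, 1.0), (4, 1, 0.4), (3, 2, 0.1)]
    )
    def test_five_arrow_design(self, maj, mino, expected):
        assert group_success_probability(cond(maj, mino)) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        total=st.integers(2, 8),
        group=st.integers(1, 8),
        maj=st.integers(1, 8),
    )
    def test_matches_exhaustive_enumeration(self, total, group, maj):
        """P_group equals the fraction of congruent subsets over all
        C(total, group) subsets of a labelled arrow set."""
        if group > total or maj > total or maj < total - maj:
            return
        c = cond(maj, total - maj, total_arrows=total, group_size=group)
        arrows = ["M"] * maj + ["m"] * (total - maj)
        subsets = list(itertools.combinations(arrows, group))
        congruent = sum(1 for s in subsets if len(set(s)) == 1)
        assert group_success_probability(c) == pytest.approx(congruent / len(subsets))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            MftCondition(2, 3, 1.0)  # majority smaller than minority
        with pytest.raises(ValueError):
            MftCondition(4, 1, 1.0, group_size=6)
        with pytest.raises(ValueError):
            MftCondition(4, 1, 0.0)


class TestInformationQuantities:
    @pytest.mark.parametrize("maj,mino,n", [(5, 0, 3.0), (4, 1, 7.5), (3, 2, 30.0)])
    def test_expected_scanned_arrows(self, maj, mino, n):
        assert expected_scanned_arrows(cond(maj, mino)) == pytest.approx(n)

    def test_degenerate_condition_errors(self):
        # a group larger than both majority and minority can never agree
        degenerate = cond(3, 2, group_size=4)
        with pytest.raises(ValueError, match="P_group = 0"):
            expected_scanned_arrows(degenerate)

    @pytest.mark.parametrize("maj,mino,bits", [(5, 0, 1.58), (4, 1, 2.91), (3, 2, 4.91)])
    def test_entropy_two_decimals(self, maj, mino, bits):
        assert round(information_entropy_bits(cond(maj, mino)), 2) == bits

    def test_entropy_ordering(self):
        e = [information_entropy_bits(cond(*r)) for r in [(5, 0), (4, 1), (3, 2)]]
        assert e[0] < e[1] < e[2]

    def test_rate_extremes_of_design(self, design):
        rates = [information_rate_bps(c) for c in design]
        assert min(rates) == pytest.approx(math.log2(1.5))
        assert max(rates) == pytest.approx(math.log2(120))
        assert round(max(rates), 2) == 6.91

    def test_rate_zero_when_n_equals_et(self):
        assert information_rate_bps(cond(5, 0, et=3.0)) == pytest.approx(0.0)


class TestExpectedAccuracy:
    def test_congruent_condition_pins_baseline(self):
        for c_val in [0.1, 1.0, 7.3]:
            assert expected_accuracy(c_val, cond(5, 0, 0.25), 0.97) == 0.97

    def test_short_exposure_limit_is_guessing(self):
        acc = expected_accuracy(1.0, cond(3, 2, 1e-9), 0.99, 0.5)
        assert acc == pytest.approx(0.5, abs=1e-6)

    def test_hand_evaluated_point(self):
        # k = 2^4 * 0.25 / 3 = 4/3; 0.99 - 0.9^(4/3) * 0.49
        acc = expected_accuracy(4.0, cond(3, 2, 0.25), 0.99, 0.5)
        assert acc == pytest.approx(0.99 - 0.9 ** (4 / 3) * 0.49, abs=1e-12)
        assert acc == pytest.approx(0.5642, abs=5e-4)

    def test_monotone_in_capacity_and_exposure_and_bounded(self, design):
        caps = np.linspace(0.1, 9, 40)
        for c in design:
            accs = [expected_accuracy(x, c, 0.99, 0.5) for x in caps]
            assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))
            assert all(0.5 - 1e-12 <= a <= 0.99 + 1e-12 for a in accs)
        for et_lo, et_hi in [(0.25, 0.5), (0.5, 1.0), (1.0, 2.0)]:
            assert expected_accuracy(3.0, cond(3, 2, et_hi), 0.99) >= expected_accuracy(
                3.0, cond(3, 2, et_lo), 0.99
            )

    def test_brute_force_process_oracle(self, rng):
        """With an integer attempt budget, simulating k independent group
        draws (voluntary stop -> Bernoulli(p0), forced stop -> Bernoulli(0.5))
        converges to the closed form."""
        c = cond(3, 2, 0.75)
        capacity = 3.0  # k = 8 * 0.75 / 3 = 2 attempts exactly
        n = 100_000
        outcomes = simulate_trial_outcomes(
            c, capacity, 0.99, n, rng, integer_attempts=True
        )
        expected = expected_accuracy(capacity, c, 0.99)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(outcomes.mean() - expected) < 3 * se


class TestBaselineAccuracy:
    def test_perfect_single_cell(self):
        cells = [CellAccuracy(cond(5, 0, 0.25), 36, 36)]
        assert baseline_accuracy(cells) == 1.0

    def test_trial_weighted_mean(self):
        ets = [0.25, 0.5, 1.0, 2.0]
        hits = [35, 33, 36, 34]
        cells = [CellAccuracy(cond(5, 0, e), 36, h) for e, h in zip(ets, hits)]
        assert baseline_accuracy(cells) == pytest.approx(138 / 144)

    def test_requires_congruent_cells_with_trials(self):
        with pytest.raises(ValueError):
            baseline_accuracy([CellAccuracy(cond(4, 1, 0.25), 36, 30)])
        with pytest.raises(ValueError):
            baseline_accuracy([CellAccuracy(cond(5, 0, 0.25), 0, 0)])


def make_cells(capacity, p0=1.0, n_per_cell=36, design=None):
    """Noise-free cells at the closed-form accuracies, counts rounded.

    p0 defaults to 1 here: with 36-trial cells any p0 >= 0.986 rounds the
    congruent counts to 36/36, so the two-stage fit would see a baseline of
    1.0 regardless and a generator p0 of e.g. 0.99 would bias the check.
    """
    cells = []
    for c in design or default_design():
        p = expected_accuracy(capacity, c, p0)
        cells.append(CellAccuracy(c, n_per_cell, round(n_per_cell * p)))
    return cells


class TestCapacityFit:
    def test_self_consistency_at_published_mean(self):
        res = fit_ccc(make_cells(3.82))
        assert abs(res.capacity - 3.82) < 0.1
        assert res.converged and not res.at_bound

    def test_bias_shrinks_with_trials(self, rng):
        true_c = 3.0
        design = default_design()

        def med_err(n_per_cell, reps=30):
            errs = []
            for _ in range(reps):
                cells = []
                for c in design:
                    if c.congruent:
                        cells.append(CellAccuracy(c, n_per_cell, int(rng.binomial(n_per_cell, 0.99))))
                    else:
                        correct = int(
                            simulate_trial_outcomes(c, true_c, 0.99, n_per_cell, rng).sum()
                        )
                        cells.append(CellAccuracy(c, n_per_cell, correct))
                errs.append(abs(fit_ccc(cells).capacity - true_c))
            return float(np.median(errs))

        assert med_err(360) < med_err(36) + 0.02

    def test_chance_data_pin_lower_bound(self):
        design = default_design()
        cells = [
            CellAccuracy(c, 36, 36 if c.congruent else 18) for c in design
        ]
        res = fit_ccc(cells)
        assert res.at_bound and not res.converged
        assert res.capacity == pytest.approx(res.model.bounds[0])

    def test_ceiling_data_pin_upper_bound(self):
        design = default_design()
        cells = [CellAccuracy(c, 36, 36) for c in design]
        res = fit_ccc(cells)
        assert res.at_bound and not res.converged
        assert res.capacity == pytest.approx(res.model.bounds[1])

    def test_least_squares_objective_agrees_on_clean_data(self):
        cells = make_cells(3.0)
        c_b = fit_ccc(cells).capacity
        c_ls = fit_ccc(cells, objective="least_squares").capacity
        assert abs(c_b - c_ls) < 0.15

    def test_predicted_accuracies_within_model_bounds(self):
        res = fit_ccc(make_cells(2.5))
        for _, _, pred in res.per_cell:
            assert res.guess_accuracy - 1e-9 <= pred <= res.baseline_accuracy + 1e-9

    def test_summary_mentions_capacity(self):
        s = fit_ccc(make_cells(3.82)).summary()
        assert "C " in s and "p0" in s

    def test_from_trials_roundtrip(self, small_cohort):
        one = small_cohort.mft_trials.query("subject_id == 'S0001'")
        res = CapacityModel.from_trials(one).fit()
        truth = small_cohort.truth.query("subject_id == 'S0001'")["true_ccc"].iloc[0]
        assert abs(res.capacity - truth) < 0.8  # single subject, sampling noise
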