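"""Covariance-structure engine: implied covariance algebra, ML fitting,
fit indices, model comparison, and the battery model fixtures."""

import numpy as np
import pandas as pd
import pytest

from cogcap.sem import (
    Covariance,
    ErrorVariance,
    Loading,
    SemModel,
    SemModelSpec,
    battery_model_specs,
    compare_models,
    fit_indices,
    implied_covariance,
    independence_spec,
    simulate_from_spec,
)


def toy_one_factor(fix_loadings=None):
    """Single latent, three indicators."""
    vals = fix_loadings or [1.0, None, None]
    return SemModelSpec(
        name="toy",
        manifest_vars=("y1", "y2", "y3"),
        latents=("F",),
        loadings=tuple(Loading("F", f"y{i+1}", v) for i, v in enumerate(vals)),
        latent_covs=(Covariance("F", "F"),),
        error_variances=tuple(ErrorVariance(f"y{i}") for i in (1, 2, 3)),
    )


class TestImpliedCovariance:
    def test_zero_loadings_give_error_structure(self):
        spec = SemModelSpec(
            name="errors-only",
            manifest_vars=("a", "b"),
            latents=("F",),
            loadings=(Loading("F", "a", 0.0), Loading("F", "b", 0.0)),
            latent_covs=(Covariance("F", "F", 1.0),),
            error_variances=(ErrorVariance("a"), ErrorVariance("b")),
            error_cov_links=(("a", "b"),),
        )
        sigma = implied_covariance(spec, np.array([2.0, 3.0, 0.5]))
        assert np.allclose(sigma, [[2.0, 0.5], [0.5, 3.0]])

    def test_unit_loadings_zero_errors_give_all_ones(self):
        spec = SemModelSpec(
            name="ones",
            manifest_vars=("a", "b", "c"),
            latents=("F",),
            loadings=tuple(Loading("F", m, 1.0) for m in ("a", "b", "c")),
            latent_covs=(Covariance("F", "F", 1.0),),
            error_variances=tuple(ErrorVariance(m, 0.0) for m in ("a", "b", "c")),
        )
        assert np.allclose(implied_covariance(spec, np.array([])), np.ones((3, 3)))

    def test_second_order_structure_matches_monte_carlo(self, rng):
        """Simulating the structural equations directly reproduces
        Sigma(theta) — an oracle independent of the matrix algebra."""
        spec = SemModelSpec(
            name="second-order",
            manifest_vars=("a", "b", "c", "d"),
            latents=("G", "F1", "F2"),
            loadings=(
                Loading("G", "F1", 1.0),
                Loading("G", "F2", 0.7),
                Loading("F1", "a", 1.0),
                Loading("F1", "b", 0.8),
                Loading("F2", "c", 1.0),
                Loading("F2", "d", 1.2),
            ),
            latent_covs=(
                Covariance("G", "G", 1.0),
                Covariance("F1", "F1", 0.0),
                Covariance("F2", "F2", 0.0),
            ),
            error_variances=tuple(ErrorVariance(m, 0.3) for m in "abcd"),
        )
        sigma = implied_covariance(spec, np.array([]))
        n = 400_000
        g = rng.normal(size=n)
        f1, f2 = g, 0.7 * g
        y = np.column_stack(
            [
                f1 + np.sqrt(0.3) * rng.normal(size=n),
                0.8 * f1 + np.sqrt(0.3) * rng.normal(size=n),
                f2 + np.sqrt(0.3) * rng.normal(size=n),
                1.2 * f2 + np.sqrt(0.3) * rng.normal(size=n),
            ]
        )
        assert np.allclose(np.cov(y.T), sigma, atol=0.02)

    def test_wrong_theta_length_rejected(self):
        with pytest.raises(ValueError, match="free parameters"):
            implied_covariance(toy_one_factor(), np.zeros(3))

    def test_unreachable_latent_rejected(self):
        with pytest.raises(ValueError, match="reaches no manifest"):
            SemModelSpec(
                name="bad",
                manifest_vars=("a",),
                latents=("F", "G"),
                loadings=(Loading("F", "a", 1.0),),
                latent_covs=(Covariance("F", "F"), Covariance("G", "G")),
                error_variances=(ErrorVariance("a"),),
            )


class TestMlFit:
    def test_saturated_model_fits_exactly(self, rng):
        # two manifests, q = 3 = p(p+1)/2 -> df 0, F_min 0
        spec = SemModelSpec(
            name="saturated",
            manifest_vars=("a", "b"),
            latents=(),
            loadings=(),
            latent_covs=(),
            error_variances=(ErrorVariance("a"), ErrorVariance("b")),
            error_cov_links=(("a", "b"),),
        )
        S = np.cov(rng.normal(size=(2, 200)))
        fit = SemModel(spec, S, 200).fit()
        assert spec.df == 0
        assert fit.chi_square == pytest.approx(0.0, abs=1e-8)
        assert fit.rmsea == 0.0

    def test_round_trip_recovery(self):
        spec = toy_one_factor()
        theta = np.array([0.8, 1.2, 1.5, 0.4, 0.3, 0.5])  # loadings y2,y3; var F; errors
        sigma = implied_covariance(spec, theta)
        fit = SemModel(spec, sigma, 1000).fit()
        assert fit.f_min < 1e-8
        assert np.abs(fit.theta - theta).max() < 1e-4

    def test_independence_model_misfit_grows_with_n(self, rng):
        x = rng.normal(size=500)
        data = np.column_stack([x, x + 0.5 * rng.normal(size=500), rng.normal(size=500)])
        S = np.cov(data.T)
        spec = independence_spec(("a", "b", "c"))
        chi_small = SemModel(spec, S, 100).fit(compute_indices=False).chi_square
        chi_large = SemModel(spec, S, 400).fit(compute_indices=False).chi_square
        assert 0 < chi_small < chi_large

    def test_nesting_monotonicity(self, rng):
        """Freeing a parameter can only decrease the discrepancy."""
        x = rng.normal(size=(300, 3))
        S = np.cov(x.T) + 0.3 * np.ones((3, 3)) + np.eye(3)
        restricted = toy_one_factor()
        extended = SemModelSpec(
            name="toy+",
            manifest_vars=restricted.manifest_vars,
            latents=restricted.latents,
            loadings=restricted.loadings,
            latent_covs=restricted.latent_covs,
            error_variances=restricted.error_variances,
            error_cov_links=(("y1", "y2"),),
        )
        f_r = SemModel(restricted, S, 300).fit(compute_indices=False).f_min
        f_e = SemModel(extended, S, 300).fit(compute_indices=False).f_min
        assert f_e <= f_r + 1e-8

    def test_chi_square_invariant_to_relabeling(self, rng):
        theta = np.array([0.8, 1.2, 1.5, 0.4, 0.3, 0.5])
        sigma = implied_covariance(toy_one_factor(), theta)
        noise = rng.normal(size=(3, 3)) * 0.05
        S = sigma + (noise + noise.T) / 2 + np.eye(3) * 0.05
        fit_a = SemModel(toy_one_factor(), S, 200).fit(compute_indices=False)
        perm = [2, 0, 1]
        spec_b = SemModelSpec(
            name="relabeled",
            manifest_vars=tuple(f"y{i+1}" for i in perm),
            latents=("F",),
            loadings=(
                Loading("F", "y3"), Loading("F", "y1", 1.0), Loading("F", "y2"),
            ),
            latent_covs=(Covariance("F", "F"),),
            error_variances=tuple(ErrorVariance(f"y{i+1}") for i in perm),
        )
        fit_b = SemModel(spec_b, S[np.ix_(perm, perm)], 200).fit(compute_indices=False)
        assert fit_a.chi_square == pytest.approx(fit_b.chi_square, abs=1e-5)

    def test_non_pd_covariance_rejected(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        spec = independence_spec(("a", "b"))
        with pytest.raises(ValueError, match="positive definite"):
            SemModel(spec, S, 100)


class TestFitIndices:
    def test_rmsea_zero_when_chi_below_df(self, rng):
        specs = battery_model_specs()
        theta = _theta_for(specs["cc_wm"])
        sigma = implied_covariance(specs["cc_wm"], theta)
        fit = SemModel(specs["cc_wm"], sigma, 88).fit()
        assert fit.chi_square < fit.df
        assert fit.rmsea == 0.0
        assert fit.verdicts["rmsea<0.06"]

    def test_formulas_on_constructed_fits(self):
        from cogcap.sem import SemResults

        spec = independence_spec(("a", "b", "c"))
        make = lambda chi, df: SemResults(
            spec=spec, theta=np.zeros(3), labels=[], implied_cov=np.eye(3),
            f_min=chi / 87, chi_square=chi, df=df, n=88, converged=True,
        )
        fit = fit_indices(make(20.0, 10), make(100.0, 3), 88)
        assert fit.rmsea == pytest.approx(np.sqrt(10 / (10 * 87)))
        assert fit.tli == pytest.approx(((100 / 3) - 2.0) / ((100 / 3) - 1.0))
        assert fit.cfi == pytest.approx(1 - 10 / 97)
        assert fit.bic == pytest.approx(20.0 + 3 * np.log(88))

    def test_baseline_equal_to_model_bounds_cfi(self):
        from cogcap.sem import SemResults

        spec = independence_spec(("a", "b"))
        make = lambda chi, df: SemResults(
            spec=spec, theta=np.zeros(2), labels=[], implied_cov=np.eye(2),
            f_min=0.1, chi_square=chi, df=df, n=50, converged=True,
        )
        fit = fit_indices(make(30.0, 5), make(30.0, 5), 50)
        assert 0.0 <= fit.cfi <= 1.0


class TestCompareModels:
    def _fit(self, chi, df, q, name="m"):
        from cogcap.sem import SemResults

        spec = independence_spec(tuple("abcdefg"[: df // 2 + 2]))
        res = SemResults(
            spec=spec, theta=np.zeros(1), labels=[], implied_cov=np.eye(2),
            f_min=0.0, chi_square=chi, df=df, n=88, converged=True,
        )
        res.bic = chi + q * np.log(88)
        res.spec = spec
        return res

    def test_identical_fits_all_zero(self):
        a = self._fit(10.0, 5, 3)
        rep = compare_models(a, a)
        assert rep["delta_chi_square"] == 0 and rep["bic_evidence"] == "none"

    def test_published_bic_difference_band(self):
        a, b = self._fit(8.12, 7, 14), self._fit(8.12, 7, 14)
        a.bic, b.bic = 70.80, 113.66
        rep = compare_models(a, b)
        assert rep["delta_bic"] == pytest.approx(-42.86)
        assert rep["bic_evidence"] == "very strong"

    def test_positive_band(self):
        a, b = self._fit(10.0, 5, 3), self._fit(10.0, 5, 3)
        a.bic, b.bic = 100.0, 104.0
        assert compare_models(a, b)["bic_evidence"] == "positive"


def _theta_for(spec, corrs=None):
    """Plausible population values for a battery fixture."""
    corrs = corrs or {}
    default_corr = {"IQ~~CC": 0.84, "IQ~~WM": 0.87, "CC~~WM": 0.96}
    default_corr.update(corrs)
    theta = []
    for kind, label in spec.free_parameters():
        if kind == "loading":
            theta.append(0.8)
        elif kind == "latent_cov":
            a, b = label.split("~~")
            theta.append(1.0 if a == b else default_corr.get(label, 0.6))
        elif kind == "error_var":
            theta.append(0.5)
        else:
            theta.append(0.08)
    return np.array(theta)


class TestBatteryFixtures:
    def test_degrees_of_freedom(self):
        specs = battery_model_specs()
        assert specs["iq_cc_wm"].df == 39
        assert specs["gc_gf_cc"].df == 7
        assert specs["gc_gf_wm"].df == 25
        assert specs["cc_wm"].df == 13

    def test_single_indicator_latent_pins_indicator_variance(self, rng):
        spec = battery_model_specs()["gc_gf_cc"]
        data = rng.normal(size=(120, 6))
        S = np.cov(data.T) + np.eye(6)
        fit = SemModel(spec, S, 120).fit(compute_indices=False)
        i = spec.manifest_vars.index("vci")
        assert fit.implied_cov[i, i] == pytest.approx(S[i, i], rel=1e-3)

    def test_latent_correlation_recovery_from_model1(self, rng):
        spec = battery_model_specs()["iq_cc_wm"]
        theta = _theta_for(spec)
        errs = []
        for rep in range(5):
            data = simulate_from_spec(spec, theta, 500, rng)
            fit = SemModel(spec, data.cov().to_numpy(), 500).fit(
                seed=rep, n_starts=2, compute_indices=False
            )
            lc = fit.latent_correlations()
            errs.append(
                max(
                    abs(lc.loc["IQ", "CC"] - 0.84),
                    abs(lc.loc["IQ", "WM"] - 0.87),
                    abs(lc.loc["CC", "WM"] - 0.96),
                )
            )
        assert np.median(errs) < 0.08

    def test_standardized_estimates_have_unit_scale(self):
        spec = battery_model_specs()["cc_wm"]
        theta = _theta_for(spec)
        sigma = implied_covariance(spec, theta)
        fit = SemModel(spec, sigma, 300).fit(compute_indices=False)
        est = fit.standardized_estimates()
        lat_corr = est[est["kind"] == "latent_cov"]
        assert (lat_corr["standardized"].abs() <= 1.0 + 1e-9).all()
        assert est[est["edge"] == "CC~~WM"]["standardized"].iloc[0] == pytest.approx(
            0.96, abs=1e-4
        )
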