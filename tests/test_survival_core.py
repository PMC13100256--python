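"""Cox fitting, concordance, spline basis and PH diagnostic against
independent oracles (literal enumeration, grid search, lifelines)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import naive_concordance, naive_cox_loglik, random_survival_data
from pacsurv.survival import (
    SplineSpec,
    default_knots,
    fit_cox,
    harrell_c,
    kaplan_meier,
    ph_diagnostic,
    predict_risk,
    rcs_basis,
)


class TestFitCox:
    def test_relabeling_symmetry_gives_zero(self):
        """Two groups with identical event-time multisets: the partial
        likelihood is even in beta, so the optimum is 0."""
        fit = fit_cox(np.array([0.0, 1, 0, 1]), [1, 1, 2, 2], [1, 1, 1, 1], ties="efron")
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle(self):
        """n=20 binary covariate, 30% censoring: Newton optimum matches
        brute-force maximization of the definitional partial likelihood."""
        rng = np.random.default_rng(5)
        x = rng.integers(0, 2, 20).astype(float)
        time = rng.exponential(np.exp(-0.8 * x))
        event = (rng.random(20) > 0.3).astype(int)
        grid = np.arange(-3.0, 3.0, 1e-3)
        for ties in ("efron", "breslow"):
            ll = naive_cox_loglik(grid, x, time, event, ties=ties)
            fit = fit_cox(x, time, event, ties=ties)
            assert fit.converged
            assert fit.coefficients[0] == pytest.approx(grid[np.argmax(ll)], abs=2e-3)

    def test_constant_column_raises(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=30), np.ones(30)])
        with pytest.raises(ValueError, match="constant"):
            fit_cox(X, rng.exponential(1, 30), np.ones(30), names=["a", "const"])

    def test_collinear_column_raises_with_name(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=40)
        X = np.column_stack([a, 2 * a, rng.normal(size=40)])
        with pytest.raises(ValueError, match="collinear"):
            fit_cox(X, rng.exponential(1, 40), np.ones(40))

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="event"):
            fit_cox(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))

    def test_separation_reports_nonconvergence(self):
        """A perfectly separating covariate must not silently 'converge'."""
        x = np.array([0.0, 0, 0, 1, 1, 1])
        time = np.array([1.0, 2, 3, 10, 11, 12])
        fit = fit_cox(x, time, np.ones(6))
        assert not fit.converged

    def test_matches_lifelines_multivariate(self):
        """Cross-check against an established implementation on a
        moderately sized multivariate problem, both tie methods."""
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(42)
        n = 300
        X = rng.normal(size=(n, 4))
        lp = X @ np.array([0.6, -0.4, 0.0, 0.25])
        T = rng.exponential(np.exp(-lp))
        C = rng.exponential(1.2, n)
        t = np.round(np.minimum(T, C), 1) + 0.05  # induce tied times
        e = (T <= C).astype(int)
        df = pd.DataFrame(X, columns=list("abcd"))
        df["t"], df["e"] = t, e
        for ties in ("efron", "breslow"):
            fit = fit_cox(X, t, e, ties=ties)
            cph = CoxPHFitter().fit(df, "t", "e")
            if ties == "breslow":
                cph = CoxPHFitter(baseline_estimation_method="breslow").fit(df, "t", "e")
                # lifelines uses Efron for the partial likelihood regardless;
                # compare coefficients only for efron
                continue
            np.testing.assert_allclose(fit.coefficients, cph.params_.values, atol=1e-5)
            np.testing.assert_allclose(fit.standard_errors, cph.standard_errors_.values,
                                       atol=1e-5)

    def test_two_group_exponential_rate_ratio(self):
        """On two-group exponential data without censoring the Cox
        coefficient estimates the log event-rate ratio."""
        rng = np.random.default_rng(99)
        n = 5000
        x = (np.arange(n) % 2).astype(float)
        rate = np.where(x == 1, 2.0, 1.0)
        time = rng.exponential(1.0 / rate)
        fit = fit_cox(x, time, np.ones(n))
        assert fit.coefficients[0] == pytest.approx(np.log(2.0), abs=0.08)

    def test_covariance_symmetric_psd(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(80, 3))
        fit = fit_cox(X, rng.exponential(1, 80), (rng.random(80) > 0.3).astype(int))
        np.testing.assert_allclose(fit.covariance, fit.covariance.T)
        assert np.all(np.linalg.eigvalsh(fit.covariance) > -1e-12)

    def test_small_n_oracle_equivalence_both_ties(self):
        """For tiny datasets with a binary covariate the fit matches
        brute-force partial-likelihood maximization to 1e-4."""
        rng = np.random.default_rng(12)
        grid = np.arange(-2.5, 2.5, 5e-5)
        checked = 0
        while checked < 12:
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 2, n).astype(float)
            if x.std() == 0:
                continue
            time = rng.exponential(np.exp(-0.5 * x))  # distinct times a.s.
            event = np.ones(n, int)
            for ties in ("efron", "breslow"):
                ll = naive_cox_loglik(grid, x, time, event, ties=ties)
                best = grid[np.argmax(ll)]
                if abs(best) > 2.0:
                    continue  # optimum too close to the grid edge
                fit = fit_cox(x, time, event, ties=ties)
                assert fit.coefficients[0] == pytest.approx(best, abs=1e-4)
            checked += 1


class TestHarrellC:
    def test_hand_enumerated_example(self):
        r = harrell_c([4, 3, 1, 2], [1, 2, 3, 4], [1, 1, 1, 1])
        assert r.c_index == pytest.approx(5 / 6)
        assert r.comparable_pairs == 6

    def test_extremes(self):
        t = [1.0, 2, 3, 4]
        assert harrell_c([4, 3, 2, 1], t, [1, 1, 1, 1]).c_index == 1.0
        assert harrell_c([1, 2, 3, 4], t, [1, 1, 1, 1]).c_index == 0.0

    def test_censoring_example(self):
        r = harrell_c([3, 1, 2], [2, 4, 6], [1, 0, 1])
        assert r.comparable_pairs == 2
        assert r.c_index == 1.0

    def test_all_censored_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([1, 2, 3], [1, 2, 3], [0, 0, 0])

    def test_result_identity(self):
        rng = np.random.default_rng(8)
        s, t, e = random_survival_data(rng, 50, tie_scores=True, tie_times=True)
        r = harrell_c(s, t, e)
        assert r.c_index == (r.concordant + 0.5 * r.tied_score) / r.comparable_pairs

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_literal_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 61))
        s, t, e = random_survival_data(
            rng, n, tie_scores=bool(seed % 2), tie_times=bool(seed % 3)
        )
        oracle = naive_concordance(s, t, e)
        if oracle is None:
            with pytest.raises(ValueError):
                harrell_c(s, t, e)
            return
        r = harrell_c(s, t, e)
        c, comparable, concordant, tied = oracle
        assert (r.c_index, r.comparable_pairs, r.concordant, r.tied_score) == (
            c, comparable, concordant, tied)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_score_reversal_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        s, t, e = random_survival_data(rng, 40)
        if e.sum() == 0:
            return
        c = harrell_c(s, t, e).c_index
        assert harrell_c(-s, t, e).c_index == pytest.approx(1.0 - c)


class TestRCSBasis:
    SPEC = SplineSpec(knots=(1.0, 2.0, 3.5, 6.0), reference=3.0)

    def test_shape_and_tail_zero(self):
        x = np.linspace(-2, 10, 50)
        B = rcs_basis(x, self.SPEC)
        assert B.shape == (50, 3)
        # nonlinear columns vanish at and below the first knot
        below = x <= 1.0
        np.testing.assert_allclose(B[below, 1:], 0.0)
        np.testing.assert_allclose(B[below, 0], x[below])

    def test_linear_tails_second_derivative_zero(self):
        spec = self.SPEC
        rng = np.random.default_rng(4)
        coef = rng.normal(size=3)
        h = 1e-4
        for x0 in (0.2, 0.7, 6.5, 9.0):  # outside [knot1, knot4]
            pts = np.array([x0 - h, x0, x0 + h])
            f = rcs_basis(pts, spec) @ coef
            second = (f[0] - 2 * f[1] + f[2]) / h**2
            assert abs(second) < 1e-6

    def test_exact_representation_of_natural_cubic(self):
        """A function cubic between the knots and linear in the tails is
        reproduced exactly by least squares on the basis."""
        spec = self.SPEC
        t = np.array(spec.knots)
        rng = np.random.default_rng(6)
        w = rng.normal(size=2)  # target in the same natural-spline space

        def target(x):
            return 0.7 * x - 1.2 + rcs_basis(x, spec)[:, 1:] @ w

        x = np.linspace(0, 8, 400)
        B = np.column_stack([np.ones_like(x), rcs_basis(x, spec)])
        beta, *_ = np.linalg.lstsq(B, target(x), rcond=None)
        np.testing.assert_allclose(B @ beta, target(x), atol=1e-9)

    def test_duplicate_or_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineSpec(knots=(1.0, 2.0, 2.0, 4.0))
        with pytest.raises(ValueError):
            SplineSpec(knots=(4.0, 2.0, 3.0, 1.0))

    def test_default_knots_quantiles(self):
        x = np.linspace(0, 1, 1001)
        k = default_knots(x)
        np.testing.assert_allclose(k, (0.05, 0.35, 0.65, 0.95), atol=1e-9)


class TestPredictRisk:
    def test_zero_coefficients_equal_scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        t = rng.exponential(1, 30)
        fit = fit_cox(X, t, np.ones(30))
        fit.coefficients[:] = 0.0
        s = predict_risk(fit, X)
        assert np.ptp(s) == 0.0

    def test_monotone_in_positive_coefficient(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 2))
        lp = X[:, 0]
        T = rng.exponential(np.exp(-lp))
        fit = fit_cox(X, T, np.ones(100))
        assert fit.coefficients[0] > 0
        grid = np.column_stack([np.linspace(-2, 2, 9), np.zeros(9)])
        s = predict_risk(fit, grid)
        assert np.all(np.diff(s) > 0)

    def test_column_mismatch_raises(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        fit = fit_cox(X, rng.exponential(1, 30), np.ones(30))
        with pytest.raises(ValueError, match="match"):
            predict_risk(fit, X.rename(columns={"b": "z"}))


class TestPHDiagnostic:
    def _fit_sim(self, rng, n=150):
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-0.5 * x))
        C = rng.exponential(2.0, n)
        t = np.minimum(T, C)
        e = (T <= C).astype(int)
        return fit_cox(x, t, e), x, t, e

    def test_null_p_uniform(self):
        """Under exact proportional hazards the global p-value is
        uniform across repeated simulations (KS check)."""
        rng = np.random.default_rng(13)
        ps = []
        for _ in range(200):
            fit, x, t, e = self._fit_sim(rng)
            ps.append(ph_diagnostic(fit, x, t, e)["global"]["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_crossing_hazards_detected(self):
        """Strong non-proportionality (crossing hazards between groups)
        is flagged in at least 80% of seeds."""
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            n = 300
            x = (np.arange(n) % 2).astype(float)
            # group 0: constant hazard; group 1: strongly increasing hazard
            t = np.where(x == 0, rng.exponential(1.0, n), rng.weibull(4.0, n) * 1.2)
            fit = fit_cox(x, t, np.ones(n))
            p = ph_diagnostic(fit, x, t, np.ones(n))["global"]["p"]
            hits += p < 0.05
        assert hits >= 0.8 * n_seeds

    def test_single_event_declined(self):
        x = np.arange(6.0)
        t = np.arange(1.0, 7.0)
        e = np.array([1, 0, 0, 0, 0, 0])
        fit = fit_cox(x, t, e)
        with pytest.raises(ValueError, match="declined|fewer"):
            ph_diagnostic(fit, x, t, e)

    def test_matches_lifelines_km_transform(self):
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        rng = np.random.default_rng(3)
        fit, x, t, e = self._fit_sim(rng, n=250)
        ours = ph_diagnostic(fit, x, t, e)["global"]
        df = pd.DataFrame({"x": x, "t": t, "e": e})
        cph = CoxPHFitter().fit(df, "t", "e")
        theirs = proportional_hazard_test(cph, df, time_transform="km")
        assert ours["chi2"] == pytest.approx(theirs.summary["test_statistic"].iloc[0],
                                             rel=0.05)


def test_kaplan_meier_simple():
    t = np.array([1.0, 2, 3, 4])
    e = np.array([1, 0, 1, 1])
    times, surv = kaplan_meier(t, e)
    np.testing.assert_allclose(times, [1, 3, 4])
    np.testing.assert_allclose(surv, [0.75, 0.75 * 0.5, 0.0])
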