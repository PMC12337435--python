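import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from famcoag.liability import (
    APPROXIMATE,
    EXACT,
    RfComponent,
    bvn_upper,
    estimate_familial_correlation,
    liability_params,
    predicted_relative_prevalence,
    solve_rf,
)
from famcoag.prevalence import PrevalenceEstimate


class TestBivariateNormal:
    def test_closed_form_at_origin(self):
        # P(X>0, Y>0) = 1/4 + asin(r)/(2 pi)
        for r in [-0.999, -0.9, -0.5, 0.0, 0.3, 0.74, 0.76, 0.9, 0.93, 0.999]:
            assert bvn_upper(0.0, 0.0, r) == pytest.approx(
                0.25 + math.asin(r) / (2 * math.pi), abs=1e-13
            )

    def test_against_scipy_mvn(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            h, k = rng.uniform(-2.5, 2.5, 2)
            r = rng.uniform(-0.99, 0.99)
            # survival via inclusion-exclusion on the scipy CDF
            ref = (
                1.0
                - norm.cdf(h)
                - norm.cdf(k)
                + multivariate_normal([0, 0], [[1, r], [r, 1]]).cdf([h, k])
            )
            assert bvn_upper(h, k, r) == pytest.approx(ref, abs=5e-7)

    def test_against_adaptive_quadrature_in_tail_region(self):
        # points straddling the |r| = 0.925 algorithm switch
        for h, k, r in [(1.5, 2.0, 0.95), (-1.0, 2.5, -0.97), (0.7, 0.7, 0.924), (0.7, 0.7, 0.926)]:
            f = lambda x: norm.pdf(x) * norm.cdf((r * x - k) / math.sqrt(1 - r * r))
            ref, err = integrate.quad(f, h, np.inf, epsabs=1e-13, limit=200)
            assert bvn_upper(h, k, r) == pytest.approx(ref, abs=1e-10)

    def test_independence_factorizes(self):
        assert bvn_upper(0.5, -0.3, 0.0) == pytest.approx(norm.sf(0.5) * norm.sf(-0.3), abs=1e-14)

    def test_perfect_correlation_limit(self):
        t = norm.isf(0.2)
        assert bvn_upper(t, t, 0.99999) / 0.2 == pytest.approx(1.0, abs=1e-2)


class TestLiabilityParams:
    def test_half_prevalence(self):
        lp = liability_params(0.5)
        assert lp.t == pytest.approx(0.0, abs=1e-12)
        assert lp.i == pytest.approx(2 * norm.pdf(0.0))

    def test_ten_percent(self):
        lp = liability_params(0.1)
        assert lp.t == pytest.approx(1.2816, abs=1e-4)
        assert lp.i == pytest.approx(norm.pdf(1.281552) / 0.1, abs=1e-4)
        assert lp.i == pytest.approx(1.755, abs=1e-3)

    @pytest.mark.parametrize("K", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_prevalence_raises(self, K):
        with pytest.raises(ValueError):
            liability_params(K)

    def test_mean_liability_exceeds_threshold(self):
        for K in np.linspace(0.01, 0.99, 25):
            lp = liability_params(K)
            assert lp.i > lp.t


class TestPredictedPrevalence:
    def test_zero_rf_returns_population_prevalence(self):
        A, B = liability_params(0.1), liability_params(0.3)
        for mode in (EXACT, APPROXIMATE):
            assert predicted_relative_prevalence(A, B, 0.5, 0.0, mode) == pytest.approx(0.1, abs=1e-12)

    def test_reich_approximation_hand_computed(self):
        # K_A = K_B = 0.1, a_R = 0.5, r_f = 0.4: t* = (t - 0.2 i)/sqrt(1 - 0.04 i (i - t))
        A = liability_params(0.1)
        t, i = A.t, A.i
        t_star = (t - 0.2 * i) / math.sqrt(1 - 0.04 * i * (i - t))
        expected = norm.sf(t_star)
        got = predicted_relative_prevalence(A, A, 0.5, 0.4, APPROXIMATE)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.17, abs=5e-3)
        exact = predicted_relative_prevalence(A, A, 0.5, 0.4, EXACT)
        assert abs(exact - got) < 0.01

    def test_exact_mode_is_conditional_tail_probability(self):
        A, B = liability_params(0.08, ), liability_params(0.25)
        rho = 0.5 * 0.3
        ref = bvn_upper(A.t, B.t, rho) / B.K
        assert predicted_relative_prevalence(A, B, 0.5, 0.3, EXACT) == pytest.approx(ref, abs=1e-14)

    def test_invalid_a_R_raises(self):
        A = liability_params(0.1)
        with pytest.raises(ValueError, match="a_R"):
            predicted_relative_prevalence(A, A, 0.3, 0.2)

    @pytest.mark.parametrize("mode", [EXACT, APPROXIMATE])
    @pytest.mark.parametrize("a_R", [0.5, 0.25])
    def test_monotone_increasing_in_rf(self, mode, a_R):
        for KA in (0.05, 0.2, 0.4):
            for KB in (0.05, 0.4):
                A, B = liability_params(KA), liability_params(KB)
                grid = [predicted_relative_prevalence(A, B, a_R, r, mode) for r in np.linspace(-0.6, 0.6, 25)]
                assert np.all(np.diff(grid) > 0)

    def test_mode_agreement_on_grid(self):
        for KA in np.linspace(0.05, 0.4, 5):
            for KB in np.linspace(0.05, 0.4, 5):
                A, B = liability_params(KA), liability_params(KB)
                for a_R in (0.25, 0.5):
                    for r in np.linspace(-0.5, 0.5, 9):
                        d = abs(
                            predicted_relative_prevalence(A, B, a_R, r, EXACT)
                            - predicted_relative_prevalence(A, B, a_R, r, APPROXIMATE)
                        )
                        assert d <= 0.02

    def test_exact_mode_joint_probability_symmetric(self):
        A, B = liability_params(0.12), liability_params(0.33)
        for r in (-0.4, 0.2, 0.5):
            ab = predicted_relative_prevalence(A, B, 0.5, r, EXACT) * B.K
            ba = predicted_relative_prevalence(B, A, 0.5, r, EXACT) * A.K
            assert ab == pytest.approx(ba, abs=1e-14)

    def test_rf_lambda_coherence(self):
        A, B = liability_params(0.1), liability_params(0.15)
        for r in (0.1, 0.3, 0.5):
            assert predicted_relative_prevalence(A, B, 0.5, r, EXACT) / A.K > 1.0
        assert predicted_relative_prevalence(A, B, 0.5, -0.3, EXACT) / A.K < 1.0


class TestSolve:
    def test_zero_at_population_prevalence(self):
        A, B = liability_params(0.1), liability_params(0.3)
        assert solve_rf(0.1, A, B, 0.5) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", [EXACT, APPROXIMATE])
    @pytest.mark.parametrize("a_R", [0.5, 0.25])
    def test_round_trip(self, mode, a_R):
        A, B = liability_params(0.1), liability_params(0.15)
        for r_true in (-0.4, 0.1, 0.35):
            K_obs = predicted_relative_prevalence(A, B, a_R, r_true, mode)
            assert solve_rf(K_obs, A, B, a_R, mode) == pytest.approx(r_true, abs=1e-6)

    def test_out_of_range_raises(self):
        A, B = liability_params(0.05), liability_params(0.1)
        with pytest.raises(ValueError, match="attainable range"):
            solve_rf(0.9999, A, B, 0.5)


def component(K_obs, se, degree, direction, K_out=0.10, K_rel=0.15, n_infl=None, infl=None):
    est = PrevalenceEstimate(K_hat=K_obs, se=se, subset="exposed", n=500, influence=infl)
    return RfComponent(
        degree=degree,
        direction=direction,
        prevalence=est,
        outcome_params=liability_params(K_out),
        relative_params=liability_params(K_rel),
    )


class TestCombination:
    def make_components(self, r_true=0.3, se=0.004, jitter=(0.0, 0.0, 0.0, 0.0)):
        comps = []
        for (degree, a_R), direction, dj in zip(
            [("first", 0.5), ("first", 0.5), ("second", 0.25), ("second", 0.25)],
            ["A|B", "B|A", "A|B", "B|A"],
            jitter,
        ):
            K_out, K_rel = (0.10, 0.15) if direction == "A|B" else (0.15, 0.10)
            K_obs = predicted_relative_prevalence(
                liability_params(K_out), liability_params(K_rel), a_R, r_true, EXACT
            ) + dj
            comps.append(component(K_obs, se, degree, direction, K_out, K_rel))
        return comps

    def test_consistent_components_recover_truth(self):
        est = estimate_familial_correlation(self.make_components())
        assert est.rf == pytest.approx(0.3, abs=1e-6)
        assert est.p_one_sided < 1e-6
        assert est.lower95 <= est.rf

    def test_combined_within_component_hull(self):
        est = estimate_familial_correlation(self.make_components(jitter=(0.003, -0.002, 0.004, -0.003)))
        rfs = [c.rf for c in est.components]
        assert min(rfs) <= est.rf <= max(rfs)

    def test_second_degree_absent_reduces_to_first(self):
        full = self.make_components()
        first_only = [c for c in full if c.degree == "first"]
        a = estimate_familial_correlation(first_only)
        assert a.rf == pytest.approx(0.3, abs=1e-6)

    def test_unsolvable_components_dropped_with_warning(self):
        comps = self.make_components()
        comps[3].prevalence.K_hat = 0.9999  # far outside attainable range
        with pytest.warns(UserWarning, match="unsolvable|usable"):
            est = estimate_familial_correlation(comps)
        assert len(est.components) == 3

    def test_all_unsolvable_returns_none(self):
        comps = self.make_components()[:1]
        comps[0].prevalence.K_hat = 0.9999
        with pytest.warns(UserWarning):
            assert estimate_familial_correlation(comps) is None

    def test_influence_covariance_inflates_se_for_correlated_components(self):
        # two identical components sharing identical influence vectors are
        # perfectly correlated: the combined SE must equal a single SE, not
        # shrink by sqrt(2)
        rng = np.random.default_rng(0)
        infl = rng.normal(0, 0.001, 200)
        se = float(np.sqrt(np.sum(infl**2)))
        A, B = liability_params(0.10), liability_params(0.15)
        K_obs = predicted_relative_prevalence(A, B, 0.5, 0.3, EXACT)
        comps = [
            component(K_obs, se, "first", "A|B", infl=infl.copy()),
            component(K_obs, se, "first", "B|A", K_out=0.10, K_rel=0.15, infl=infl.copy()),
        ]
        est_corr = estimate_familial_correlation(comps)
        single = estimate_familial_correlation([component(K_obs, se, "first", "A|B", infl=infl.copy())])
        assert est_corr.se == pytest.approx(single.se, rel=1e-6)
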