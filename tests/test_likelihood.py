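"""Logistic curve, beta-binomial pmf, state mixtures, dataset log-likelihood."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import betaln, gammaln

from moltcurve import (
    AnimalState,
    CommunityParams,
    beta_binomial_pmf,
    dataset_loglik,
    linear_predictors,
    logistic_fraction,
    mixture_pmf,
)
from moltcurve.data_model import BinnedObservation
from moltcurve.likelihood import mixture_weights


def params(**over):
    base = dict(
        p=0.666, q=0.5, tau0=0.533, tauM=-0.012, tauK=0.017,
        tauY=-0.001, tauE=0.008, tauL=-0.001,
        alpha0=22.3, alphaM=1.3, alphaK=-0.8,
        alphaY=0.062, alphaE=0.158, alphaL=1.549,
        phi=0.264, sigma_tau=0.014, sigma_alpha=1.399,
        eta_tau=18.7, eta_alpha=16.8,
    )
    base.update(over)
    return CommunityParams(**base)


class TestLogisticFraction:
    def test_half_shed_at_tau(self):
        for alpha in (1.0, 22.3, 200.0):
            assert logistic_fraction(0.533, 0.533, alpha) == pytest.approx(0.5)

    def test_slope_at_tau_is_alpha_over_four(self):
        alpha, tau, h = 22.3, 0.533, 1e-6
        slope = (logistic_fraction(tau + h, tau, alpha)
                 - logistic_fraction(tau - h, tau, alpha)) / (2 * h)
        assert slope == pytest.approx(alpha / 4, rel=1e-6)

    def test_matches_high_precision_formula(self):
        # independent evaluation at extended precision
        from mpmath import mp, mpf, exp as mexp

        mp.dps = 50
        alpha, dt = mpf("22.3"), mpf("0.1")
        expected = float(mexp(alpha * dt) / (1 + mexp(alpha * dt)))
        assert logistic_fraction(0.6, 0.5, 22.3) == pytest.approx(expected, rel=1e-12)

    def test_overflow_safe(self):
        assert logistic_fraction(1.0, 0.0, 1e6) == 1.0
        assert logistic_fraction(0.0, 1.0, 1e6) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(
        t=st.floats(0, 1), tau=st.floats(0, 1),
        alpha=st.floats(-100, 100),
    )
    def test_point_symmetry_about_tau(self, t, tau, alpha):
        a = logistic_fraction(t, tau, alpha)
        b = logistic_fraction(2 * tau - t, tau, alpha)
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_for_positive_alpha(self):
        t = np.linspace(0.3, 0.8, 100)
        f = logistic_fraction(t, 0.533, 22.3)
        assert np.all(np.diff(f) > 0)


class TestLinearPredictors:
    def test_baseline_state_returns_intercepts(self):
        P = params()
        tau, alpha = linear_predictors(AnimalState.FN, 0, 0, 0, 0, P)
        assert (tau, alpha) == (P.tau0, P.alpha0)

    def test_male_and_kid_offsets(self):
        P = params()
        tau_m, alpha_m = linear_predictors(AnimalState.MN, 0, 0, 0, 0, P)
        assert tau_m == pytest.approx(P.tau0 + P.tauM)
        assert alpha_m == pytest.approx(P.alpha0 + P.alphaM)
        tau_k, alpha_k = linear_predictors(AnimalState.FY, 0, 0, 0, 0, P)
        assert tau_k == pytest.approx(P.tau0 + P.tauK)
        assert alpha_k == pytest.approx(P.alpha0 + P.alphaK)

    def test_covariates_and_year_effects_enter_linearly(self):
        P = params(tau_re=np.array([0.01]), alpha_re=np.array([0.5]))
        tau, alpha = linear_predictors(AnimalState.FN, 1.0, -2.0, 5.0, 0, P)
        assert tau == pytest.approx(P.tau0 + P.tauE - 2 * P.tauL + 5 * P.tauY + 0.01)
        assert alpha == pytest.approx(
            P.alpha0 + P.alphaE - 2 * P.alphaL + 5 * P.alphaY + 0.5
        )

    def test_ambiguous_state_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            linear_predictors(AnimalState.XX, 0, 0, 0, 0, params())

    def test_day_scale_state_shifts(self):
        # community medians: males shed 4.38 d earlier, kids delay by 6.20 d
        P = params(tauM=-4.38 / 365, tauK=6.20 / 365)
        tau_fn, _ = linear_predictors(AnimalState.FN, 0, 0, 0, 0, P)
        tau_mn, _ = linear_predictors(AnimalState.MN, 0, 0, 0, 0, P)
        tau_fy, _ = linear_predictors(AnimalState.FY, 0, 0, 0, 0, P)
        assert (tau_mn - tau_fn) * 365 == pytest.approx(-4.38)
        assert (tau_fy - tau_fn) * 365 == pytest.approx(6.20)


class TestBetaBinomial:
    def test_normalizes(self):
        total = sum(beta_binomial_pmf(n, 25, 0.3, 0.264) for n in range(26))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_binomial_limit_as_phi_vanishes(self):
        from scipy.stats import binom

        n = np.arange(26)
        bb = beta_binomial_pmf(n, 25, 0.3, 1e-8)
        np.testing.assert_allclose(bb, binom.pmf(n, 25, 0.3), atol=1e-6)

    def test_monte_carlo_variance_matches_inflation_factor(self, rng):
        # independent oracle: simulate the hierarchical draw directly
        N, f, phi, m = 25, 0.4, 0.264, 1_000_000
        pi = rng.beta(f / phi, (1 - f) / phi, size=m)
        n = rng.binomial(N, pi)
        v = 1 + (N - 1) * phi / (1 + phi)
        expected_var = N * f * (1 - f) * v
        # MC standard error of the sample variance
        se = np.std((n - n.mean()) ** 2) / np.sqrt(m)
        assert abs(n.var() - expected_var) < 4 * se
        assert n.mean() == pytest.approx(N * f, abs=4 * n.std() / np.sqrt(m))

    def test_mean_is_Nf_regardless_of_phi(self):
        n = np.arange(26)
        for phi in (0.05, 0.264, 2.0):
            pmf = beta_binomial_pmf(n, 25, 0.3, phi)
            assert float((n * pmf).sum()) == pytest.approx(25 * 0.3, rel=1e-9)

    def test_matches_direct_beta_function_evaluation(self):
        # brute-force pmf via the beta-function identity, independent coding
        N, f, phi = 25, 0.37, 0.264
        a, b = f / phi, (1 - f) / phi
        for n in (0, 7, 25):
            direct = np.exp(
                gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
                + betaln(n + a, N - n + b) - betaln(a, b)
            )
            assert beta_binomial_pmf(n, N, f, phi) == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 25, 0.3, 0.2), (26, 25, 0.3, 0.2), (5, 25, 0.3, -1.0)])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            beta_binomial_pmf(*bad)

    def test_extreme_f_clamped_not_nan(self):
        assert np.isfinite(beta_binomial_pmf(0, 25, 0.0, 0.264))
        assert np.isfinite(beta_binomial_pmf(25, 25, 1.0, 0.264))


class TestMixture:
    def test_unambiguous_pass_through(self):
        for state, expected in ((AnimalState.FN, 0.1), (AnimalState.FY, 0.2), (AnimalState.MN, 0.3)):
            assert mixture_pmf(state, 0.1, 0.2, 0.3, 0.666, 0.5) == expected

    def test_fx_collapses_when_q_zero(self):
        # q -> 0: every female is kidless
        assert mixture_pmf(AnimalState.FX, 0.1, 0.9, 0.3, 0.5, 1e-12) == pytest.approx(0.1)

    def test_xn_hand_worked_case(self):
        # (0.25*0.1 + 0.5*0.3) / (0.25 + 0.5)
        got = mixture_pmf(AnimalState.XN, 0.1, 0.7, 0.3, 0.5, 0.5)
        assert got == pytest.approx(0.23333333333, rel=1e-9)

    def test_xx_weights_sum_to_one(self):
        p, q = 0.666, 0.5
        w = mixture_weights(AnimalState.XX, p, q)
        assert sum(w.values()) == pytest.approx(1.0)
        assert w[AnimalState.FN] == pytest.approx(p * (1 - q))
        assert w[AnimalState.FY] == pytest.approx(p * q)
        assert w[AnimalState.MN] == pytest.approx(1 - p)

    def test_xn_contains_no_fy_component(self):
        w = mixture_weights(AnimalState.XN, 0.666, 0.5)
        assert AnimalState.FY not in w
        assert sum(w.values()) == pytest.approx(1.0)

    @settings(max_examples=60, deadline=None)
    @given(
        p=st.floats(0.05, 0.95), q=st.floats(0.05, 0.95),
        state=st.sampled_from(list(AnimalState)),
    )
    def test_mixture_pmf_normalizes_over_support(self, p, q, state):
        """Sum over n of the mixed pmf is exactly 1 for every state code."""
        N, phi = 25, 0.264
        taus = {"FN": 0.533, "FY": 0.55, "MN": 0.52}
        total = 0.0
        for n in range(N + 1):
            comp = {
                k: beta_binomial_pmf(n, N, logistic_fraction(0.5, taus[k], 22.3), phi)
                for k in taus
            }
            total += mixture_pmf(state, comp["FN"], comp["FY"], comp["MN"], p, q)
        assert total == pytest.approx(1.0, abs=1e-9)


def _naive_loglik(observations, P):
    """Independent reimplementation: direct beta-function pmf, explicit
    mixture arithmetic, no shared code with the fast path."""
    import math

    def bb(n, N, f, phi):
        f = min(max(f, 1e-9), 1 - 1e-9)
        a, b = f / phi, (1 - f) / phi
        return math.exp(
            math.lgamma(N + 1) - math.lgamma(n + 1) - math.lgamma(N - n + 1)
            + (math.lgamma(n + a) + math.lgamma(N - n + b) - math.lgamma(N + a + b))
            - (math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b))
        )

    total = 0.0
    for o in observations:
        comps = {}
        for s, (xm, xk) in (("FN", (0, 0)), ("FY", (0, 1)), ("MN", (1, 0))):
            tau = (P.tau0 + P.tauM * xm + P.tauK * xk + P.tauE * o.z_elevation
                   + P.tauL * o.z_latitude + P.tauY * o.year_centered
                   + P.tau_re[o.year_index])
            al = (P.alpha0 + P.alphaM * xm + P.alphaK * xk + P.alphaE * o.z_elevation
                  + P.alphaL * o.z_latitude + P.alphaY * o.year_centered
                  + P.alpha_re[o.year_index])
            f = 1 / (1 + math.exp(-al * (o.t - tau)))
            comps[s] = bb(o.n_shed, o.n_total, f, P.phi)
        p, q = P.p, P.q
        code = o.state.value
        if code in comps:
            pr = comps[code]
        elif code == "FX":
            pr = (1 - q) * comps["FN"] + q * comps["FY"]
        elif code == "XN":
            pr = (p * (1 - q) * comps["FN"] + (1 - p) * comps["MN"]) / (p * (1 - q) + 1 - p)
        else:
            pr = p * (1 - q) * comps["FN"] + p * q * comps["FY"] + (1 - p) * comps["MN"]
        total += math.log(pr)
    return total


class TestDatasetLoglik:
    @pytest.fixture
    def random_observations(self, rng):
        obs = []
        for _ in range(50):
            obs.append(
                BinnedObservation(
                    n_shed=int(rng.integers(0, 26)), n_total=25,
                    z_elevation=float(rng.normal()), z_latitude=float(rng.normal()),
                    year_centered=float(rng.integers(-10, 19)),
                    year_index=int(rng.integers(0, 3)),
                    state=list(AnimalState)[int(rng.integers(0, 6))],
                    t=float(rng.uniform(0.38, 0.72)),
                )
            )
        return obs

    def test_single_unambiguous_record_is_its_own_beta_binomial(self):
        P = params(tau_re=np.zeros(1), alpha_re=np.zeros(1))
        o = BinnedObservation(n_shed=12, n_total=25, z_elevation=0.0, z_latitude=0.0,
                              year_centered=0.0, year_index=0, state=AnimalState.FN, t=0.52)
        f = logistic_fraction(o.t, P.tau0, P.alpha0)
        expected = np.log(beta_binomial_pmf(12, 25, f, P.phi))
        assert dataset_loglik([o], P) == pytest.approx(expected, rel=1e-12)

    def test_additive_over_partition(self, random_observations):
        P = params(tau_re=np.zeros(3), alpha_re=np.zeros(3))
        whole = dataset_loglik(random_observations, P)
        parts = (dataset_loglik(random_observations[:20], P)
                 + dataset_loglik(random_observations[20:], P))
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_order_invariant(self, random_observations, rng):
        P = params(tau_re=np.zeros(3), alpha_re=np.zeros(3))
        shuffled = list(random_observations)
        rng.shuffle(shuffled)
        assert dataset_loglik(shuffled, P) == pytest.approx(
            dataset_loglik(random_observations, P), rel=1e-12
        )

    def test_matches_naive_reimplementation(self, random_observations, rng):
        P = params(
            tau_re=rng.normal(0, 0.01, 3), alpha_re=rng.normal(0, 1, 3),
        )
        fast = dataset_loglik(random_observations, P)
        naive = _naive_loglik(random_observations, P)
        assert fast == pytest.approx(naive, abs=1e-8)

    def test_vectorized_sampler_path_matches_reference(self, random_observations, rng):
        from moltcurve.likelihood import PackedData, community_loglik_batch

        P = params(tau_re=rng.normal(0, 0.01, 3), alpha_re=rng.normal(0, 1, 3))
        data = PackedData(random_observations)
        theta = {
            k: np.array([getattr(P, k)])
            for k in ("p", "q", "tau0", "tauM", "tauK", "tauY", "tauE", "tauL",
                      "alpha0", "alphaM", "alphaK", "alphaY", "alphaE", "alphaL", "phi")
        }
        theta["tau_re"] = P.tau_re[None, :]
        theta["alpha_re"] = P.alpha_re[None, :]
        batched = community_loglik_batch(data, theta)[0]
        assert batched == pytest.approx(dataset_loglik(random_observations, P), abs=1e-8)


class TestParamValidation:
    @pytest.mark.parametrize(
        "over", [{"p": 0.0}, {"q": 1.0}, {"phi": -0.1}, {"sigma_tau": 0.0}, {"eta_alpha": -2}]
    )
    def test_community_params_rejects_out_of_domain(self, over):
        with pytest.raises(ValueError):
            params(**over)
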