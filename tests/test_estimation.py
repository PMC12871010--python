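"""Pseudo-EM estimation: ECDF, pseudo-data, E/M steps, fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from nestedidr import (
    FitControls,
    ModelParams,
    ScoreMatrix,
    StudyDesign,
    e_step,
    fit,
    log_likelihood,
    m_step,
    make_pseudo_data,
    scaled_ecdf,
)
from nestedidr.estimation import (
    PseudoDataTransformer,
    _equicorrelated_weighted_mle,
    default_initializations,
)
from nestedidr.model import inverse_marginal_cdf
from nestedidr.simulate import scenario_preset, simulate_dataset

from conftest import random_params
from test_model import equicorr_cov


class TestScoreMatrix:
    def test_validates_shape_and_content(self, design22):
        rng = np.random.default_rng(0)
        x = ScoreMatrix(rng.standard_normal((10, 4)), design22)
        assert x.n == 10 and len(x.candidate_ids) == 10
        with pytest.raises(ValueError):
            ScoreMatrix(rng.standard_normal((10, 3)), design22)
        with pytest.raises(ValueError):
            ScoreMatrix(rng.standard_normal((4, 4)), design22)  # n < P + 2
        bad = rng.standard_normal((10, 4))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError):
            ScoreMatrix(bad, design22)

    def test_rejects_degenerate_column(self, design22):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 4))
        x[:, 2] = np.repeat([1.0, 2.0], 5)  # only two distinct values
        with pytest.raises(ValueError):
            ScoreMatrix(x, design22)


class TestScaledECDF:
    def test_hand_examples(self):
        # ranks of (3,1,2) are (3,1,2); divide by n+1=4
        np.testing.assert_allclose(scaled_ecdf([3.0, 1.0, 2.0]), [0.75, 0.25, 0.5])
        # mid-ranks for the tie: ranks (1.5, 1.5, 3) / 4
        np.testing.assert_allclose(scaled_ecdf([1.0, 1.0, 2.0]), [0.375, 0.375, 0.75])

    def test_open_unit_interval(self):
        rng = np.random.default_rng(2)
        u = scaled_ecdf(rng.standard_normal(500))
        assert np.all((u > 0) & (u < 1))

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(scaled_ecdf(x), scaled_ecdf(np.exp(x)))

    def test_rejects_constant(self):
        with pytest.raises(ValueError):
            scaled_ecdf(np.ones(10))
        with pytest.raises(ValueError):
            scaled_ecdf(np.array([1.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 60))
    def test_mean_is_half(self, seed, n):
        # ranks always sum to n(n+1)/2, so the scaled ECDF always averages 1/2
        x = np.random.default_rng(seed).standard_normal(n)
        assert scaled_ecdf(x).mean() == pytest.approx(0.5, rel=1e-12)


class TestPseudoData:
    def test_matches_componentwise_inverse(self, params22, design22):
        rng = np.random.default_rng(4)
        x = ScoreMatrix(rng.standard_normal((40, 4)), design22)
        z = make_pseudo_data(x, params22)
        for j in range(4):
            u = scaled_ecdf(x.x[:, j])
            want = inverse_marginal_cdf(u, params22, design22.lab_of_column(j))
            np.testing.assert_allclose(z[:, j], want, atol=1e-7)

    def test_transformer_warm_start_consistency(self, params22, design22):
        rng = np.random.default_rng(5)
        x = ScoreMatrix(rng.standard_normal((60, 4)), design22)
        tr = PseudoDataTransformer(x)
        z1 = tr.transform(params22)
        z2 = tr.transform(params22)  # warm-started second call, same params
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    def test_log_jacobian_matches_direct_sum(self, params22, design22):
        from nestedidr.model import marginal_mixture_pdf

        rng = np.random.default_rng(6)
        x = ScoreMatrix(rng.standard_normal((30, 4)), design22)
        tr = PseudoDataTransformer(x)
        z = tr.transform(params22)
        want = sum(
            float(np.log(marginal_mixture_pdf(z[:, sl], params22, l)).sum())
            for l, sl in enumerate(design22.lab_slices)
        )
        assert tr.log_jacobian(params22) == pytest.approx(want, rel=1e-10)


def brute_force_estep(z, params, design):
    """Posterior responsibilities by explicit Bayes on each candidate."""
    n = z.shape[0]
    gamma = np.zeros(n)
    tau1 = np.zeros((n, design.L))
    for i in range(n):
        noise = params.pi0
        signal = params.pi1
        for l, sl in enumerate(design.lab_slices):
            m = design.M[l]
            zi = z[i, sl]
            h00 = stats.multivariate_normal(np.zeros(m), np.eye(m)).pdf(zi)
            h01 = stats.multivariate_normal(np.full(m, params.mu01[l]), np.eye(m)).pdf(zi)
            h11 = stats.multivariate_normal(
                np.full(m, params.mu11[l]),
                equicorr_cov(m, params.sigma11[l], params.rho11[l]),
            ).pdf(zi)
            a = (1 - params.pi11[l]) * h01
            b = params.pi11[l] * h11
            tau1[i, l] = b / (a + b)
            noise *= h00
            signal *= a + b
        gamma[i] = signal / (noise + signal)
    return gamma, tau1


class TestESTep:
    @pytest.mark.parametrize("M,seed", [((2, 2), 7), ((3, 1), 8), ((2, 2, 2), 9)])
    def test_matches_brute_force_bayes(self, M, seed):
        design = StudyDesign(M=M)
        rng = np.random.default_rng(seed)
        params = random_params(rng, design.L)
        z = rng.standard_normal((10, design.P)) * 1.5 + 1.0
        gamma, tau1, ll = e_step(z, params, design)
        g_want, t_want = brute_force_estep(z, params, design)
        np.testing.assert_allclose(gamma, g_want, rtol=1e-10)
        np.testing.assert_allclose(tau1, t_want, rtol=1e-10)
        assert ll == pytest.approx(log_likelihood(z, params, design), rel=1e-12)

    def test_posteriors_in_unit_interval(self, params22, design22):
        rng = np.random.default_rng(10)
        z = rng.standard_normal((200, 4)) * 3
        gamma, tau1, _ = e_step(z, params22, design22)
        assert np.all((gamma >= 0) & (gamma <= 1))
        assert np.all((tau1 >= 0) & (tau1 <= 1))


class TestMStep:
    def test_weighted_mle_equals_sample_moments_equal_weights(self):
        # spec-level oracle: with equal weights and one equicorrelated
        # component (mu=2, sigma=1, rho=0.8, M=2, n=20000) the weighted MLE
        # must land within 3 Monte-Carlo SEs of the sample-moment values
        rng = np.random.default_rng(11)
        n, m, mu, sigma, rho = 20000, 2, 2.0, 1.0, 0.8
        block = stats.multivariate_normal(
            np.full(m, mu), equicorr_cov(m, sigma, rho)
        ).rvs(n, random_state=rng)
        w = np.ones(n)
        mu_hat, s2_hat, rho_hat = _equicorrelated_weighted_mle(block, w)
        # independent sample-moment oracle on the same draw
        assert mu_hat == pytest.approx(block.mean(), rel=1e-12)
        zbar = block.mean(axis=1)
        a = (m * (zbar - block.mean()) ** 2).mean()
        b = (((block - zbar[:, None]) ** 2).sum(axis=1) / (m - 1)).mean()
        assert s2_hat == pytest.approx((a + (m - 1) * b) / m, rel=1e-10)
        assert rho_hat == pytest.approx(1 - b / s2_hat, rel=1e-10)
        # and the estimates must be near the generator truth
        se_mu = sigma * np.sqrt((1 + (m - 1) * rho) / (n * m))
        assert abs(mu_hat - mu) < 3 * se_mu
        assert abs(np.sqrt(s2_hat) - sigma) < 0.03
        assert abs(rho_hat - rho) < 0.03

    def test_full_m_step_recovers_mixture_weights(self, design22):
        # hard-assign responsibilities: the M-step must reproduce each
        # component's sample statistics exactly
        rng = np.random.default_rng(12)
        n = 4000
        params = ModelParams(
            pi1=0.5,
            pi11=np.array([0.5, 0.5]),
            mu01=np.array([1.0, 1.0]),
            mu11=np.array([3.0, 3.0]),
            sigma11=np.array([1.0, 1.0]),
            rho11=np.array([0.8, 0.8]),
        )
        z = rng.standard_normal((n, 4))
        gamma = rng.uniform(size=n).round()  # hard 0/1 labels
        tau1 = rng.uniform(size=(n, 2)).round()
        new = m_step(z, (gamma, tau1), design22, params)
        assert new.pi1 == pytest.approx(gamma.mean(), rel=1e-10)
        for l in (0, 1):
            w1 = gamma * tau1[:, l]
            assert new.pi11[l] == pytest.approx(w1.sum() / gamma.sum(), rel=1e-10)

    def test_projection_keeps_constraints(self, params22, design22):
        rng = np.random.default_rng(13)
        z = rng.standard_normal((100, 4)) * 0.1  # pushes means towards 0
        gamma = np.full(100, 0.5)
        tau1 = np.full((100, 2), 0.5)
        new = m_step(z, (gamma, tau1), design22, params22)
        assert np.all(new.mu01 > 0)
        assert np.all(new.mu11 > new.mu01)
        assert np.all((new.rho11 > 0) & (new.rho11 < 1))
        assert np.all(new.sigma11 > 0)

    def test_starved_component_warns_and_keeps_previous(self, params22, design22):
        rng = np.random.default_rng(14)
        z = rng.standard_normal((50, 4))
        gamma = np.full(50, 1e-9)  # essentially no signal mass
        tau1 = np.full((50, 2), 0.5)
        with pytest.warns(UserWarning, match="starved"):
            new = m_step(z, (gamma, tau1), design22, params22)
        np.testing.assert_allclose(new.mu11, params22.mu11)


class TestInnerEMMonotonicity:
    def test_likelihood_nondecreasing_on_fixed_pseudo_data(self, design22):
        """Classic EM guarantee: with the pseudo-data held fixed, each
        E+M cycle cannot decrease the observed log-likelihood (up to the
        tiny constraint projection, which this data does not trigger)."""
        cfg = scenario_preset("S1", n=800, seed=21)
        x, _ = simulate_dataset(cfg)
        z = make_pseudo_data(x, cfg.params)
        theta = random_params(np.random.default_rng(22), 2)
        prev = -np.inf
        for _ in range(25):
            gamma, tau1, ll = e_step(z, theta, x.design)
            assert ll >= prev - 1e-8
            prev = ll
            theta = m_step(z, (gamma, tau1), x.design, theta)


class TestFit:
    def test_deterministic(self):
        cfg = scenario_preset("S1", n=600, seed=31)
        x, _ = simulate_dataset(cfg)
        r1 = fit(x)
        r2 = fit(x)
        np.testing.assert_array_equal(r1.params.as_vector(), r2.params.as_vector())
        assert r1.best_loglik == r2.best_loglik

    def test_rank_invariance(self):
        """Monotone per-column transforms leave the fit untouched: only
        ranks enter the pipeline."""
        cfg = scenario_preset("S2", n=600, seed=32)
        x, _ = simulate_dataset(cfg)
        r1 = fit(x)
        y = x.x.copy()
        y[:, 0] = np.exp(y[:, 0] / 2)
        y[:, 1] = y[:, 1] ** 3
        y[:, 2] = 1 / (1 + np.exp(-y[:, 2]))
        y[:, 3] = stats.rankdata(y[:, 3])
        r2 = fit(ScoreMatrix(y, x.design))
        np.testing.assert_allclose(
            r1.params.as_vector(), r2.params.as_vector(), atol=1e-10
        )

    def test_single_start_and_trace(self):
        cfg = scenario_preset("S1", n=500, seed=33)
        x, _ = simulate_dataset(cfg)
        init = default_initializations(x)[1][1]
        res = fit(x, init=init, controls=FitControls(max_outer=40, polish=False))
        assert res.loglik_trace.shape[0] == res.n_outer_iters
        assert res.best_loglik == pytest.approx(res.loglik_trace.max())
        # the polish step may only improve on the best EM iterate
        res_p = fit(x, init=init, controls=FitControls(max_outer=40))
        assert res_p.best_loglik >= res.best_loglik

    def test_multi_start_reports_all(self):
        cfg = scenario_preset("S1", n=500, seed=34)
        x, _ = simulate_dataset(cfg)
        res = fit(x, controls=FitControls(max_outer=60))
        assert len(res.all_starts) == 4
        assert res.best_loglik >= max(s["best_loglik"] for s in res.all_starts)

    def test_fast_and_reference_paths_agree(self):
        """The numba fast path must reproduce the NumPy reference path."""
        from nestedidr import _fast

        if not _fast.HAVE_NUMBA:
            pytest.skip("numba unavailable; only the reference path exists")
        cfg = scenario_preset("S1", n=400, seed=35)
        x, _ = simulate_dataset(cfg)
        # polish disabled: its simplex search would amplify the ~1e-13
        # kernel differences through iteration-count branch points
        r_fast = fit(x, controls=FitControls(max_outer=50, polish=False))
        orig = _fast.HAVE_NUMBA
        try:
            _fast.HAVE_NUMBA = False
            r_ref = fit(x, controls=FitControls(max_outer=50, polish=False))
        finally:
            _fast.HAVE_NUMBA = orig
        np.testing.assert_allclose(
            r_fast.params.as_vector(), r_ref.params.as_vector(), atol=1e-8
        )
        assert r_fast.best_loglik == pytest.approx(r_ref.best_loglik, abs=1e-6)


class TestTwoComponentReduction:
    def test_l1_frozen_pi11_matches_standard_idr(self):
        """With one lab and pi11 frozen at 1 - eps the nested model collapses
        to the two-component standard IDR model; fitting both from matched
        starts must agree to 1e-3 in the shared parameters."""
        from nestedidr.baselines import TwoComponentParams, standard_idr

        cfg = scenario_preset("S1", n=2000, seed=41)
        full, _ = simulate_dataset(cfg)
        design = StudyDesign(M=(2,))
        x = ScoreMatrix(full.x[:, :2], design)
        eps = 1e-8
        init = ModelParams(
            pi1=0.3,
            pi11=np.array([1 - eps]),
            mu01=np.array([1.0]),
            mu11=np.array([2.6]),
            sigma11=np.array([1.3]),
            rho11=np.array([0.8]),
        )
        nested = fit(x, init=init, controls=FitControls(freeze_pi11=1 - eps))
        two = standard_idr(x, inits=[TwoComponentParams(0.3, 2.6, 1.3, 0.8)])
        assert nested.params.pi1 == pytest.approx(two.params.pi1, abs=1e-3)
        assert nested.params.mu11[0] == pytest.approx(two.params.mu, abs=1e-3)
        assert nested.params.sigma11[0] == pytest.approx(two.params.sigma, abs=1e-3)
        assert nested.params.rho11[0] == pytest.approx(two.params.rho, abs=1e-3)
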