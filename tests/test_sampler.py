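import numpy as np
import pandas as pd
import pytest

from mlirt.grm import loglik
from mlirt.sampler import (ChainStore, GibbsSampler, MCMCConfig, compute_dic,
                           geweke_diagnostic, hpd_interval, rescale_identify,
                           run_mcmc, summarize)


def brute_force_hpd(draws, prob):
    """Independent oracle: scan every window of ceil(prob*n) sorted draws."""
    x = np.sort(draws)
    n = len(x)
    m = int(np.ceil(prob * n))
    best = (np.inf, None)
    for j in range(n - m + 1):
        w = x[j + m - 1] - x[j]
        if w < best[0]:
            best = (w, (x[j], x[j + m - 1]))
    return best[1]


class TestHPD:
    def test_matches_bruteforce_on_integers(self):
        draws = np.arange(1, 101, dtype=float)
        assert hpd_interval(draws, 0.95) == brute_force_hpd(draws, 0.95)
        lo, hi = hpd_interval(draws, 0.95)
        assert hi - lo == 94.0

    def test_matches_bruteforce_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            draws = rng.gamma(2.0, 1.0, size=100)
            assert hpd_interval(draws, 0.9) == brute_force_hpd(draws, 0.9)

    def test_symmetric_sample_close_to_equal_tails(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(100_000)
        lo, hi = hpd_interval(draws, 0.95)
        qlo, qhi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(qlo, abs=0.02)
        assert hi == pytest.approx(qhi, abs=0.02)

    def test_prob_one_is_range(self):
        draws = np.linspace(-3, 7, 500)
        assert hpd_interval(draws, 1.0) == (-3.0, 7.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(50), 0.95)

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        draws = rng.beta(2, 5, size=5000)
        lo, hi = hpd_interval(draws, 0.94)
        ref = az.hdi(draws, hdi_prob=0.94)
        assert lo == pytest.approx(ref[0], abs=0.01)
        assert hi == pytest.approx(ref[1], abs=0.01)


class TestGeweke:
    def test_iid_chain_rarely_flagged(self):
        rng = np.random.default_rng(3)
        zs = [geweke_diagnostic(rng.standard_normal(10_000))["z"].iloc[0]
              for _ in range(50)]
        assert np.mean(np.abs(zs) < 3) >= 0.98

    def test_trend_flagged(self):
        rng = np.random.default_rng(4)
        chain = np.linspace(0, 5, 2000) + rng.standard_normal(2000) * 0.5
        out = geweke_diagnostic(chain)
        assert out["flag"].iloc[0] == "nonstationary"

    def test_constant_chain_degenerate(self):
        out = geweke_diagnostic(np.full(500, 2.5))
        assert out["flag"].iloc[0] == "degenerate"
        assert np.isnan(out["z"].iloc[0])

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(100))


class TestRescaleIdentify:
    def _state(self, seed=5):
        rng = np.random.default_rng(seed)
        return {"theta": rng.normal(1.5, 2.0, 60),
                "a": rng.uniform(0.5, 2.5, 4),
                "kappa": np.sort(rng.normal(0, 1, (4, 2)), axis=1),
                "beta0": 0.3, "beta": rng.normal(0, 0.5, 3),
                "u": rng.normal(0, 0.3, 10), "sigma2": 0.8, "tau2": 0.2}

    def test_standardizes_exactly(self):
        out = rescale_identify(self._state())
        assert out["theta"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["theta"].std() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        once = rescale_identify(self._state())
        twice = rescale_identify(once)
        for key in ("theta", "a", "kappa", "beta", "u"):
            np.testing.assert_allclose(twice[key], once[key], atol=1e-12)

    def test_zero_variance_rejected(self):
        state = self._state()
        state["theta"] = np.zeros(60)
        with pytest.raises(ZeroDivisionError):
            rescale_identify(state)


def small_sampler(n=400, K=5, seed=0, icc=0.3, beta=(0.0, 0.6), cluster=2.0):
    """Build a GibbsSampler on freshly generated GRM data, returning truth."""
    rng = np.random.default_rng(seed)
    J = int(n / cluster)
    codes = rng.integers(0, J, n)
    x = rng.standard_normal(n)
    u = rng.normal(0, np.sqrt(icc), J)
    theta = beta[0] + beta[1] * x + u[codes] + \
        rng.normal(0, np.sqrt(1 - icc), n)
    theta = (theta - theta.mean()) / theta.std()
    a = rng.uniform(0.8, 2.5, K)
    kappa = np.sort(rng.normal(0, 0.8, (K, 2)), axis=1)
    from mlirt.grm import category_probs
    values = np.empty((n, K), int)
    for k in range(K):
        p = category_probs(a[k], kappa[k], theta, "probit")
        values[:, k] = (rng.random(n)[:, None] > p.cumsum(1)[:, :-1]).sum(1)
    X = np.column_stack([np.ones(n), x])
    cfg = MCMCConfig(n_iterations=400, burn_in=100, seed=seed)
    smp = GibbsSampler(values, np.zeros((n, K), bool), X, codes, cfg,
                       beta_names=["intercept", "x"])
    return smp, dict(theta=theta, a=a, kappa=kappa, beta=np.asarray(beta),
                     values=values)


class TestGibbsSteps:
    def test_measurement_recovery_with_clamped_theta(self):
        """With abilities clamped at truth, repeated measurement steps
        recover the discriminations."""
        smp, truth = small_sampler(n=3000, K=3, seed=6)
        smp.theta = truth["theta"].copy()
        draws = []
        for it in range(600):
            smp.step_measurement()
            if it >= 200:
                draws.append(smp.a.copy())
        a_hat = np.mean(draws, axis=0)
        np.testing.assert_allclose(a_hat, truth["a"], atol=0.1)

    def test_thresholds_ordered_every_iteration(self):
        smp, _ = small_sampler(n=200, K=4, seed=7)
        for _ in range(100):
            smp.step_measurement()
            assert (np.diff(smp.t, axis=1) > 0).all()

    def test_degenerate_single_category_item_no_crash(self):
        values = np.zeros((80, 2), int)
        values[:, 1] = np.tile([0, 1, 2, 1], 20)
        cfg = MCMCConfig(n_iterations=200, burn_in=50, seed=8)
        smp = GibbsSampler(values, np.zeros((80, 2), bool),
                           np.ones((80, 1)), np.arange(80), cfg)
        for _ in range(50):
            smp.step_measurement()
            smp.step_ability()
        assert np.isfinite(smp.a).all()

    def test_ability_full_conditional_matches_closed_form(self):
        """The ability draw must match the precision-weighted normal that
        combines measurement and structural information."""
        smp, truth = small_sampler(n=50, K=4, seed=9)
        smp._augment_z()
        mu_struct = smp.X @ smp.beta + smp.u[smp.codes]
        a_cell = smp.a[smp.cell_item]
        prec = np.bincount(smp.cell_person, a_cell**2, smp.n) + 1 / smp.sigma2
        mean = (np.bincount(smp.cell_person, a_cell * smp.Z, smp.n)
                + mu_struct / smp.sigma2) / prec
        draws = []
        z_fixed = smp.Z.copy()
        for _ in range(4000):
            smp.Z = z_fixed
            smp.step_ability()
            draws.append(smp.theta.copy())
        draws = np.array(draws)
        np.testing.assert_allclose(draws.mean(0), mean, atol=0.06)
        np.testing.assert_allclose(draws.std(0), 1 / np.sqrt(prec), atol=0.05)

    def test_person_with_no_items_draws_from_structural_prior(self):
        values = np.array([[1, 2], [-1, -1]])
        mask = np.array([[False, False], [True, True]])
        cfg = MCMCConfig(n_iterations=200, burn_in=50, seed=10)
        smp = GibbsSampler(values, mask, np.ones((2, 1)), np.array([0, 1]), cfg)
        smp.beta = np.array([0.7])
        smp.u = np.zeros(2)
        smp.sigma2 = 0.25
        smp._augment_z()
        draws = [smp.step_ability() or smp.theta[1] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.7, abs=0.05)
        assert np.std(draws) == pytest.approx(0.5, abs=0.05)

    def test_structural_step_matches_regression_oracle(self):
        """With theta clamped at truth, the structural step recovers the
        generating coefficients within posterior uncertainty."""
        smp, truth = small_sampler(n=5000, K=3, seed=11,
                                   beta=(0.9, -0.17), icc=0.1)
        smp.theta = truth["theta"].copy()
        draws = []
        for it in range(500):
            smp.step_structural()
            if it >= 100:
                draws.append(smp.beta.copy())
        draws = np.array(draws)
        # independent oracle: OLS of theta on X (random effects are small)
        ols = np.linalg.lstsq(smp.X, truth["theta"], rcond=None)[0]
        np.testing.assert_allclose(draws.mean(0), ols, atol=0.05)
        sd = draws.std(0)
        assert (np.abs(draws.mean(0) - ols) < 4 * sd + 0.02).all()

    def test_tau2_always_nonnegative(self):
        smp, _ = small_sampler(n=300, seed=12)
        for _ in range(100):
            smp.step_structural()
            assert smp.tau2 > 0 and smp.sigma2 > 0

    def test_rank_deficient_design_rejected(self):
        values = np.ones((10, 2), int)
        X = np.ones((10, 2))   # duplicated intercept
        with pytest.raises(ValueError, match="rank"):
            GibbsSampler(values, np.zeros((10, 2), bool), X,
                         np.arange(10), MCMCConfig(seed=0, n_iterations=10,
                                                   burn_in=5))


class TestRunMCMC:
    def test_identification_invariant_every_stored_draw(self):
        smp, _ = small_sampler(n=300, K=4, seed=13)
        cfg = MCMCConfig(n_iterations=300, burn_in=100, seed=13,
                         store_theta_trace=True)
        chains = run_mcmc(smp.values, smp.mask, smp.X, smp.codes, cfg)
        means = chains.theta_trace.mean(axis=1)
        sds = chains.theta_trace.std(axis=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-10)
        np.testing.assert_allclose(sds, 1.0, atol=1e-10)

    def test_rescale_preserves_likelihood_inside_fit(self):
        smp, _ = small_sampler(n=200, K=3, seed=14)
        for _ in range(20):
            smp.step_measurement()
            smp.step_ability()
            smp.step_structural()
            before = loglik(smp.values, smp.mask, smp.a, smp.kappa(),
                            smp.theta, "probit")
            smp.rescale()
            after = loglik(smp.values, smp.mask, smp.a, smp.kappa(),
                           smp.theta, "probit")
            assert after == pytest.approx(before, abs=1e-8)

    def test_seed_determinism_bitwise(self):
        smp, _ = small_sampler(n=150, K=3, seed=15)
        cfg = MCMCConfig(n_iterations=150, burn_in=50, seed=42)
        c1 = run_mcmc(smp.values, smp.mask, smp.X, smp.codes, cfg)
        c2 = run_mcmc(smp.values, smp.mask, smp.X, smp.codes, cfg)
        np.testing.assert_array_equal(c1.a, c2.a)
        np.testing.assert_array_equal(c1.beta, c2.beta)
        np.testing.assert_array_equal(c1.deviance, c2.deviance)

    def test_identical_persons_exchangeable(self):
        """Two persons with identical data and covariates in one dwelling get
        equal posterior mean abilities within Monte Carlo error."""
        rng = np.random.default_rng(16)
        base = rng.integers(0, 3, (100, 4))
        values = np.vstack([base, base[:1], base[:1]])   # persons 100, 101 identical
        n = values.shape[0]
        codes = np.arange(n)
        codes[-1] = codes[-2]   # same dwelling
        cfg = MCMCConfig(n_iterations=2000, burn_in=500, seed=16)
        chains = run_mcmc(values, np.zeros_like(values, bool),
                          np.ones((n, 1)), codes, cfg)
        assert chains.theta_mean[-1] == pytest.approx(chains.theta_mean[-2],
                                                      abs=0.15)

    def test_logit_link_runs_and_recovers_roughly(self):
        smp, truth = small_sampler(n=800, K=6, seed=17)
        # regenerate responses under the logit link with a wide, known
        # spread of discriminations for a meaningful recovery check
        rng = np.random.default_rng(18)
        a_true = np.linspace(0.8, 2.6, 6)
        kappa = np.tile([-0.8, 0.8], (6, 1))
        from mlirt.grm import category_probs
        values = np.empty((800, 6), int)
        for k in range(6):
            p = category_probs(a_true[k], kappa[k], truth["theta"], "logit")
            values[:, k] = (rng.random(800)[:, None] >
                            p.cumsum(1)[:, :-1]).sum(1)
        cfg = MCMCConfig(n_iterations=1200, burn_in=400, seed=18, link="logit")
        chains = run_mcmc(values, np.zeros_like(values, bool), smp.X,
                          smp.codes, cfg)
        a_hat = chains.a.mean(0)
        assert np.corrcoef(a_hat, a_true)[0, 1] > 0.8
        assert np.abs(a_hat - a_true).mean() < 0.4


class TestDICAndSummaries:
    def _toy_chains(self, deviance, a=None, n_draws=None):
        deviance = np.asarray(deviance, float)
        S = len(deviance)
        K = 2
        return ChainStore(
            a=np.tile([1.0, 2.0], (S, 1)) if a is None else a,
            kappa=np.tile([[-1.0, 1.0], [0.0, 1.0]], (S, 1, 1)),
            beta=np.zeros((S, 1)), sigma2=np.ones(S), tau2=np.ones(S),
            deviance=deviance, theta_mean=np.zeros(3),
            beta_names=["intercept"], item_ids=["i0", "i1"],
            config=MCMCConfig(seed=0, n_iterations=10, burn_in=5))

    def test_dic_formula_on_toy_chain(self):
        values = np.array([[0, 1], [1, 2], [2, 0]])
        mask = np.zeros((3, 2), bool)
        chains = self._toy_chains([10.0, 12.0, 11.0, 9.0, 13.0])
        dic, p_d, dbar = compute_dic(chains, values, mask)
        # independent arithmetic: Dbar = 11, Dhat from the posterior means
        d_hat = -2 * loglik(values, mask, np.array([1.0, 2.0]),
                            np.array([[-1.0, 1.0], [0.0, 1.0]]),
                            np.zeros(3), "probit")
        assert dbar == pytest.approx(11.0)
        assert p_d == pytest.approx(11.0 - d_hat)
        assert dic == pytest.approx(11.0 + (11.0 - d_hat))

    def test_duplicating_data_doubles_mean_deviance(self):
        """Conditional deviance is a sum over cells, so duplicating every
        person's data doubles it."""
        values = np.array([[0, 1], [1, 2]])
        mask = np.zeros((2, 2), bool)
        a = np.array([1.0, 2.0])
        kappa = np.array([[-1.0, 1.0], [0.0, 1.0]])
        theta = np.array([0.3, -0.4])
        d1 = -2 * loglik(values, mask, a, kappa, theta)
        d2 = -2 * loglik(np.vstack([values, values]),
                         np.vstack([mask, mask]), a, kappa,
                         np.concatenate([theta, theta]))
        assert d2 == pytest.approx(2 * d1, abs=1e-10)

    def test_negative_pd_warns(self):
        values = np.array([[0, 0], [0, 0], [0, 0]])
        mask = np.zeros((3, 2), bool)
        chains = self._toy_chains([0.1, 0.1, 0.1])
        with pytest.warns(RuntimeWarning):
            compute_dic(chains, values, mask)

    def test_summarize_constant_chain(self):
        S = 200
        chains = self._toy_chains(np.full(S, 5.0))
        chains.beta = np.full((S, 1), 3.25)
        out = summarize(chains, include_items=False)
        row = out.loc["intercept"]
        assert row["mean"] == 3.25 and row["sd"] == 0.0
        assert (row["hpd_lower"], row["hpd_upper"]) == (3.25, 3.25)

    def test_summarize_matches_independent_recomputation(self):
        rng = np.random.default_rng(19)
        S = 1000
        chains = self._toy_chains(rng.random(S))
        chains.beta = rng.standard_normal((S, 1)) * 2 + 1
        out = summarize(chains, include_items=False)
        col = chains.beta[:, 0]
        assert out.loc["intercept", "mean"] == pytest.approx(col.mean())
        assert out.loc["intercept", "sd"] == pytest.approx(col.std(ddof=1))
        lo, hi = brute_force_hpd(col, 0.95)
        assert out.loc["intercept", "hpd_lower"] == pytest.approx(lo)
        assert out.loc["intercept", "hpd_upper"] == pytest.approx(hi)

    def test_summary_row_order_follows_declaration(self):
        S = 120
        chains = self._toy_chains(np.ones(S))
        chains.beta = np.zeros((S, 3))
        chains.beta_names = ["intercept", "zeta", "alpha"]
        out = summarize(chains, include_items=False)
        assert list(out.index[:5]) == ["intercept", "zeta", "alpha",
                                       "sigma2", "tau2"]
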