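import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

import diffreg.mcmc_engine as me
from diffreg.ec_data import ECDataset, EquivalenceClass, FeatureCatalog
from diffreg.mcmc_engine import (
    AdaptiveRWSampler,
    DeltaPrior,
    ECArrays,
    McmcConfig,
    allocate_reads,
    delta_to_eta,
    eta_to_delta,
    heidelberger_welch,
    log_posterior_delta,
    run_chain,
    sample_pi,
    sample_rho,
)
from tests.conftest import make_conjugate_dataset


def two_feature_ds(count):
    cat = FeatureCatalog(("w", "z"), eff_len=np.ones((2, 2)))
    ecs = [EquivalenceClass((("w", "S"), ("z", "U")), np.array([count]))]
    return ECDataset(cat, ("s1",), {"s1": "A"}, ecs)


class TestAllocateReads:
    def test_stated_probability_rule(self):
        # rho equal, weights 0.8 vs 0.4 -> member probabilities (2/3, 1/3)
        ds = two_feature_ds(30_000)
        arrays = ECArrays(ds)
        rho = np.array([[0.5, 0.5]])
        weights = np.zeros((1, 2, 2))
        weights[0, 0, 0] = 0.8  # (w, S)
        weights[0, 1, 1] = 0.4  # (z, U)
        latent = allocate_reads(arrays, rho, weights, np.random.default_rng(0))
        frac = latent.X[0, 0, 0] / 30_000
        se = np.sqrt((2 / 3) * (1 / 3) / 30_000)
        assert abs(frac - 2 / 3) < 3 * se
        assert latent.X.sum() == 30_000

    def test_single_member_ec_deterministic(self):
        cat = FeatureCatalog(("w",), eff_len=np.ones((1, 2)))
        ds = ECDataset(cat, ("s1",), {"s1": "A"},
                       [EquivalenceClass((("w", "S"),), np.array([9]))])
        arrays = ECArrays(ds)
        latent = allocate_reads(arrays, np.array([[1.0]]), np.ones((1, 1, 2)),
                                np.random.default_rng(0))
        assert latent.X[0, 0, 0] == 9

    def test_all_zero_probabilities_error_names_ec(self):
        ds = two_feature_ds(5)
        arrays = ECArrays(ds)
        with pytest.raises(ValueError, match="probabilities are zero"):
            allocate_reads(arrays, np.array([[0.5, 0.5]]), np.zeros((1, 2, 2)),
                           np.random.default_rng(0))

    def test_conservation_across_iterations(self):
        from tests.conftest import random_ec_dataset

        ds = random_ec_dataset(seed=2, n_samples=3)
        arrays = ECArrays(ds)
        rng = np.random.default_rng(1)
        totals = ds.total_counts()
        for _ in range(20):
            rho = rng.dirichlet(np.ones(arrays.n_features), size=3)
            weights = rng.uniform(0.1, 1.0, size=(3, arrays.n_features, 2))
            latent = allocate_reads(arrays, rho, weights, rng)
            np.testing.assert_array_equal(latent.X.sum(axis=(1, 2)), totals)
            np.testing.assert_array_equal(latent.Y, latent.X.sum(axis=2))


class TestConjugateBlocks:
    def test_rho_prior_only_mean(self):
        rng = np.random.default_rng(0)
        draws = sample_rho(np.zeros((10_000, 2)), 1.0, rng)
        assert abs(draws[:, 0].mean() - 0.5) < 0.01

    def test_rho_posterior_mean(self):
        rng = np.random.default_rng(0)
        Y = np.tile([[30.0, 10.0]], (10_000, 1))
        draws = sample_rho(Y, 1.0, rng)
        se = np.sqrt(0.25 / 43) / np.sqrt(10_000)
        assert abs(draws[:, 0].mean() - 31 / 42) < 5 * se
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-10)
        assert (draws > 0).all()

    def test_pi_beta_conjugacy(self):
        rng = np.random.default_rng(0)
        X = np.tile([[[3.0, 1.0]]], (10_000, 1, 1))
        draws = sample_pi(X, np.array([[1.0, 1.0]]), rng)  # Beta(4, 2)
        assert abs(draws[:, 0, 0].mean() - 2 / 3) < 0.01

    def test_pi_dirichlet_prior_only(self):
        rng = np.random.default_rng(0)
        X = np.zeros((10_000, 1, 3))
        draws = sample_pi(X, np.array([[2.0, 2.0, 2.0]]), rng)
        assert np.allclose(draws.mean(axis=0), 1 / 3, atol=0.01)

    def test_pi_moments_large_counts(self):
        rng = np.random.default_rng(0)
        X = np.tile([[[50.0, 50.0]]], (10_000, 1, 1))
        draws = sample_pi(X, np.array([[1.0, 1.0]]), rng)  # Beta(51, 51)
        mean, sd = 0.5, np.sqrt(0.25 / 103)
        assert abs(draws[:, 0, 0].mean() - mean) < 4 * sd / np.sqrt(10_000)


class TestLogPosteriorDelta:
    def test_uniform_beta_density_is_prior_only(self):
        prior = DeltaPrior(np.log(10), 1.0)
        delta = np.array([[1.0, 1.0]])
        pi = np.array([[[0.3, 0.7]]])
        got = log_posterior_delta(delta, pi, prior)
        np.testing.assert_allclose(got, prior.logpdf(delta))

    def test_beta_2_1_closed_form(self):
        prior = DeltaPrior(np.log(10), 1.0)
        delta = np.array([[2.0, 1.0]])
        pi = np.array([[[0.5, 0.5]]])
        got = log_posterior_delta(delta, pi, prior) - prior.logpdf(delta)
        np.testing.assert_allclose(got, np.log(2 * 0.5), atol=1e-10)

    @pytest.mark.parametrize("delta", [(0.7, 2.3), (5.0, 1.2), (12.0, 8.0)])
    def test_density_normalises_by_quadrature(self, delta):
        prior = DeltaPrior(np.log(10), 1.0)
        d = np.array([delta])

        def dens(p):
            pi = np.array([[[p, 1 - p]]])
            return np.exp(log_posterior_delta(d, pi, prior)[0] - prior.logpdf(d)[0])

        integral, _ = quad(dens, 0, 1)
        assert abs(integral - 1.0) < 1e-6

    def test_boundary_pi_is_finite(self):
        prior = DeltaPrior(np.log(10), 1.0)
        out = log_posterior_delta(np.array([[2.0, 3.0]]),
                                  np.array([[[0.0, 1.0]]]), prior)
        assert np.isfinite(out).all()


class TestAdaptiveSampler:
    def test_identity_proposal_always_accepted(self):
        s = AdaptiveRWSampler(5, 2)
        accept = s.accept_step(np.zeros(5), np.random.default_rng(0))
        assert accept.all()

    def test_nonfinite_log_ratio_auto_rejects(self):
        s = AdaptiveRWSampler(3, 2)
        accept = s.accept_step(np.array([np.nan, -np.inf, 0.0]),
                               np.random.default_rng(0))
        assert not accept[0] and not accept[1] and accept[2]

    def test_recovers_gaussian_target(self):
        # generic MH machinery against a known 2-d Gaussian
        rng = np.random.default_rng(3)
        mean = np.array([1.0, -2.0])
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def logp(x):
            d = x - mean
            return -0.5 * np.einsum("fi,ij,fj->f", d, prec, d)

        s = AdaptiveRWSampler(1, 2)
        x = np.zeros((1, 2))
        lp = logp(x)
        burn, keep = 2000, 10_000
        draws = np.empty((keep, 2))
        for it in range(burn + keep):
            prop = s.propose(x, rng)
            lp_prop = logp(prop)
            acc = s.accept_step(lp_prop - lp, rng)
            x = np.where(acc[:, None], prop, x)
            lp = np.where(acc, lp_prop, lp)
            if it < burn:
                s.adapt(x)
            else:
                draws[it - burn] = x[0]
        assert np.allclose(draws.mean(axis=0), mean, atol=0.15)
        assert np.allclose(np.cov(draws.T), cov, atol=0.35)
        assert 0.1 < s.acceptance_rate[0] < 0.6

    def test_eta_transform_round_trip(self):
        delta = np.array([[3.0, 7.0], [0.5, 0.1]])
        np.testing.assert_allclose(eta_to_delta(delta_to_eta(delta)), delta)


class TestHeidelbergerWelch:
    def test_iid_normal_mostly_passes(self):
        rng = np.random.default_rng(0)
        passed = sum(heidelberger_welch(rng.standard_normal(2000)).passed
                     for _ in range(40))
        assert passed >= 36  # >= 90%

    def test_strong_trend_mostly_fails(self):
        rng = np.random.default_rng(0)
        failed = sum(
            not heidelberger_welch(0.01 * np.arange(2000)
                                   + rng.standard_normal(2000)).passed
            for _ in range(40))
        assert failed >= 36

    def test_constant_trace_passes(self):
        res = heidelberger_welch(np.full(200, 3.7))
        assert res.passed and res.start_index == 0

    def test_short_trace_errors(self):
        with pytest.raises(ValueError, match="too short"):
            heidelberger_welch(np.arange(10))

    def test_half_stationary_trace_reports_start_index(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([np.linspace(30, 0, 600) + rng.standard_normal(600),
                            rng.standard_normal(1400)])
        res = heidelberger_welch(x)
        assert res.passed and res.start_index > 0


class TestRunChain:
    def test_uniquely_mapping_limit_matches_conjugate_posterior(self):
        """With no multi-mapping ECs, pi draws must match the Beta draw
        Beta(delta_S + X_S, delta_U + X_U) mixed over the delta chain."""
        ds, X, _ = make_conjugate_dataset(n_features=4, n_samples=3, seed=8)
        prior = DeltaPrior(np.log(20), 1.0)
        post = run_chain(ds, McmcConfig(n_iter=3500, burn_in=500, seed=4,
                                        store_pi=True),
                         model="bulk", prior=prior)
        rng = np.random.default_rng(0)
        for f in range(2):
            mcmc_draws = post.pi[:, 0, f, 0]
            ref = rng.beta(post.delta[:, f, 0] + X[0, f, 0],
                           post.delta[:, f, 1] + X[0, f, 1])
            ks = stats.ks_2samp(mcmc_draws, ref).statistic
            assert ks < 0.06

    def test_duplicate_features_statistically_indistinguishable(self):
        cat = FeatureCatalog(("a", "b"), eff_len=np.ones((2, 2)))
        ecs = []
        for f in ("a", "b"):
            ecs.append(EquivalenceClass(((f, "S"),), np.array([40, 35, 50])))
            ecs.append(EquivalenceClass(((f, "U"),), np.array([20, 25, 15])))
        ds = ECDataset(cat, ("s1", "s2", "s3"), {s: "A" for s in ("s1", "s2", "s3")}, ecs)
        post = run_chain(ds, McmcConfig(seed=3), model="bulk",
                         prior=DeltaPrior(np.log(20), 1.0))
        pu = post.pi_tilde_u()
        assert abs(pu[:, 0].mean() - pu[:, 1].mean()) < 0.03

    def test_seed_determinism(self, conjugate_ds):
        ds, _, _ = conjugate_ds
        cfg = McmcConfig(n_iter=300, burn_in=100, seed=11)
        p1 = run_chain(ds, cfg, model="bulk")
        p2 = run_chain(ds, cfg, model="bulk")
        np.testing.assert_array_equal(p1.delta, p2.delta)
        np.testing.assert_array_equal(p1.log_post, p2.log_post)

    def test_stored_quantities_are_valid(self, conjugate_ds):
        ds, _, _ = conjugate_ds
        post = run_chain(ds, McmcConfig(n_iter=400, burn_in=100, seed=2),
                         model="bulk")
        assert (post.delta > 0).all()
        np.testing.assert_allclose(post.pi_bar.sum(axis=2), 1.0, atol=1e-10)
        assert ((post.pi_tilde_u() >= 0) & (post.pi_tilde_u() <= 1)).all()

    def test_escalation_and_restart(self, conjugate_ds, monkeypatch):
        """A failed stationarity test must double the chain once; a
        persistent failure must flag the result non-converged."""
        ds, _, _ = conjugate_ds
        calls = []

        def failing_hw(trace, alpha=0.05):
            calls.append(len(trace))
            return me.HWResult(False, None, 0.001)

        monkeypatch.setattr(me, "heidelberger_welch", failing_hw)
        post = run_chain(ds, McmcConfig(n_iter=200, burn_in=50, seed=1),
                         model="bulk")
        assert not post.converged
        assert calls == [150, 300]  # doubled n_iter/burn_in on restart
        assert post.config.n_iter == 400 and post.config.burn_in == 100

    def test_serialisation_round_trip(self, conjugate_ds, tmp_path):
        ds, _, _ = conjugate_ds
        post = run_chain(ds, McmcConfig(n_iter=200, burn_in=80, seed=1),
                         model="bulk")
        post.save(tmp_path / "chains.parquet")
        back = me.GroupPosterior.load(tmp_path / "chains.parquet")
        np.testing.assert_allclose(back.delta, post.delta)
        assert back.feature_ids == post.feature_ids
        assert back.converged == post.converged
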