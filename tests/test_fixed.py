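"""Fixed-K sampler: conjugate updates against their analytic moments, FFBS
imputation against exact enumeration, and posterior parameter recovery."""

import itertools

import numpy as np
import pytest

from cthmm.ctmc import transition_probability
from cthmm.fixed import (MHState, SufficientStats, ffbs_states, fixed_k_sweep,
                         impute_paths, impute_stats, update_B, update_pi,
                         update_Q)
from cthmm.model import (GLMFamily, Subject, ThetaK, forward_marginal_loglik,
                         glm_logdensity, pack_subjects)
from cthmm.priors import BetaCoefPrior, PriorSpec
from cthmm.runner import fit_fixed_k
from cthmm.simulate import builtin_scenario, generate

from test_model import make_subject, make_theta


class TestUpdateQ:
    def test_prior_recovery_without_data(self, rng):
        prior = PriorSpec(q_shape=1.0, q_rate=2.0)
        stats = SufficientStats(np.zeros((3, 3)), np.zeros(3), np.zeros(3),
                                np.full((0, 0), -1))
        draws = np.array([update_Q(stats, prior, rng)[0, 1]
                          for _ in range(20000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se  # Gamma(1,2) mean

    def test_conjugate_posterior_mean(self, rng):
        prior = PriorSpec(q_shape=1.0, q_rate=2.0)
        ntr = np.array([[0.0, 7.0], [3.0, 0.0]])
        dwell = np.array([4.0, 9.0])
        stats = SufficientStats(ntr, dwell, np.zeros(2), np.full((0, 0), -1))
        draws = np.array([update_Q(stats, prior, rng)[0, 1]
                          for _ in range(20000)])
        want = (1.0 + 7.0) / (2.0 + 4.0)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - want) < 3 * se

    def test_rows_sum_to_zero(self, rng):
        prior = PriorSpec()
        stats = SufficientStats(np.ones((4, 4)) - np.eye(4), np.ones(4) * 2,
                                np.zeros(4), np.full((0, 0), -1))
        Q = update_Q(stats, prior, rng)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestUpdatePi:
    def test_prior_recovery(self, rng):
        prior = PriorSpec(pi_dirichlet=1.0)
        draws = np.array([update_pi(np.zeros(2), prior, rng)[0]
                          for _ in range(20000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_posterior_mean_with_counts(self, rng):
        prior = PriorSpec(pi_dirichlet=1.0)
        draws = np.array([update_pi(np.array([10.0, 0.0]), prior, rng)[0]
                          for _ in range(20000)])
        want = 11.0 / 12.0
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - want) < 3 * se
        one = update_pi(np.array([3.0, 1.0]), prior, rng)
        assert abs(one.sum() - 1.0) < 1e-12


class TestUpdateB:
    def test_normal_posterior_mean_is_ols(self, rng):
        """With a diffuse prior and sigma known, the conjugate posterior
        mean equals the least-squares estimate."""
        n, D = 40, 2
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_true = np.array([1.0, -2.0])
        y = X @ beta_true + rng.normal(0, 0.5, n)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        subj = Subject(np.arange(n, dtype=float) * 0.1
                       - 0.0, y, X)
        subj.times[0] = 0.0
        packed = pack_subjects([subj])
        theta = ThetaK(np.ones(1), np.zeros((1, 1)), np.zeros((2, 1)),
                       GLMFamily("normal", 0.5))
        stats = SufficientStats(np.zeros((1, 1)), np.zeros(1), np.ones(1),
                                np.zeros((1, n), dtype=np.int64))
        prior = PriorSpec(beta_prior=BetaCoefPrior("normal", 0.0, 1e6))
        draws = np.stack([
            update_B(theta, stats, packed, prior, rng, fix_sigma=True)[0][:, 0]
            for _ in range(3000)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        assert np.all(np.abs(draws.mean(axis=0) - ols) < 4 * se)

    def test_empty_state_draws_from_prior(self, rng):
        packed = pack_subjects([make_subject(3, 1, rng)])
        theta = make_theta(2, 1, rng=rng)
        # all observations assigned to state 1; state 2 empty
        stats = SufficientStats(np.zeros((2, 2)), np.zeros(2),
                                np.array([1.0, 0.0]),
                                np.zeros((1, 3), dtype=np.int64))
        prior = PriorSpec(beta_prior=BetaCoefPrior("normal", 3.0, 0.01))
        draws = np.array([
            update_B(theta, stats, packed, prior, rng)[0][0, 1]
            for _ in range(2000)])
        assert abs(draws.mean() - 3.0) < 0.02

    def test_poisson_mh_moves_toward_data(self, rng):
        n = 200
        y = rng.poisson(5.0, n).astype(float)
        subj = Subject(np.concatenate([[0.0], np.sort(rng.uniform(0, 10, n - 1))]),
                       y, np.ones((n, 1)))
        packed = pack_subjects([subj])
        theta = ThetaK(np.ones(1), np.zeros((1, 1)), np.array([[0.0]]),
                       GLMFamily("poisson"))
        stats = SufficientStats(np.zeros((1, 1)), np.zeros(1), np.ones(1),
                                np.zeros((1, n), dtype=np.int64))
        prior = PriorSpec(beta_prior=BetaCoefPrior("gamma-rate",
                                                   shape=10.0, rate=10.0))
        mh = MHState.fresh(1)
        for _ in range(400):
            B, _, mh = update_B(theta, stats, packed, prior, rng, mh=mh)
            theta.B[:] = B
        assert abs(np.exp(theta.B[0, 0]) - y.mean()) < 1.0
        assert 0.05 < mh.accepted / mh.proposed < 0.95


def skeleton_posterior_enumeration(theta, subj):
    """Exact conditional law of the state skeleton given observations."""
    K, T = theta.K, subj.T
    gaps = np.diff(subj.times)
    Ps = [transition_probability(theta.Q, g) for g in gaps]
    probs = {}
    for seq in itertools.product(range(K), repeat=T):
        p = theta.pi[seq[0]]
        for t in range(1, T):
            p *= Ps[t - 1][seq[t - 1], seq[t]]
        for t in range(T):
            p *= np.exp(float(glm_logdensity(
                subj.outcomes[t], subj.Z[t], theta.B[:, seq[t]],
                theta.family)))
        probs[seq] = p
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


class TestImputation:
    def test_k1_deterministic(self, rng):
        theta = make_theta(1, 1)
        subjects = [make_subject(4, 1, rng)]
        paths = impute_paths(theta, subjects, rng)
        assert paths[0].n_jumps == 0 and paths[0].states[0] == 1

    def test_skeleton_matches_enumeration(self, rng):
        """FFBS skeleton distribution vs exact enumeration on K=2, T=3
        (8 sequences), chi-square at 50,000 draws."""
        from scipy.stats import chisquare

        theta = make_theta(2, 1, rng=rng, betas=[[-0.8, 0.8]])
        subj = make_subject(3, 1, rng)
        exact = skeleton_posterior_enumeration(theta, subj)
        # replicate the subject: each row is an independent skeleton draw
        n_rep, n_call = 100, 500
        packed = pack_subjects([subj] * n_rep)
        counts = {}
        for _ in range(n_call):
            S = ffbs_states(theta, packed, rng)
            for row in S:
                key = tuple(row)
                counts[key] = counts.get(key, 0) + 1
        n = n_rep * n_call
        keys = sorted(exact)
        obs = np.array([counts.get(k, 0) for k in keys], dtype=float)
        exp = np.array([exact[k] for k in keys]) * n
        keep = exp > 5
        res = chisquare(obs[keep], exp[keep], sum_check=False)
        assert res.pvalue > 0.001

    def test_informative_observations_pin_states(self, rng):
        """With sigma = 1e-3 and well-separated means the imputed states at
        observation times equal the data-implied states."""
        theta = make_theta(3, 1, sigma=1e-3, rng=rng, betas=[[-4.0, 0.0, 5.0]])
        means = np.array([-4.0, 0.0, 5.0])
        truth = np.array([2, 0, 1, 2, 0])
        subj = Subject(np.array([0.0, 1.0, 2.0, 3.0, 4.0]), means[truth],
                       np.ones((5, 1)))
        packed = pack_subjects([subj])
        for _ in range(20):
            S = ffbs_states(theta, packed, rng)
            np.testing.assert_array_equal(S[0], truth)

    def test_stats_consistent_with_paths(self, rng):
        """Aggregated sufficient statistics have the right structure and
        conservation properties."""
        theta = make_theta(3, 1, rng=rng)
        subjects = [make_subject(6, 1, rng) for _ in range(5)]
        packed = pack_subjects(subjects)
        stats = impute_stats(theta, packed, rng)
        assert stats.init_counts.sum() == 5
        assert np.all(np.diag(stats.n_trans) == 0)
        total_window = sum(s.times[-1] for s in subjects)
        assert abs(stats.dwell.sum() - total_window) < 1e-8

    def test_impute_paths_cover_windows(self, rng):
        theta = make_theta(2, 1, rng=rng)
        subjects = [make_subject(4, 1, rng) for _ in range(3)]
        paths = impute_paths(theta, subjects, rng)
        for p, s in zip(paths, subjects):
            p.validate()
            assert p.horizon == s.times[-1]


class TestSweepAndRecovery:
    def test_sweep_preserves_types(self, rng):
        theta = make_theta(3, 2, rng=rng)
        packed = pack_subjects([make_subject(6, 2, rng) for _ in range(4)])
        prior = PriorSpec()
        new, stats, mh = fixed_k_sweep(theta, packed, prior, rng)
        new.validate()
        assert new.K == 3

    def test_intercept_recovery_three_state_normal(self, rng):
        """Fixed K=3 intercept-only normal model: posterior means of the
        sorted intercepts land within 3 posterior SDs of (-4, 0, 5)."""
        cfg = builtin_scenario("SIM2-3state-intercept").scaled(0.2)  # n=200
        subjects, _ = generate(cfg, rng)
        packed = pack_subjects(subjects)
        prior = PriorSpec(beta_prior=BetaCoefPrior("normal", 0.0, 1.0))
        res = fit_fixed_k(packed, 3, GLMFamily("normal", 1.0), prior, 600,
                          rng, thin=5)
        draws = np.stack([np.sort(th.B[0]) for it, th in res.snapshots
                          if it >= 200])
        mean, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
        target = np.array([-4.0, 0.0, 5.0])
        assert np.all(np.abs(mean - target) < 3 * np.maximum(sd, 1e-3) + 0.1)
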