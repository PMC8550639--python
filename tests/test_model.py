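"""Observation model and likelihoods: GLM densities, complete-data
likelihood against a hand-assembled oracle, and the forward marginal
likelihood against exhaustive enumeration."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import norm, poisson

from cthmm.ctmc import LatentPath, transition_probability
from cthmm.fixed import impute_paths
from cthmm.model import (GLMFamily, PackedData, Subject, ThetaK,
                         complete_data_loglik, forward_marginal_loglik,
                         glm_logdensity, pack_subjects)

from conftest import random_generator


def make_theta(K, D, family="normal", sigma=1.0, rng=None, betas=None):
    rng = rng or np.random.default_rng(5)
    Q = random_generator(K, rng) if K > 1 else np.zeros((1, 1))
    pi = rng.dirichlet(np.ones(K))
    B = rng.normal(0, 1.5, size=(D, K)) if betas is None else np.asarray(betas)
    return ThetaK(pi, Q, B, GLMFamily(family, sigma))


def make_subject(T, D, rng, family="normal"):
    times = np.concatenate([[0.0], np.sort(rng.uniform(0, 10, T - 1))]) \
        if T > 1 else np.array([0.0])
    Z = np.ones((T, D))
    if D > 1:
        Z[:, 1:] = rng.normal(size=(T, D - 1))
    if family == "normal":
        y = rng.normal(size=T)
    else:
        y = rng.poisson(3.0, size=T).astype(float)
    return Subject(times, y, Z)


class TestGlmLogdensity:
    def test_normal_at_mode(self):
        fam = GLMFamily("normal", 1.0)
        val = glm_logdensity(2.5, np.array([1.0, 0.5]),
                             np.array([2.0, 1.0]), fam)
        assert abs(val - (-0.5 * np.log(2 * np.pi))) < 1e-12

    def test_normal_matches_scipy(self):
        fam = GLMFamily("normal", 1.7)
        val = glm_logdensity(0.3, np.array([1.0]), np.array([-0.4]), fam)
        assert abs(val - norm.logpdf(0.3, -0.4, 1.7)) < 1e-12

    def test_poisson_direct_pmf(self):
        # z = (1), beta = log 4, o = 4: log(4^4 e^-4 / 4!)
        fam = GLMFamily("poisson")
        val = glm_logdensity(4.0, np.array([1.0]), np.array([np.log(4.0)]), fam)
        direct = 4 * np.log(4) - 4 - np.log(24.0)
        assert abs(val - direct) < 1e-12
        assert abs(val - poisson.logpmf(4, 4.0)) < 1e-12

    def test_poisson_rejects_invalid_outcomes(self):
        fam = GLMFamily("poisson")
        with pytest.raises(ValueError):
            glm_logdensity(2.5, np.array([1.0]), np.array([0.0]), fam)
        with pytest.raises(ValueError):
            glm_logdensity(-1.0, np.array([1.0]), np.array([0.0]), fam)

    def test_additivity_over_observations(self, rng):
        fam = GLMFamily("normal", 0.8)
        z = np.ones((5, 1))
        o = rng.normal(size=5)
        beta = np.array([0.3])
        total = glm_logdensity(o, z, beta, fam).sum()
        parts = sum(glm_logdensity(o[i], z[i], beta, fam) for i in range(5))
        assert abs(total - parts) < 1e-12


class TestCompleteDataLoglik:
    def test_k1_reduces_to_observation_terms(self, rng):
        theta = make_theta(1, 1, betas=[[0.7]])
        subj = make_subject(4, 1, rng)
        path = LatentPath(subj.times[-1], np.array([1]), np.array([0.0]))
        val = complete_data_loglik(theta, [path], [subj])
        expect = sum(
            glm_logdensity(subj.outcomes[t], subj.Z[t], theta.B[:, 0],
                           theta.family) for t in range(4))
        assert abs(val - expect) < 1e-12

    def test_two_subject_hand_assembly(self):
        """Hand-assembled product of initial probability, exponential dwell
        densities, jump rates, and GLM densities on a 2-subject toy."""
        Q = np.array([[-0.5, 0.5], [1.2, -1.2]])
        theta = ThetaK(np.array([0.6, 0.4]), Q,
                       np.array([[-1.0, 2.0]]), GLMFamily("normal", 0.9))
        s1 = Subject(np.array([0.0, 1.0, 3.0]), np.array([-1.2, 1.8, 2.4]),
                     np.ones((3, 1)))
        s2 = Subject(np.array([0.0, 0.5, 2.0]), np.array([2.2, 2.0, -0.7]),
                     np.ones((3, 1)))
        p1 = LatentPath(3.0, np.array([1, 2]), np.array([0.0, 0.6]))
        p2 = LatentPath(2.0, np.array([2, 1]), np.array([0.0, 1.1]))
        val = complete_data_loglik(theta, [p1, p2], [s1, s2])
        # subject 1: start 1, dwell 0.6 in 1, jump 1->2, dwell 2.4 in 2
        hand = (np.log(0.6) - 0.5 * 0.6 + np.log(0.5) - 1.2 * 2.4
                + norm.logpdf(-1.2, -1.0, 0.9) + norm.logpdf(1.8, 2.0, 0.9)
                + norm.logpdf(2.4, 2.0, 0.9))
        # subject 2: start 2, dwell 1.1 in 2, jump 2->1, dwell 0.9 in 1
        hand += (np.log(0.4) - 1.2 * 1.1 + np.log(1.2) - 0.5 * 0.9
                 + norm.logpdf(2.2, 2.0, 0.9) + norm.logpdf(2.0, 2.0, 0.9)
                 + norm.logpdf(-0.7, -1.0, 0.9))
        assert abs(val - hand) < 1e-10

    def test_relabeling_invariance(self, rng):
        theta = make_theta(3, 2, rng=rng)
        subj = make_subject(5, 2, rng)
        path = LatentPath(subj.times[-1], np.array([2, 1, 3]),
                          np.array([0.0, 2.0, 6.0]))
        perm = np.array([2, 0, 1])  # new index -> old index
        inv = np.argsort(perm)
        theta_p = ThetaK(theta.pi[perm], theta.Q[np.ix_(perm, perm)],
                         theta.B[:, perm], theta.family)
        path_p = LatentPath(path.horizon, inv[path.states - 1] + 1, path.times)
        v1 = complete_data_loglik(theta, [path], [subj])
        v2 = complete_data_loglik(theta_p, [path_p], [subj])
        assert abs(v1 - v2) < 1e-10

    def test_window_mismatch_raises(self, rng):
        theta = make_theta(2, 1, rng=rng)
        subj = make_subject(3, 1, rng)
        short = LatentPath(subj.times[-1] / 2, np.array([1]), np.array([0.0]))
        with pytest.raises(ValueError, match="window"):
            complete_data_loglik(theta, [short], [subj])


def enumeration_loglik(theta, subj):
    """Brute-force marginal likelihood: sum over all K^T state sequences."""
    K, T = theta.K, subj.T
    gaps = np.diff(subj.times)
    Ps = [transition_probability(theta.Q, g) for g in gaps]
    total = 0.0
    for seq in itertools.product(range(K), repeat=T):
        p = theta.pi[seq[0]]
        for t in range(1, T):
            p *= Ps[t - 1][seq[t - 1], seq[t]]
        for t in range(T):
            p *= np.exp(glm_logdensity(subj.outcomes[t], subj.Z[t],
                                       theta.B[:, seq[t]], theta.family))
        total += p
    return np.log(total)


class TestForwardMarginal:
    def test_matches_enumeration_k3_t5(self, rng):
        theta = make_theta(3, 2, rng=rng)
        subj = make_subject(5, 2, rng)
        expect = enumeration_loglik(theta, subj)
        got = forward_marginal_loglik(theta, [subj])
        assert abs(got - expect) < 1e-8

    def test_matches_enumeration_poisson(self, rng):
        theta = make_theta(3, 1, family="poisson", rng=rng,
                           betas=[[np.log(1.5), np.log(4.0), np.log(6.0)]])
        subj = make_subject(5, 1, rng, family="poisson")
        assert abs(forward_marginal_loglik(theta, [subj])
                   - enumeration_loglik(theta, subj)) < 1e-8

    def test_single_observation_no_dynamics(self, rng):
        theta = make_theta(3, 1, rng=rng)
        subjects = [make_subject(1, 1, rng) for _ in range(4)]
        got = forward_marginal_loglik(theta, subjects)
        expect = 0.0
        for s in subjects:
            mix = sum(theta.pi[k] * np.exp(glm_logdensity(
                s.outcomes[0], s.Z[0], theta.B[:, k], theta.family))
                for k in range(theta.K))
            expect += np.log(mix)
        assert abs(got - expect) < 1e-10

    def test_duplicated_subject_doubles_contribution(self, rng):
        theta = make_theta(2, 1, rng=rng)
        subj = make_subject(6, 1, rng)
        one = forward_marginal_loglik(theta, [subj])
        two = forward_marginal_loglik(theta, [subj, subj])
        assert abs(two - 2 * one) < 1e-10

    def test_no_underflow_at_t60(self, rng):
        theta = make_theta(3, 1, rng=rng)
        subj = make_subject(60, 1, rng)
        val = forward_marginal_loglik(theta, [subj])
        assert np.isfinite(val)

    def test_continuity_in_beta(self, rng):
        theta = make_theta(3, 1, rng=rng)
        subjects = [make_subject(8, 1, rng) for _ in range(3)]
        base = forward_marginal_loglik(theta, subjects)
        theta2 = theta.copy()
        theta2.B[0, 0] += 1e-6
        assert abs(forward_marginal_loglik(theta2, subjects) - base) < 1e-4

    def test_importance_identity(self, rng):
        """Monte-Carlo consistency of the two likelihoods: averaging the
        conditional observation density exp(sum of emission terms) over
        latent paths drawn from their prior law recovers the forward
        marginal likelihood (the latent paths integrate out exactly)."""
        from cthmm.ctmc import simulate_ctmc

        theta = make_theta(2, 1, rng=rng, betas=[[-1.0, 1.0]])
        subj = make_subject(3, 1, rng)
        marg = forward_marginal_loglik(theta, [subj])
        n = 20000
        vals = np.empty(n)
        for i in range(n):
            path = simulate_ctmc(theta.Q, theta.pi, subj.times[-1] + 1e-9, rng)
            states = path.state_at(subj.times) - 1
            vals[i] = np.exp(sum(
                glm_logdensity(subj.outcomes[t], subj.Z[t],
                               theta.B[:, states[t]], theta.family)
                for t in range(subj.T)))
        est = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(n)
        assert abs(est - np.exp(marg)) < 4 * se


class TestPacking:
    def test_pack_roundtrip_shapes(self, rng):
        subjects = [make_subject(T, 2, rng) for T in (3, 5, 1)]
        packed = pack_subjects(subjects)
        assert packed.N == 3 and packed.Tmax == 5 and packed.D == 2
        np.testing.assert_array_equal(packed.lengths, [3, 5, 1])
        sub = packed.subset([1])
        assert sub.N == 1 and sub.lengths[0] == 5

    def test_subject_validation(self):
        with pytest.raises(ValueError):
            Subject(np.array([0.5, 1.0]), np.zeros(2), np.ones((2, 1))).validate()
        with pytest.raises(ValueError):
            Subject(np.array([0.0, 1.0]), np.zeros(2),
                    np.full((2, 1), 2.0)).validate()
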