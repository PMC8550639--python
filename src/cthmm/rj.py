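"""Reversible-jump split/combine moves on the number of hidden states.

The split proposal is "centered": the state chosen for splitting donates
its outgoing rates to both children, its incoming rates are divided by
Beta(2, 2) weights, the two new cross rates come from the rate prior, the
child intercept is a normal perturbation of the parent's, and the initial
probability is split by a Beta(2, 2) weight.  This construction preserves
the stationary law of the chain (the children's stationary masses sum to
the parent's), so current and proposed models make similar likelihood
contributions and trans-dimensional acceptance rates stay useful.  The
combine move merges the selected pair by stationary-probability-weighted
averages and is the reverse operation.

Acceptance ratios are evaluated on the forward marginal likelihood (latent
paths play no role and are re-imputed after an accepted jump).  The
proposal-ratio bookkeeping includes the probabilities of selecting the
split state (1/K) and of the reverse combine selecting the matched pair
(m/(K+1) with m in {1, 2} directions of the nearest-neighbour rule), and
the combine factor includes the intercept-perturbation density of the
reverse split; both are validated by exact factor reciprocity and by prior
recovery of p0(K) under a flat likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctmc import stationary_probs
from .model import GLMFamily, PackedData, ThetaK, forward_marginal_loglik
from .priors import (PriorSpec, log_beta_pdf, log_gamma_pdf, log_normal_pdf,
                     theta_log_prior)

__all__ = [
    "MoveConfig",
    "SplitProposal",
    "select_combine_pair",
    "nearest_state",
    "check_split_adjacency",
    "propose_split",
    "propose_combine",
    "split_log_acceptance",
    "combine_log_acceptance",
    "rj_state_step",
]


@dataclass
class MoveConfig:
    """Tuning constants of the state split/combine move: split probability
    b_split (boundary dimensions force the only legal move), intercept
    perturbation SD c, hard cap Kmax, and the Beta shape pair of the
    splitting weights (fixed at (2, 2))."""

    b_split: float = 0.5
    c: float = 1.0
    Kmax: int = 10
    w_beta: tuple = (2.0, 2.0)

    def validate(self) -> None:
        if not (0.0 < self.b_split < 1.0):
            raise ValueError("b_split must lie in (0, 1)")
        if not self.c > 0:
            raise ValueError("c must be > 0")
        if self.Kmax < 1:
            raise ValueError("Kmax must be >= 1")

    def b_of(self, K: int) -> float:
        """Probability of proposing a split when the chain is at K states."""
        if K <= 1:
            return 1.0
        if K >= self.Kmax:
            return 0.0
        return self.b_split

    def d_of(self, K: int) -> float:
        """Probability of proposing a combine at K states."""
        return 1.0 - self.b_of(K)


@dataclass
class SplitProposal:
    source_state: int            # 1-based label of the split state
    new_theta: ThetaK            # K+1 states; children at source and K+1
    w_incoming: np.ndarray
    w_pi: float
    q_cross: tuple
    beta_new: float
    log_proposal_ratio: float    # q2(theta_K; theta_{K+1}) / q2(theta_{K+1}; theta_K)
    log_alpha: float | None = None


def _l1_dists(B: np.ndarray, k: int) -> np.ndarray:
    d = np.abs(B - B[:, [k]]).sum(axis=0)
    d[k] = np.inf
    return d


def nearest_state(B: np.ndarray, k: int) -> int:
    """The state whose coefficient column is L1-closest to state k's
    (smallest index on ties)."""
    return int(np.argmin(_l1_dists(B, k)))


def select_combine_pair(B: np.ndarray, rng: np.random.Generator):
    """Combine-pair selection: k uniform, partner = L1-nearest column.
    0-based indices."""
    K = B.shape[1]
    if K < 2:
        raise ValueError("combine requires K >= 2")
    k = int(rng.integers(K))
    return k, nearest_state(B, k)


def check_split_adjacency(B_new: np.ndarray, k: int, k_new: int) -> bool:
    """Early-rejection test of a split: the two children must be mutually
    closer (L1 on coefficient columns) than the split state is to any other
    state; otherwise the reverse combine could not select the pair."""
    if B_new.shape[1] <= 2:
        return True
    d = _l1_dists(B_new, k)
    return bool(d[k_new] < np.min(np.delete(d, k_new)))


def _pair_selection_count(B: np.ndarray, k: int, k2: int) -> int:
    """Number of ways the nearest-neighbour rule proposes the pair {k, k2}:
    counts each member whose nearest state is the other."""
    return int(nearest_state(B, k) == k2) + int(nearest_state(B, k2) == k)


def propose_split(theta: ThetaK, k: int, cfg: MoveConfig, prior: PriorSpec,
                  rng: np.random.Generator) -> SplitProposal:
    """Split state k (0-based) into children at positions k and K (new last
    index).  Returns the proposal with its log proposal-density ratio."""
    K = theta.K
    if K >= cfg.Kmax:
        raise ValueError("split unavailable at Kmax")
    others = np.array([i for i in range(K) if i != k], dtype=np.int64)
    aw, bw = cfg.w_beta

    Q = theta.Q
    Qn = np.zeros((K + 1, K + 1))
    Qn[:K, :K] = Q
    # outgoing rates copied to both children
    Qn[K, :K] = Q[k, :K]
    Qn[K, k] = 0.0
    # incoming rates divided by Beta(2,2) weights
    w_in = rng.beta(aw, bw, size=others.size)
    Qn[others, k] = w_in * Q[others, k]
    Qn[others, K] = (1.0 - w_in) * Q[others, k]
    # new cross rates from the rate prior
    q1 = rng.gamma(prior.q_shape, 1.0 / prior.q_rate)
    q2 = rng.gamma(prior.q_shape, 1.0 / prior.q_rate)
    Qn[k, K] = q1
    Qn[K, k] = q2
    np.fill_diagonal(Qn, 0.0)
    np.fill_diagonal(Qn, -Qn.sum(axis=1))

    Bn = np.concatenate([theta.B, theta.B[:, [k]]], axis=1)
    beta_new = float(rng.normal(theta.B[0, k], cfg.c))
    Bn[0, K] = beta_new

    w_pi = float(rng.beta(aw, bw))
    pin = np.concatenate([theta.pi, [0.0]])
    pin[k] = w_pi * theta.pi[k]
    pin[K] = (1.0 - w_pi) * theta.pi[k]

    with np.errstate(divide="ignore"):
        # a structurally zero incoming rate gives a -inf Jacobian term: such
        # a split can never be accepted, which the min() handles gracefully
        log_num = float(np.log(Q[others, k]).sum()) + float(np.log(theta.pi[k]))
    log_den = float(log_gamma_pdf(q1, prior.q_shape, prior.q_rate)
                    + log_gamma_pdf(q2, prior.q_shape, prior.q_rate)
                    + log_beta_pdf(w_in, aw, bw).sum()
                    + log_normal_pdf(beta_new, theta.B[0, k], cfg.c ** 2)
                    + log_beta_pdf(w_pi, aw, bw))
    new_theta = ThetaK(pin, Qn, Bn,
                       GLMFamily(theta.family.family, theta.family.sigma))
    return SplitProposal(k + 1, new_theta, w_in, w_pi, (q1, q2), beta_new,
                         log_num - log_den)


def propose_combine(theta: ThetaK, k: int, k2: int, cfg: MoveConfig,
                    prior: PriorSpec):
    """Deterministic merge of states k and k2 (0-based) by
    stationary-probability-weighted averages; incoming rates are summed and
    initial probabilities added.  Returns (merged_theta, reverse_log_ratio)
    where the reverse log ratio is the log proposal-density ratio of the
    matching split move, evaluated at the recovered splitting variables.
    """
    K = theta.K
    if K < 2:
        raise ValueError("combine requires K >= 2")
    lo, hi = (k, k2) if k < k2 else (k2, k)
    s = stationary_probs(theta.Q)  # raises for reducible proposals
    u = s[k] / (s[k] + s[k2])
    keep = np.array([i for i in range(K) if i != hi], dtype=np.int64)
    pos = int(np.where(keep == lo)[0][0])
    others = keep[keep != lo]

    Q = theta.Q
    Qm = Q[np.ix_(keep, keep)].copy()
    # merged outgoing rates: stationary-weighted average of the pair's rows
    Qm[pos, :] = u * Q[k, keep] + (1.0 - u) * Q[k2, keep]
    # merged incoming rates: sums (the cross rates q_{k,k2}, q_{k2,k} drop)
    Qm[:, pos] = Q[keep, lo] + Q[keep, hi]
    np.fill_diagonal(Qm, 0.0)
    np.fill_diagonal(Qm, -Qm.sum(axis=1))

    Bm = theta.B[:, keep].copy()
    Bm[:, pos] = u * theta.B[:, k] + (1.0 - u) * theta.B[:, k2]
    pim = theta.pi[keep].copy()
    pim[pos] = theta.pi[k] + theta.pi[k2]

    aw, bw = cfg.w_beta
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = Q[others, k] + Q[others, k2]
        w_in = np.where(denom > 0, Q[others, k] / np.where(denom > 0, denom, 1.0), np.nan)
        w_pi = theta.pi[k] / (theta.pi[k] + theta.pi[k2])
        log_num = float(log_gamma_pdf(Q[k, k2], prior.q_shape, prior.q_rate)
                        + log_gamma_pdf(Q[k2, k], prior.q_shape, prior.q_rate)
                        + np.sum(log_beta_pdf(w_in, aw, bw))
                        + log_normal_pdf(theta.B[0, k2] - theta.B[0, k], 0.0,
                                         cfg.c ** 2)
                        + log_beta_pdf(w_pi, aw, bw))
        log_den = float(np.log(Qm[others_pos(keep, others), pos]).sum()
                        + np.log(pim[pos]))
    if not np.isfinite(log_num):
        log_num = -np.inf
    merged = ThetaK(pim, Qm, Bm,
                    GLMFamily(theta.family.family, theta.family.sigma))
    return merged, log_num - log_den


def others_pos(keep: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Positions of `others` within the retained index list `keep`."""
    lookup = {int(v): i for i, v in enumerate(keep)}
    return np.array([lookup[int(v)] for v in others], dtype=np.int64)


def _log_posterior_terms(theta: ThetaK, data, prior: PriorSpec,
                         k_logpmf: np.ndarray) -> float:
    """log L(o | Theta_K, K) + log p0(Theta_K | K) + log p0(K); a proposal
    whose forward recursion degenerates numerically scores -inf (the move
    is rejected with that diagnostic rather than aborting the chain)."""
    try:
        ll = forward_marginal_loglik(theta, data)
    except FloatingPointError:
        return -np.inf
    return ll + theta_log_prior(theta, prior) + float(k_logpmf[theta.K - 1])


def split_log_acceptance(proposal: SplitProposal, theta_old: ThetaK, data,
                         prior: PriorSpec, cfg: MoveConfig,
                         ll_terms_old: float | None = None,
                         k_logpmf: np.ndarray | None = None) -> float:
    """Log MH acceptance probability of a split proposal."""
    if k_logpmf is None:
        k_logpmf = prior.k_prior.log_pmf(cfg.Kmax)
    K = theta_old.K
    k = proposal.source_state - 1
    m_rev = _pair_selection_count(proposal.new_theta.B, k, K)
    if m_rev == 0:
        return -np.inf
    if ll_terms_old is None:
        ll_terms_old = _log_posterior_terms(theta_old, data, prior, k_logpmf)
    ll_terms_new = _log_posterior_terms(proposal.new_theta, data, prior, k_logpmf)
    if not np.isfinite(ll_terms_new):
        return -np.inf
    log_sel = np.log(m_rev) - np.log(K + 1) + np.log(K)
    log_move = np.log(cfg.d_of(K + 1)) - np.log(cfg.b_of(K))
    return min(0.0, log_move + log_sel + proposal.log_proposal_ratio
               + ll_terms_new - ll_terms_old)


def combine_log_acceptance(theta: ThetaK, merged: ThetaK,
                           reverse_log_ratio: float, m_fwd: int, data,
                           prior: PriorSpec, cfg: MoveConfig,
                           ll_terms_old: float | None = None,
                           k_logpmf: np.ndarray | None = None) -> float:
    """Log MH acceptance probability of combining a pair at K+1 states into
    the merged K-state model."""
    if k_logpmf is None:
        k_logpmf = prior.k_prior.log_pmf(cfg.Kmax)
    K1 = theta.K          # current dimension (K+1 in the derivation)
    K = merged.K
    if ll_terms_old is None:
        ll_terms_old = _log_posterior_terms(theta, data, prior, k_logpmf)
    ll_terms_new = _log_posterior_terms(merged, data, prior, k_logpmf)
    if not np.isfinite(ll_terms_new):
        return -np.inf
    log_sel = -np.log(K) - (np.log(m_fwd) - np.log(K1))
    log_move = np.log(cfg.b_of(K)) - np.log(cfg.d_of(K1))
    return min(0.0, log_move + log_sel + reverse_log_ratio
               + ll_terms_new - ll_terms_old)


def rj_state_step(theta: ThetaK, data, prior: PriorSpec, cfg: MoveConfig,
                  rng: np.random.Generator,
                  ll_terms_old: float | None = None,
                  k_logpmf: np.ndarray | None = None):
    """One trans-dimensional step on K.

    Chooses split with probability b(K) (forced at the boundaries), applies
    the early adjacency rejection, and MH-accepts on the forward marginal
    likelihood.  Returns (theta, record) where record reports the move type,
    acceptance and log alpha; theta is unchanged on rejection.
    """
    if k_logpmf is None:
        k_logpmf = prior.k_prior.log_pmf(cfg.Kmax)
    K = theta.K
    record = {"K": K, "move": None, "accepted": False, "log_alpha": -np.inf}
    if cfg.Kmax == 1:
        return theta, record
    if rng.random() < cfg.b_of(K):
        record["move"] = "split"
        k = int(rng.integers(K))
        proposal = propose_split(theta, k, cfg, prior, rng)
        if not check_split_adjacency(proposal.new_theta.B, k, K):
            record["early_reject"] = True
            return theta, record
        log_alpha = split_log_acceptance(proposal, theta, data, prior, cfg,
                                         ll_terms_old=ll_terms_old,
                                         k_logpmf=k_logpmf)
        record["log_alpha"] = log_alpha
        if np.log(rng.random()) < log_alpha:
            record["accepted"] = True
            record["K"] = K + 1
            return proposal.new_theta, record
        return theta, record
    record["move"] = "combine"
    k, k2 = select_combine_pair(theta.B, rng)
    m_fwd = _pair_selection_count(theta.B, k, k2)
    try:
        merged, rev = propose_combine(theta, k, k2, cfg, prior)
    except ValueError as exc:  # reducible merged generator
        record["diagnostic"] = str(exc)
        return theta, record
    log_alpha = combine_log_acceptance(theta, merged, rev, m_fwd, data, prior,
                                       cfg, ll_terms_old=ll_terms_old,
                                       k_logpmf=k_logpmf)
    record["log_alpha"] = log_alpha
    if np.log(rng.random()) < log_alpha:
        record["accepted"] = True
        record["K"] = K - 1
        return merged, record
    return theta, record
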