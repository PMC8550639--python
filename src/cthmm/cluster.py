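"""Finite-mixture model-based clustering of trajectories.

Each mixture component is a full CTHMM with its own state count K_m,
generator, initial law and GLM coefficients; subjects carry latent
component memberships C_n with weights (varpi_1, ..., varpi_M) ~
Dirichlet(delta).  Both the number of components M and each component's
state count are sampled: one sweep (i) runs the state split/combine move
inside every component using its currently assigned subjects, (ii) splits
or combines whole components on the marginalized likelihood (component
labels and latent paths integrated out), (iii) resamples memberships from
their posterior, (iv) runs fixed-dimension parameter sweeps per component
(an empty component's sweep reduces to a prior refresh), and (v) updates
the weights by Dirichlet conjugacy.

The number of components M and the number of occupied components M* (the
"clusters" actually generating data) are reported separately each
iteration.

Component split moves duplicate a component and perturb every state's
intercept; combines merge two same-K components state-by-state with
stationary-probability weights.  As with the state moves, the proposal
bookkeeping includes the pair-selection probabilities and the product of
intercept-perturbation densities over the component's states, validated by
factor reciprocity and by prior recovery of p0(M) under a flat likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .ctmc import stationary_probs
from .fixed import MHState, fixed_k_sweep
from .model import GLMFamily, PackedData, ThetaK, forward_marginal_loglik
from .priors import (PriorSpec, log_beta_pdf, log_dirichlet_sym,
                     log_normal_pdf, theta_log_prior)
from .rj import MoveConfig, rj_state_step

__all__ = [
    "MixtureModel",
    "ClusterMoveConfig",
    "ClusterState",
    "membership_posterior",
    "membership_posteriors",
    "mixture_marginal_loglik",
    "component_loglik_matrix",
    "propose_component_split",
    "propose_component_combine",
    "cluster_sweep",
    "init_cluster_state",
]


@dataclass
class MixtureModel:
    """M mixture components with weights on the simplex; component m is a
    ThetaK with K_m states."""

    weights: np.ndarray
    components: list

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)

    @property
    def M(self) -> int:
        return self.weights.size

    def state_counts(self) -> list[int]:
        return [c.K for c in self.components]

    def validate(self) -> None:
        if self.M < 1 or len(self.components) != self.M:
            raise ValueError("weights and components must align, M >= 1")
        if abs(self.weights.sum() - 1.0) > 1e-8 or self.weights.min() < 0:
            raise ValueError("mixture weights must lie on the simplex")
        for c in self.components:
            c.validate()


@dataclass
class ClusterMoveConfig:
    """Component split/combine tuning: the combine move dominates by
    default (probability 0.7, i.e. b_split = 0.3) because a combine only
    succeeds once two similar components share a state count."""

    b_split: float = 0.3
    c: float = 1.0
    Mmax: int = 15

    def b_of(self, M: int) -> float:
        if M <= 1:
            return 1.0
        if M >= self.Mmax:
            return 0.0
        return self.b_split

    def d_of(self, M: int) -> float:
        return 1.0 - self.b_of(M)


def component_loglik_matrix(model: MixtureModel, packed: PackedData) -> np.ndarray:
    """Per-subject forward marginal log-likelihood under every component,
    shape (N, M)."""
    cols = [forward_marginal_loglik(c, packed, per_subject=True, strict=False)
            for c in model.components]
    return np.stack(cols, axis=1) if cols else np.zeros((packed.N, 0))


def membership_posteriors(model: MixtureModel, packed: PackedData,
                          LL: np.ndarray | None = None) -> np.ndarray:
    """Posterior membership probabilities (N, M): row n is proportional to
    varpi_m * L(o_n | Theta^(m), K_m), normalised in log space."""
    if LL is None:
        LL = component_loglik_matrix(model, packed)
    with np.errstate(divide="ignore"):
        logw = LL + np.log(model.weights)[None, :]
    m = logw.max(axis=1, keepdims=True)
    W = np.exp(logw - m)
    tot = W.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):  # all components impossible: fall back to weights
        bad = (tot[:, 0] <= 0)
        W[bad] = model.weights[None, :]
        tot = W.sum(axis=1, keepdims=True)
    return W / tot


def membership_posterior(n: int, model: MixtureModel, packed: PackedData) -> np.ndarray:
    return membership_posteriors(model, packed.subset([n]))[0]


def mixture_marginal_loglik(model: MixtureModel, packed: PackedData,
                            LL: np.ndarray | None = None) -> float:
    """Marginalized observed-data log-likelihood
    sum_n log sum_m varpi_m L(o_n | Theta^(m), K_m)."""
    if LL is None:
        LL = component_loglik_matrix(model, packed)
    if LL.shape[0] == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(logsumexp(LL + np.log(model.weights)[None, :], axis=1).sum())


def _frob_dists(model: MixtureModel, m: int) -> np.ndarray:
    """L2 distance between coefficient matrices, infinite for components
    with a different state count (they can never be merge partners)."""
    Km = model.components[m].K
    d = np.full(model.M, np.inf)
    for j in range(model.M):
        if j != m and model.components[j].K == Km:
            d[j] = float(np.linalg.norm(model.components[j].B
                                        - model.components[m].B))
    return d


def _nearest_component(model: MixtureModel, m: int) -> int | None:
    d = _frob_dists(model, m)
    j = int(np.argmin(d))
    return j if np.isfinite(d[j]) else None


def _pair_count(model: MixtureModel, a: int, b: int) -> int:
    return int(_nearest_component(model, a) == b) \
        + int(_nearest_component(model, b) == a)


def propose_component_split(model: MixtureModel, m: int, cfg: ClusterMoveConfig,
                            rng: np.random.Generator):
    """Centered component split: duplicate component m (same Q and pi), with
    every state's intercept in the copy perturbed by N(0, c^2), and the
    weight divided by a Beta(2, 2) draw.  Returns
    (new_model, new_component_index, log_proposal_ratio)."""
    comp = model.components[m]
    new_comp = comp.copy()
    perturb = rng.normal(0.0, cfg.c, size=comp.K)
    new_comp.B[0, :] = comp.B[0, :] + perturb
    w = float(rng.beta(2.0, 2.0))
    weights = np.concatenate([model.weights, [0.0]])
    weights[m] = w * model.weights[m]
    weights[-1] = (1.0 - w) * model.weights[m]
    log_ratio = float(np.log(model.weights[m])
                      - log_beta_pdf(w, 2.0, 2.0)
                      - log_normal_pdf(perturb, 0.0, cfg.c ** 2).sum())
    new_model = MixtureModel(weights, model.components[:m]
                             + [comp] + model.components[m + 1:] + [new_comp])
    return new_model, model.M, log_ratio


def propose_component_combine(model: MixtureModel, m: int, m2: int,
                              cfg: ClusterMoveConfig):
    """Merge same-K components m and m2 state-by-state: each state k of the
    merged component is the stationary-probability-weighted average of the
    pair's state-k parameters; weights add.  Returns
    (new_model, merged_index, reverse_log_ratio)."""
    a, b = model.components[m], model.components[m2]
    if a.K != b.K:
        raise ValueError("combine requires components with equal state counts")
    sa = stationary_probs(a.Q)
    sb = stationary_probs(b.Q)
    u = sa / (sa + sb)  # per-state weights
    Qm = u[:, None] * a.Q + (1.0 - u[:, None]) * b.Q
    np.fill_diagonal(Qm, 0.0)
    np.fill_diagonal(Qm, -Qm.sum(axis=1))
    Bm = u[None, :] * a.B + (1.0 - u[None, :]) * b.B
    pim = u * a.pi + (1.0 - u) * b.pi
    pim = pim / pim.sum()
    merged = ThetaK(pim, Qm, Bm, GLMFamily(a.family.family, a.family.sigma))

    lo, hi = (m, m2) if m < m2 else (m2, m)
    weights = np.delete(model.weights, hi)
    w_merged = model.weights[m] + model.weights[m2]
    weights[lo] = w_merged
    comps = [c for i, c in enumerate(model.components) if i != hi]
    comps[lo] = merged
    w_rec = model.weights[m] / w_merged
    rev = float(log_beta_pdf(w_rec, 2.0, 2.0)
                + log_normal_pdf(b.B[0, :] - a.B[0, :], 0.0, cfg.c ** 2).sum()
                - np.log(w_merged))
    return MixtureModel(weights, comps), lo, rev


def _mixture_log_prior(model: MixtureModel, prior: PriorSpec,
                       k_logpmf: np.ndarray, m_logpmf: np.ndarray) -> float:
    lp = float(m_logpmf[model.M - 1])
    lp += log_dirichlet_sym(model.weights, prior.delta_mix)
    for c in model.components:
        lp += theta_log_prior(c, prior) + float(k_logpmf[c.K - 1])
    return lp


@dataclass
class ClusterState:
    """Trans-dimensional sampler state for the clustering model."""

    model: MixtureModel
    memberships: np.ndarray           # (N,), 0-based component labels
    LL: np.ndarray                    # (N, M) per-subject loglik cache
    mh: list = field(default_factory=list)

    @property
    def M_star(self) -> int:
        if self.memberships.size == 0:
            return 0
        return int(np.unique(self.memberships).size)


def init_cluster_state(packed: PackedData, family: GLMFamily,
                       prior: PriorSpec, rng: np.random.Generator,
                       sigma0: float = 1.0) -> ClusterState:
    """One component with one hidden state, parameters drawn from priors
    (coefficient draw variance capped at 1, as for the single-model
    samplers, to keep log-link predictors in floating-point range)."""
    bp = prior.beta_prior
    if bp.kind == "normal":
        from .priors import BetaCoefPrior

        bp = BetaCoefPrior("normal", bp.mean, np.minimum(bp.var, 1.0))
    B = bp.sample_column(packed.D if packed.D else 1, rng)[:, None]
    theta = ThetaK(np.ones(1), np.zeros((1, 1)), B,
                   GLMFamily(family.family, sigma0))
    model = MixtureModel(np.ones(1), [theta])
    LL = component_loglik_matrix(model, packed)
    C = np.zeros(packed.N, dtype=np.int64)
    return ClusterState(model, C, LL, mh=[MHState.fresh(1)])


def _component_move(state: ClusterState, packed: PackedData, prior: PriorSpec,
                    cfg: ClusterMoveConfig, k_logpmf, m_logpmf,
                    rng: np.random.Generator) -> dict:
    """Step (ii): split or combine whole components on the marginalized
    likelihood."""
    model = state.model
    M = model.M
    record = {"move": None, "accepted": False, "log_alpha": -np.inf}
    if cfg.Mmax == 1:
        return record
    if rng.random() < cfg.b_of(M):
        record["move"] = "comp-split"
        m = int(rng.integers(M))
        new_model, new_idx, log_ratio = propose_component_split(model, m, cfg, rng)
        # reverse combine must be able to select the pair
        m_rev = _pair_count(new_model, m, new_idx)
        if m_rev == 0:
            record["early_reject"] = True
            return record
        new_col = forward_marginal_loglik(new_model.components[new_idx],
                                          packed, per_subject=True,
                                          strict=False)
        LL_new = np.concatenate([state.LL, new_col[:, None]], axis=1)
        d_ll = mixture_marginal_loglik(new_model, packed, LL_new) \
            - mixture_marginal_loglik(model, packed, state.LL)
        d_prior = _mixture_log_prior(new_model, prior, k_logpmf, m_logpmf) \
            - _mixture_log_prior(model, prior, k_logpmf, m_logpmf)
        log_sel = np.log(m_rev) - np.log(M + 1) + np.log(M)
        log_alpha = min(0.0, np.log(cfg.d_of(M + 1)) - np.log(cfg.b_of(M))
                        + log_sel + log_ratio + d_ll + d_prior)
        record["log_alpha"] = log_alpha
        if np.log(rng.random()) < log_alpha:
            record["accepted"] = True
            state.model = new_model
            state.LL = LL_new
            state.mh.append(MHState(state.mh[m].scales.copy()))
        return record
    record["move"] = "comp-combine"
    m = int(rng.integers(M))
    m2 = _nearest_component(model, m)
    if m2 is None:  # no same-K partner: move aborts, counts as a rejection
        record["no_partner"] = True
        return record
    m_fwd = _pair_count(model, m, m2)
    try:
        new_model, lo, rev = propose_component_combine(model, m, m2, cfg)
    except ValueError as exc:
        record["diagnostic"] = str(exc)
        return record
    merged_col = forward_marginal_loglik(new_model.components[lo], packed,
                                         per_subject=True, strict=False)
    hi = max(m, m2)
    LL_new = np.delete(state.LL, hi, axis=1)
    LL_new[:, lo] = merged_col
    d_ll = mixture_marginal_loglik(new_model, packed, LL_new) \
        - mixture_marginal_loglik(model, packed, state.LL)
    d_prior = _mixture_log_prior(new_model, prior, k_logpmf, m_logpmf) \
        - _mixture_log_prior(model, prior, k_logpmf, m_logpmf)
    log_sel = -np.log(M - 1) + np.log(M) - np.log(m_fwd)
    log_alpha = min(0.0, np.log(cfg.b_of(M - 1)) - np.log(cfg.d_of(M))
                    + log_sel + rev + d_ll + d_prior)
    record["log_alpha"] = log_alpha
    if np.log(rng.random()) < log_alpha:
        record["accepted"] = True
        state.model = new_model
        state.LL = LL_new
        mh = [s for i, s in enumerate(state.mh) if i != hi]
        mh[lo] = state.mh[m].resize(new_model.components[lo].K)
        state.mh = mh
    return record


def cluster_sweep(state: ClusterState, packed: PackedData, prior: PriorSpec,
                  cluster_cfg: ClusterMoveConfig, state_cfg: MoveConfig,
                  rng: np.random.Generator, fix_sigma: bool = False):
    """One full sweep of the clustering sampler; mutates and returns
    ``state`` plus a trace record."""
    k_logpmf = prior.k_prior.log_pmf(state_cfg.Kmax)
    m_logpmf = prior.m_prior.log_pmf(cluster_cfg.Mmax)
    N = packed.N

    # (i) state split/combine inside each component, on its subjects
    k_records = []
    for m in range(state.model.M):
        sub = packed.subset(state.memberships == m) if N else packed.subset([])
        theta, rec = rj_state_step(state.model.components[m], sub, prior,
                                   state_cfg, rng, k_logpmf=k_logpmf)
        k_records.append(rec)
        if rec["accepted"]:
            state.model.components[m] = theta
            state.mh[m] = state.mh[m].resize(theta.K)
            state.LL[:, m] = forward_marginal_loglik(theta, packed,
                                                     per_subject=True,
                                                     strict=False)

    # (ii) component split/combine on the marginalized model
    comp_record = _component_move(state, packed, prior, cluster_cfg,
                                  k_logpmf, m_logpmf, rng)

    # (iii) membership resampling from the posterior probabilities
    M = state.model.M
    if N:
        W = membership_posteriors(state.model, packed, state.LL)
        c = np.cumsum(W, axis=1)
        u = rng.random(N) * c[:, -1]
        state.memberships = (c < u[:, None]).sum(axis=1).astype(np.int64)
    occupancy = np.bincount(state.memberships, minlength=M).astype(float) \
        if N else np.zeros(M)

    # (iv)+(v) fixed-dimension sweeps per component; a component with no
    # assigned subjects reduces to a draw from the prior
    for m in range(M):
        sub = packed.subset(state.memberships == m) if N else packed.subset([])
        theta, _, mh = fixed_k_sweep(state.model.components[m], sub, prior,
                                     rng, mh=state.mh[m], fix_sigma=fix_sigma)
        state.model.components[m] = theta
        state.mh[m] = mh
        state.LL[:, m] = forward_marginal_loglik(theta, packed,
                                                 per_subject=True,
                                                 strict=False)

    # weights by Dirichlet conjugacy
    state.model.weights = rng.dirichlet(prior.delta_mix + occupancy)

    record = {
        "M": M,
        "M_star": state.M_star,
        "K": state.model.state_counts(),
        "weights": state.model.weights.tolist(),
        "component_move": comp_record,
        "state_moves": k_records,
        "occupancy": occupancy.astype(int).tolist(),
    }
    return state, record
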