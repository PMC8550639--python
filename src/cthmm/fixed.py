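"""Fixed-dimension MCMC sweep for the CTHMM-GLM.

One sweep, in the order: (i) impute latent paths given the current
parameters -- forward-filtering backward-sampling of the state skeleton at
the observation times, then exact endpoint-conditioned bridges over every
inter-observation interval, reduced to CTMC sufficient statistics; (ii)
update the GLM coefficients B (conjugate multivariate-normal draws per state
for the normal-identity family, adaptive random-walk Metropolis for the
poisson-log family) and the dispersion sigma; (iii) update the initial law
pi by Dirichlet conjugacy; (iv) update the generator Q by Gamma conjugacy,
q_ij | . ~ Gamma(a + N_ij, b + T_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._pathstats import interval_stats
from .ctmc import GeneratorMatrix, LatentPath, sample_conditioned_path
from .model import (GLMFamily, PackedData, Subject, ThetaK, forward_filter,
                    pack_subjects)
from .priors import PriorSpec

__all__ = [
    "SufficientStats",
    "MHState",
    "ffbs_states",
    "impute_stats",
    "impute_paths",
    "update_Q",
    "update_pi",
    "update_B",
    "fixed_k_sweep",
]


@dataclass
class SufficientStats:
    """CTMC sufficient statistics from imputed latent paths plus the state
    skeleton at observation times (-1 marks padding)."""

    n_trans: np.ndarray     # (K, K), N_ij
    dwell: np.ndarray       # (K,), T_i
    init_counts: np.ndarray  # (K,)
    obs_states: np.ndarray  # (N, Tmax), 0-based, -1 padded

    def validate(self) -> None:
        if np.any(np.diag(self.n_trans) != 0):
            raise ValueError("diagonal transition counts must be zero")
        if self.dwell.min() < 0:
            raise ValueError("dwell times must be non-negative")


@dataclass
class MHState:
    """Adaptive random-walk state for the poisson-log coefficient update.

    Proposal scales adapt on a diminishing schedule towards an acceptance
    rate around 0.3 (within the targeted 0.2-0.5 band)."""

    scales: np.ndarray
    n_updates: int = 0
    accepted: int = 0
    proposed: int = 0

    @classmethod
    def fresh(cls, K: int, scale: float = 0.5) -> "MHState":
        return cls(np.full(K, scale))

    def resize(self, K: int) -> "MHState":
        if self.scales.size == K:
            return self
        scales = np.full(K, float(np.median(self.scales)))
        scales[: min(K, self.scales.size)] = self.scales[: min(K, self.scales.size)]
        return MHState(scales, self.n_updates, self.accepted, self.proposed)


def ffbs_states(theta: ThetaK, packed: PackedData, rng: np.random.Generator,
                alphas=None, P=None) -> np.ndarray:
    """Joint draw of the latent states at all observation times, by
    forward-filtering backward-sampling over the discrete skeleton with
    interval transition matrices.  Returns (N, Tmax) 0-based states, -1
    padded."""
    if alphas is None or P is None:
        _, alphas, P = forward_filter(theta, packed)
    N, Tmax, K = alphas.shape
    S = np.full((N, Tmax), -1, dtype=np.int64)
    if N == 0:
        return S
    last = packed.lengths - 1
    W = alphas[np.arange(N), last]
    S[np.arange(N), last] = _categorical_rows(W, rng)
    for t in range(Tmax - 2, -1, -1):
        act = np.where(packed.lengths > t + 1)[0]
        if act.size == 0:
            continue
        s_next = S[act, t + 1]
        Psub = P[act, t]
        back = np.take_along_axis(
            Psub, s_next[:, None, None] * np.ones((1, K, 1), dtype=np.int64),
            axis=2)[:, :, 0]
        W = alphas[act, t] * back
        S[act, t] = _categorical_rows(W, rng)
    return S


def _categorical_rows(W: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    c = np.cumsum(W, axis=1)
    tot = c[:, -1]
    if np.any(tot <= 0):
        raise FloatingPointError("degenerate backward-sampling weights")
    u = rng.random(W.shape[0]) * tot
    return (c < u[:, None]).sum(axis=1)


def impute_stats(theta: ThetaK, packed: PackedData, rng: np.random.Generator,
                 alphas=None, P=None) -> SufficientStats:
    """Draw latent paths from p(path | O, Theta) and reduce them to
    sufficient statistics in one pass."""
    K = theta.K
    S = ffbs_states(theta, packed, rng, alphas=alphas, P=P)
    if packed.N == 0:
        return SufficientStats(np.zeros((K, K)), np.zeros(K), np.zeros(K), S)
    init_counts = np.bincount(S[:, 0], minlength=K).astype(float)
    valid = (np.arange(packed.Tmax - 1)[None, :]
             < (packed.lengths - 1)[:, None]) if packed.Tmax > 1 else \
        np.zeros((packed.N, 0), dtype=bool)
    a = S[:, :-1][valid]
    b = S[:, 1:][valid]
    dt = packed.gaps[:, : max(packed.Tmax - 1, 1)][valid] \
        if packed.Tmax > 1 else np.zeros(0)
    ntrans, dwell = interval_stats(theta.Q, a, b, dt, rng)
    return SufficientStats(ntrans, dwell, init_counts, S)


def impute_paths(theta: ThetaK, data: list[Subject],
                 rng: np.random.Generator) -> list[LatentPath]:
    """Full latent trajectories from their joint conditional law given the
    observations: an FFBS skeleton draw stitched together with exact
    endpoint-conditioned bridges on every inter-observation interval."""
    packed = pack_subjects(data)
    S = ffbs_states(theta, packed, rng)
    paths = []
    for n, subj in enumerate(data):
        T = subj.T
        states = [int(S[n, 0]) + 1]
        times = [0.0]
        for t in range(T - 1):
            seg = sample_conditioned_path(
                theta.Q, int(S[n, t]) + 1, int(S[n, t + 1]) + 1,
                float(subj.times[t + 1] - subj.times[t]), rng)
            for s, tt in zip(seg.states[1:], seg.times[1:]):
                states.append(int(s))
                times.append(float(subj.times[t] + tt))
        horizon = float(subj.times[-1]) if T > 1 else 0.0
        paths.append(LatentPath(horizon, np.asarray(states), np.asarray(times)))
    return paths


def update_Q(stats: SufficientStats, prior: PriorSpec,
             rng: np.random.Generator, K: int | None = None) -> np.ndarray:
    """Conjugate generator draw: q_ij | . ~ Gamma(a + N_ij, b + T_i)."""
    K = stats.dwell.size if K is None else K
    if K == 1:
        return np.zeros((1, 1))
    shape = prior.q_shape + stats.n_trans
    rate = prior.q_rate + stats.dwell[:, None]
    q = rng.gamma(shape, 1.0 / rate)
    return GeneratorMatrix.from_offdiag(q).rates


def update_pi(init_counts: np.ndarray, prior: PriorSpec,
              rng: np.random.Generator) -> np.ndarray:
    """Conjugate initial-law draw: pi | . ~ Dirichlet(delta + init counts)."""
    return rng.dirichlet(prior.pi_dirichlet + np.asarray(init_counts, dtype=float))


def _normal_column_draw(X, y, sigma2, prior, rng, D):
    m0 = np.broadcast_to(np.asarray(prior.beta_prior.mean, dtype=float), (D,))
    v0 = np.broadcast_to(np.asarray(prior.beta_prior.var, dtype=float), (D,))
    prec = np.diag(1.0 / v0) + X.T @ X / sigma2
    # proper prior keeps this nonsingular even for states with < D observations
    L = np.linalg.cholesky(prec)
    rhs = m0 / v0 + X.T @ y / sigma2
    mean = np.linalg.solve(prec, rhs)
    z = rng.standard_normal(D)
    return mean + np.linalg.solve(L.T, z)


def update_B(theta: ThetaK, stats: SufficientStats, packed: PackedData,
             prior: PriorSpec, rng: np.random.Generator,
             mh: MHState | None = None, fix_sigma: bool = False,
             adapt: bool = True):
    """Observation-process update.

    normal-identity: per-state conjugate multivariate-normal coefficient
    draws given sigma, followed by an inverse-gamma draw of sigma^2 from its
    full conditional.  poisson-log: per-state random-walk Metropolis with
    diminishing adaptation of the proposal scale.  States with no assigned
    observations are refreshed from the prior.

    Returns (B, sigma, mh_state).
    """
    K, D = theta.K, theta.D
    B = theta.B.copy()
    sigma = theta.family.sigma
    obs_mask = stats.obs_states >= 0
    normal = theta.family.family == "normal"
    if mh is None:
        mh = MHState.fresh(K)
    mh = mh.resize(K)
    rss = 0.0
    ntot = 0
    for k in range(K):
        sel = obs_mask & (stats.obs_states == k)
        nk = int(sel.sum())
        if nk == 0:
            B[:, k] = prior.beta_prior.sample_column(D, rng)
            continue
        X = packed.Z[sel]
        y = packed.obs[sel]
        if normal:
            B[:, k] = _normal_column_draw(X, y, sigma ** 2, prior, rng, D)
            resid = y - X @ B[:, k]
            rss += float(resid @ resid)
            ntot += nk
        else:
            beta = B[:, k]
            eta = X @ beta
            cur = float(y @ eta - np.exp(eta).sum()) \
                + prior.beta_prior.logpdf_column(beta)
            prop = beta + mh.scales[k] * rng.standard_normal(D)
            eta_p = X @ prop
            with np.errstate(over="ignore"):
                new = float(y @ eta_p - np.exp(eta_p).sum()) \
                    + prior.beta_prior.logpdf_column(prop)
            mh.proposed += 1
            acc_prob = float(np.exp(min(0.0, new - cur))) if np.isfinite(new) else 0.0
            if rng.random() < acc_prob:
                B[:, k] = prop
                mh.accepted += 1
            if adapt:
                mh.n_updates += 1
                step = min(0.1, 2.0 / np.sqrt(mh.n_updates))
                mh.scales[k] = float(np.clip(
                    mh.scales[k] * np.exp(step * (acc_prob - 0.3)), 1e-3, 50.0))
    if normal and not fix_sigma:
        shape = prior.sigma_shape + 0.5 * ntot
        scale = prior.sigma_scale + 0.5 * rss
        # tiny shapes (the weak prior with no data) can underflow to 0
        g = max(rng.gamma(shape), 1e-300)
        sigma = float(min(np.sqrt(scale / g), 1e150))
    return B, sigma, mh


def fixed_k_sweep(theta: ThetaK, packed: PackedData, prior: PriorSpec,
                  rng: np.random.Generator, mh: MHState | None = None,
                  fix_sigma: bool = False, adapt: bool = True,
                  alphas=None, P=None):
    """One full fixed-K sweep: paths, B (and sigma), pi, Q.

    Returns (new_theta, stats, mh_state)."""
    stats = impute_stats(theta, packed, rng, alphas=alphas, P=P)
    B, sigma, mh = update_B(theta, stats, packed, prior, rng, mh=mh,
                            fix_sigma=fix_sigma, adapt=adapt)
    pi = update_pi(stats.init_counts, prior, rng)
    Q = update_Q(stats, prior, rng, K=theta.K)
    new_theta = ThetaK(pi, Q, B, GLMFamily(theta.family.family, sigma))
    return new_theta, stats, mh
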