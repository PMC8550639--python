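"""CTHMM-GLM observation model and likelihoods.

A subject's outcomes O_1..O_T at irregular times tau_1..tau_T (tau_1 = 0)
are emitted by a GLM whose linear predictor depends on the latent CTMC state
at the observation time: state k has coefficient column beta_k, so
g(E[O_t | X_t = k]) = z_t' beta_k.  Two exponential-family members are
implemented: the normal-identity family with a shared dispersion sigma, and
the poisson-log family for counts.

Two likelihoods are exposed:

* ``complete_data_loglik`` -- the joint density of outcomes and the full
  latent trajectory (initial state, exponential dwell times, jump rates,
  emissions); this is what the fixed-dimension parameter updates condition
  on once latent paths are imputed.
* ``forward_marginal_loglik`` -- the observed-data likelihood with latent
  paths integrated out, computed by the forward recursion with interval
  transition matrices exp(Q * dt) and per-step scaling so that it cannot
  underflow for long records.  Trans-dimensional acceptance ratios are
  evaluated on this quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .ctmc import GeneratorMatrix, LatentPath, transition_matrices

__all__ = [
    "GLMFamily",
    "CoefficientMatrix",
    "Subject",
    "ThetaK",
    "PackedData",
    "pack_subjects",
    "glm_logdensity",
    "emission_logdensities",
    "complete_data_loglik",
    "forward_marginal_loglik",
    "forward_filter",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GLMFamily:
    """Exponential-family emission model: 'normal' (identity link, shared
    dispersion sigma) or 'poisson' (log link)."""

    family: str
    sigma: float = 1.0

    def validate(self) -> None:
        if self.family not in ("normal", "poisson"):
            raise ValueError("family must be 'normal' or 'poisson'")
        if self.family == "normal" and not self.sigma > 0:
            raise ValueError("normal dispersion sigma must be > 0")


@dataclass
class CoefficientMatrix:
    """D x K GLM coefficient matrix; row 1 is the intercept, column k the
    state-k linear predictor."""

    betas: np.ndarray

    def __post_init__(self):
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))

    @property
    def D(self) -> int:
        return self.betas.shape[0]

    @property
    def K(self) -> int:
        return self.betas.shape[1]

    def validate(self) -> None:
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("coefficients must be finite")


@dataclass
class Subject:
    """One subject's record: strictly increasing times (first = 0), outcomes,
    and a T x D covariate matrix whose first column is the intercept."""

    times: np.ndarray
    outcomes: np.ndarray
    Z: np.ndarray
    subject_id: object = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))

    @property
    def T(self) -> int:
        return self.times.size

    def validate(self) -> None:
        if self.times.size != self.outcomes.size or self.Z.shape[0] != self.times.size:
            raise ValueError("times, outcomes and covariate rows must align")
        if self.times.size < 1:
            raise ValueError("each subject needs at least one observation")
        if self.times[0] != 0.0:
            raise ValueError("first observation time must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if not np.allclose(self.Z[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (== 1)")


@dataclass
class ThetaK:
    """Full parameter block at a given number of states K:
    initial law pi, generator Q, coefficient matrix B (D x K), and family."""

    pi: np.ndarray
    Q: np.ndarray
    B: np.ndarray
    family: GLMFamily

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))

    @property
    def K(self) -> int:
        return self.pi.size

    @property
    def D(self) -> int:
        return self.B.shape[0]

    def validate(self) -> None:
        K = self.K
        if self.Q.shape != (K, K) or self.B.shape[1] != K:
            raise ValueError("pi, Q and B dimensions are inconsistent")
        if abs(self.pi.sum() - 1.0) > 1e-8 or self.pi.min() < 0:
            raise ValueError("pi must lie on the probability simplex")
        GeneratorMatrix(self.Q)  # validates generator structure
        CoefficientMatrix(self.B).validate()
        self.family.validate()

    def copy(self) -> "ThetaK":
        return ThetaK(
            self.pi.copy(), self.Q.copy(), self.B.copy(),
            GLMFamily(self.family.family, self.family.sigma),
        )


def glm_logdensity(o, z, beta_k, family: GLMFamily):
    """Log emission density of outcome(s) o given covariates z in state k.

    normal-identity: log N(o; z' beta_k, sigma^2);
    poisson-log:     log Poisson(o; exp(z' beta_k)).
    """
    o = np.asarray(o, dtype=float)
    z = np.asarray(z, dtype=float)
    beta_k = np.asarray(beta_k, dtype=float)
    eta = z @ beta_k
    if family.family == "normal":
        s2 = family.sigma ** 2
        return -0.5 * (_LOG2PI + np.log(s2)) - 0.5 * (o - eta) ** 2 / s2
    if np.any(o < 0) or np.any(o != np.floor(o)):
        raise ValueError("poisson outcomes must be non-negative integers")
    return o * eta - np.exp(eta) - gammaln(o + 1.0)


@dataclass
class PackedData:
    """Ragged subject records padded to rectangular arrays for batched
    likelihood evaluation (padding masked by ``lengths``)."""

    obs: np.ndarray       # (N, Tmax)
    Z: np.ndarray         # (N, Tmax, D)
    gaps: np.ndarray      # (N, Tmax - 1), 0-padded
    lengths: np.ndarray   # (N,)
    subject_ids: list

    @property
    def N(self) -> int:
        return self.obs.shape[0]

    @property
    def Tmax(self) -> int:
        return self.obs.shape[1]

    @property
    def D(self) -> int:
        return self.Z.shape[2]

    def subset(self, idx) -> "PackedData":
        """Row (subject) subset as a new packed dataset (views where
        possible)."""
        idx = np.asarray(idx, dtype=np.int64) if np.asarray(idx).size == 0 \
            else np.asarray(idx)
        if idx.dtype == bool:
            idx = np.where(idx)[0]
        return PackedData(self.obs[idx], self.Z[idx], self.gaps[idx],
                          self.lengths[idx],
                          [self.subject_ids[int(i)] for i in idx])


def pack_subjects(subjects: list[Subject]) -> PackedData:
    N = len(subjects)
    if N == 0:
        return PackedData(
            np.zeros((0, 1)), np.zeros((0, 1, 1)), np.zeros((0, 0)),
            np.zeros(0, dtype=np.int64), [],
        )
    Tmax = max(s.T for s in subjects)
    D = subjects[0].Z.shape[1]
    obs = np.zeros((N, Tmax))
    Z = np.zeros((N, Tmax, D))
    Z[:, :, 0] = 1.0
    gaps = np.zeros((N, max(Tmax - 1, 1)))
    lengths = np.zeros(N, dtype=np.int64)
    ids = []
    for n, s in enumerate(subjects):
        T = s.T
        obs[n, :T] = s.outcomes
        Z[n, :T] = s.Z
        if T > 1:
            gaps[n, : T - 1] = np.diff(s.times)
        lengths[n] = T
        ids.append(s.subject_id if s.subject_id is not None else n + 1)
    return PackedData(obs, Z, gaps, lengths, ids)


def emission_logdensities(theta: ThetaK, packed: PackedData) -> np.ndarray:
    """Per-observation, per-state log emission densities, shape (N, Tmax, K);
    padded slots are 0."""
    eta = np.einsum("ntd,dk->ntk", packed.Z, theta.B)
    if theta.family.family == "normal":
        s2 = theta.family.sigma ** 2
        ll = -0.5 * (_LOG2PI + np.log(s2)) \
            - 0.5 * (packed.obs[:, :, None] - eta) ** 2 / s2
    else:
        o = packed.obs[:, :, None]
        with np.errstate(over="ignore"):
            ll = o * eta - np.exp(eta) - gammaln(packed.obs + 1.0)[:, :, None]
    mask = np.arange(packed.Tmax)[None, :] < packed.lengths[:, None]
    ll[~mask] = 0.0
    return ll


def _interval_transitions(theta: ThetaK, packed: PackedData) -> np.ndarray:
    """Transition matrices for every inter-observation gap, (N, Tmax-1, K, K)."""
    K = theta.K
    if packed.Tmax == 1 or packed.N == 0:
        return np.zeros((packed.N, 0, K, K))
    flat = packed.gaps.ravel()
    P = transition_matrices(theta.Q, flat)
    return P.reshape(packed.N, packed.gaps.shape[1], K, K)


def forward_filter(theta: ThetaK, packed: PackedData, P=None, ll=None,
                   strict: bool = True):
    """Scaled forward recursion over all subjects simultaneously.

    Returns ``(loglik_per_subject, alphas, P)`` where ``alphas[n, t]`` is the
    normalised filtering distribution of the state at observation t and ``P``
    the interval transition matrices (reusable for backward sampling).

    With ``strict=True`` a vanished or non-finite forward mass raises,
    naming the subject and step; with ``strict=False`` such subjects get
    log-likelihood -inf (used when scoring subjects under arbitrary mixture
    components, where an extreme component must yield probability 0, never
    NaN).
    """
    if P is None:
        P = _interval_transitions(theta, packed)
    if ll is None:
        ll = emission_logdensities(theta, packed)
    N, Tmax, K = ll.shape
    alphas = np.zeros((N, Tmax, K))
    loglik = np.zeros(N)
    if N == 0:
        return loglik, alphas, P
    alive = np.ones(N, dtype=bool)

    def _degenerate(rows, step):
        if strict:
            bad = int(rows[0])
            raise FloatingPointError(
                f"forward recursion degenerate for subject "
                f"{packed.subject_ids[bad]} at step {step}"
            )
        loglik[rows] = -np.inf
        alive[rows] = False

    m0 = ll[:, 0, :].max(axis=1)
    with np.errstate(invalid="ignore"):
        a = theta.pi[None, :] * np.exp(ll[:, 0, :] - m0[:, None])
    s = a.sum(axis=1)
    bad = np.where(~np.isfinite(s) | (s <= 0))[0]
    if bad.size:
        _degenerate(bad, 1)
    ok = alive
    loglik[ok] += m0[ok] + np.log(s[ok])
    alphas[ok, 0, :] = a[ok] / s[ok, None]
    for t in range(1, Tmax):
        act = np.where((packed.lengths > t) & alive)[0]
        if act.size == 0:
            continue
        a = np.einsum("nj,njk->nk", alphas[act, t - 1], P[act, t - 1])
        mt = ll[act, t, :].max(axis=1)
        with np.errstate(invalid="ignore"):
            a = a * np.exp(ll[act, t, :] - mt[:, None])
        s = a.sum(axis=1)
        badloc = np.where(~np.isfinite(s) | (s <= 0))[0]
        if badloc.size:
            _degenerate(act[badloc], t + 1)
            keep = np.setdiff1d(np.arange(act.size), badloc)
            act, a, mt, s = act[keep], a[keep], mt[keep], s[keep]
            if act.size == 0:
                continue
        loglik[act] += mt + np.log(s)
        alphas[act, t, :] = a / s[:, None]
    return loglik, alphas, P


def forward_marginal_loglik(theta: ThetaK, data, per_subject: bool = False,
                            strict: bool = True):
    """Observed-data log-likelihood with latent paths integrated out.

    ``data`` may be a list of ``Subject`` or an already-packed dataset.
    """
    packed = data if isinstance(data, PackedData) else pack_subjects(data)
    loglik, _, _ = forward_filter(theta, packed, strict=strict)
    return loglik if per_subject else float(loglik.sum())


def complete_data_loglik(theta: ThetaK, paths: list[LatentPath],
                         data: list[Subject]) -> float:
    """Joint log density of outcomes and full latent trajectories.

    Per subject: log pi at the initial state, plus log jump rates for each
    transition, plus q_ii * (dwell time) for the exponential sojourns over
    the path's window, plus the emission terms at the observation times.
    """
    if len(paths) != len(data):
        raise ValueError("one latent path per subject is required")
    total = 0.0
    Q = theta.Q
    fam = theta.family
    for path, subj in zip(paths, data):
        if path.horizon < subj.times[-1] - 1e-12:
            raise ValueError(
                f"latent path (horizon {path.horizon}) does not cover subject "
                f"{subj.subject_id}'s observation window [0, {subj.times[-1]}]"
            )
        st = path.states - 1
        if st.max() >= theta.K:
            raise ValueError("path states exceed the model's state count")
        total += np.log(theta.pi[st[0]])
        seg_ends = np.append(path.times[1:], path.horizon)
        dwell = seg_ends - path.times
        total += float(np.sum(np.diag(Q)[st] * dwell))
        if st.size > 1:
            total += float(np.sum(np.log(Q[st[:-1], st[1:]])))
        obs_states = path.state_at(subj.times) - 1
        for t in range(subj.T):
            total += float(glm_logdensity(
                subj.outcomes[t], subj.Z[t], theta.B[:, obs_states[t]], fam))
    return total
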