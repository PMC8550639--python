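"""Continuous-time Markov chain primitives.

A CTMC on the finite state space {1, ..., K} is parameterised by its
infinitesimal generator Q: off-diagonal entries q_ij >= 0 are instantaneous
jump rates and each diagonal entry is minus the row's off-diagonal sum, so
rows sum to zero.  This module provides the operations the samplers are
built on: stationary laws, interval transition probabilities exp(Q*dt),
exact (Gillespie) path simulation, and exact endpoint-conditioned path
simulation, which is what latent-path imputation between irregularly spaced
observations requires.

States are labelled 1..K in all public inputs and outputs; internal
computations are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GeneratorMatrix",
    "LatentPath",
    "StationaryDistribution",
    "stationary_distribution",
    "transition_probability",
    "transition_matrices",
    "simulate_ctmc",
    "sample_conditioned_path",
]

_ROWSUM_TOL = 1e-10


def _as_generator_array(Q) -> np.ndarray:
    if isinstance(Q, GeneratorMatrix):
        return Q.rates
    return np.asarray(Q, dtype=float)


@dataclass
class GeneratorMatrix:
    """K x K infinitesimal generator of a CTMC (rates in events per unit time)."""

    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.validate()

    @property
    def K(self) -> int:
        return self.rates.shape[0]

    @classmethod
    def from_offdiag(cls, rates) -> "GeneratorMatrix":
        """Build a generator from a matrix whose off-diagonal entries are the
        jump rates; the diagonal is overwritten with minus the row sums."""
        R = np.asarray(rates, dtype=float).copy()
        np.fill_diagonal(R, 0.0)
        np.fill_diagonal(R, -R.sum(axis=1))
        return cls(R)

    def validate(self) -> None:
        R = self.rates
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 1:
            raise ValueError("generator must be a square K x K matrix with K >= 1")
        off = R[~np.eye(R.shape[0], dtype=bool)]
        if off.size and off.min() < 0:
            raise ValueError("off-diagonal generator entries must be >= 0")
        if np.abs(R.sum(axis=1)).max() > _ROWSUM_TOL:
            raise ValueError("generator rows must sum to zero (tolerance 1e-10)")

    def exit_rates(self) -> np.ndarray:
        return -np.diag(self.rates)


@dataclass
class LatentPath:
    """A complete continuous-time trajectory on [0, horizon].

    ``states`` holds the visited states (1-based labels) and ``times`` the
    entry time of each segment; ``times[0] == 0`` and consecutive states
    differ.  The path occupies ``states[-1]`` from ``times[-1]`` to
    ``horizon``.
    """

    horizon: float
    states: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)

    def validate(self) -> None:
        if self.states.shape != self.times.shape or self.states.size < 1:
            raise ValueError("states and times must be equal-length, non-empty")
        if self.times[0] != 0.0:
            raise ValueError("first entry time must be 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("entry times must be strictly increasing")
        if np.any(self.times >= self.horizon):
            if not (self.times.size == 1 and self.times[0] == 0.0):
                raise ValueError("all entry times must lie inside [0, horizon)")
        if np.any(self.states[1:] == self.states[:-1]):
            raise ValueError("consecutive states must differ")
        if self.states.min() < 1:
            raise ValueError("states are labelled 1..K")

    @property
    def n_jumps(self) -> int:
        return self.states.size - 1

    def state_at(self, t) -> np.ndarray:
        """State occupied at time(s) t (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return self.states[np.clip(idx, 0, self.states.size - 1)]


@dataclass
class StationaryDistribution:
    """Stationary law s of an irreducible CTMC: s Q = 0, sum(s) = 1."""

    probs: np.ndarray
    _Q: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)

    def validate(self) -> None:
        s = self.probs
        if s.min() < 0:
            raise ValueError("stationary probabilities must be non-negative")
        if abs(s.sum() - 1.0) > 1e-10:
            raise ValueError("stationary probabilities must sum to 1 (tol 1e-10)")
        if self._Q is not None and np.abs(s @ self._Q).max() > 1e-8:
            raise ValueError("s Q = 0 violated beyond tolerance 1e-8")


def _is_irreducible(R: np.ndarray) -> bool:
    K = R.shape[0]
    if K == 1:
        return True
    adj = csr_matrix((R > 0).astype(np.int8))
    n, _ = connected_components(adj, directed=True, connection="strong")
    return n == 1


def stationary_probs(Q) -> np.ndarray:
    """Stationary probabilities as a plain array (see stationary_distribution)."""
    R = _as_generator_array(Q)
    K = R.shape[0]
    if K == 1:
        return np.ones(1)
    if not _is_irreducible(R):
        raise ValueError(
            "generator is reducible (or has an absorbing state): "
            "no unique stationary law"
        )
    # Solve s Q = 0 with sum(s) = 1 as an overdetermined least-squares system.
    A = np.vstack([R.T, np.ones(K)])
    rhs = np.zeros(K + 1)
    rhs[-1] = 1.0
    s, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    s = np.clip(s, 0.0, None)
    return s / s.sum()


def stationary_distribution(Q) -> StationaryDistribution:
    """Stationary law of an irreducible generator.

    Raises ``ValueError`` when the generator has more than one closed
    communicating class (equivalently, when no unique stationary law exists).
    """
    R = _as_generator_array(Q)
    out = StationaryDistribution(stationary_probs(R), _Q=R)
    out.validate()
    return out


def transition_probability(Q, dt: float) -> np.ndarray:
    """Interval transition matrix P(dt) = exp(Q * dt).

    Computed by scaling-and-squaring; valid for defective generators.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    R = _as_generator_array(Q)
    if dt == 0.0:
        return np.eye(R.shape[0])
    return expm(R * dt)


def transition_matrices(Q, dts: np.ndarray) -> np.ndarray:
    """exp(Q * dt) for a whole vector of gaps at once.

    Uses an eigendecomposition of Q when it is numerically safe (the common
    case for the small dense generators handled here), falling back to
    per-gap scaling-and-squaring otherwise.  Returns an array of shape
    ``(len(dts), K, K)``.
    """
    R = _as_generator_array(Q)
    dts = np.asarray(dts, dtype=float)
    K = R.shape[0]
    if K == 1:
        return np.ones((dts.size, 1, 1))
    use_eig = False
    try:
        w, V = np.linalg.eig(R)
        condV = np.linalg.cond(V)
        if np.isfinite(condV) and condV < 1e8:
            Vinv = np.linalg.inv(V)
            use_eig = True
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass
    if use_eig:
        E = np.exp(np.multiply.outer(dts, w))  # (G, K)
        P = np.einsum("ik,gk,kj->gij", V, E, Vinv).real
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P
    return np.stack([expm(R * dt) if dt > 0 else np.eye(K) for dt in dts])


def simulate_ctmc(Q, pi, horizon: float, rng: np.random.Generator) -> LatentPath:
    """Exact (Gillespie) simulation of a CTMC path on [0, horizon].

    The initial state is drawn from ``pi``; holding times in state i are
    Exponential(-q_ii) and jumps go to j != i with probability q_ij / (-q_ii).
    """
    R = _as_generator_array(Q)
    pi = np.asarray(pi, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if abs(pi.sum() - 1.0) > 1e-8 or pi.min() < 0:
        raise ValueError("pi must lie on the probability simplex")
    K = R.shape[0]
    exit_rates = -np.diag(R)
    state = int(rng.choice(K, p=pi / pi.sum()))
    states = [state]
    times = [0.0]
    t = 0.0
    while True:
        r = exit_rates[state]
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= horizon:
            break
        probs = R[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(K, p=probs / probs.sum()))
        states.append(state)
        times.append(t)
    return LatentPath(horizon, np.asarray(states) + 1, np.asarray(times))


def _forward_from(R, exit_rates, state, t0, dt, rng):
    """Continue Gillespie simulation from ``state`` at time t0 until dt.

    Returns (states, times, end_state) with 0-based states, times relative to
    the interval origin."""
    states = [state]
    times = [t0]
    t = t0
    while True:
        r = exit_rates[state]
        if r <= 0:
            break
        t += rng.exponential(1.0 / r)
        if t >= dt:
            break
        probs = R[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(R.shape[0], p=probs / probs.sum()))
        states.append(state)
        times.append(t)
    return states, times, state


def _uniformization_path(R, a, b, dt, rng, trunc_tol=1e-12, nmax=500):
    """Exact endpoint-conditioned draw via uniformization.

    The CTMC on [0, dt] conditioned on X_0 = a, X_dt = b is realised as a
    dominating Poisson process of potential jumps with rate mu = max exit
    rate, with transitions governed by R_u = I + Q/mu (self-transitions are
    'virtual' and removed at the end).
    """
    K = R.shape[0]
    mu = float(np.max(-np.diag(R)))
    if mu <= 0:
        return [a], [0.0]
    Ru = np.eye(K) + R / mu
    lam = mu * dt
    # accumulate Poisson(lam) weighted powers of Ru until the tail is negligible
    powers = [np.eye(K)]
    log_w = -lam
    weights = [np.exp(log_w) * powers[0][a, b]]
    pois_cdf = np.exp(-lam)
    n = 0
    while pois_cdf < 1 - trunc_tol and n < nmax:
        n += 1
        powers.append(powers[-1] @ Ru)
        log_w += np.log(lam) - np.log(n)
        weights.append(np.exp(log_w) * powers[n][a, b])
        pois_cdf += np.exp(log_w)
    weights = np.asarray(weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"endpoint pair ({a + 1} -> {b + 1}) has numerically zero "
            f"probability over dt={dt}"
        )
    njump = int(rng.choice(len(weights), p=weights / total))
    # sample the dominated state sequence bridge
    seq = [a]
    for i in range(1, njump):
        probs = Ru[seq[-1]] * powers[njump - i][:, b]
        seq.append(int(rng.choice(K, p=probs / probs.sum())))
    if njump >= 1:
        seq.append(b)
    jump_times = np.sort(rng.uniform(0.0, dt, size=njump))
    # strip virtual self-transitions
    states = [seq[0]]
    times = [0.0]
    for s, t in zip(seq[1:], jump_times):
        if s != states[-1]:
            states.append(s)
            times.append(float(t))
    return states, times


def sample_conditioned_path(
    Q, a: int, b: int, dt: float, rng: np.random.Generator,
    max_rejection_trials: int = 256,
) -> LatentPath:
    """Exact draw of a CTMC path on [0, dt] given X_0 = a and X_dt = b.

    Uses rejection sampling (direct when a == b; modified -- conditioning on
    at least one jump -- when a != b), switching to uniformization when the
    probe batch of rejection trials produces no acceptance, which bounds the
    runtime for unlikely endpoint pairs.  States are 1-based.
    """
    R = _as_generator_array(Q)
    K = R.shape[0]
    if not (1 <= a <= K and 1 <= b <= K):
        raise ValueError("endpoint states must lie in 1..K")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    a0, b0 = a - 1, b - 1
    if dt == 0.0:
        if a != b:
            raise ValueError(
                f"endpoint pair ({a} -> {b}) is infeasible over dt=0"
            )
        return LatentPath(dt, np.array([a]), np.array([0.0]))
    pab = transition_probability(R, dt)[a0, b0]
    if pab <= 1e-300:
        raise ValueError(
            f"endpoint pair ({a} -> {b}) has numerically zero probability "
            f"over dt={dt}"
        )
    exit_rates = -np.diag(R)
    for _ in range(max_rejection_trials):
        if a0 == b0:
            states, times, end = _forward_from(R, exit_rates, a0, 0.0, dt, rng)
        else:
            r = exit_rates[a0]
            if r <= 0:
                break
            # first jump from a truncated Exponential(r) on (0, dt)
            u = rng.uniform()
            t1 = -np.log1p(-u * (1.0 - np.exp(-r * dt))) / r
            probs = R[a0].copy()
            probs[a0] = 0.0
            s1 = int(rng.choice(K, p=probs / probs.sum()))
            states, times, end = _forward_from(R, exit_rates, s1, t1, dt, rng)
            states = [a0] + states
            times = [0.0] + times
        if end == b0:
            return LatentPath(dt, np.asarray(states) + 1, np.asarray(times))
    states, times = _uniformization_path(R, a0, b0, dt, rng)
    return LatentPath(dt, np.asarray(states) + 1, np.asarray(times))
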