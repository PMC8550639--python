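"""Batched endpoint-conditioned sufficient statistics.

Latent-path imputation only feeds the parameter updates through the CTMC
sufficient statistics (transition counts N_ij and dwell times T_i), so the
per-interval bridges between consecutive observation states are sampled
here by uniformization -- an exact construction of the endpoint-conditioned
law via a dominating Poisson process with rate mu = max exit rate and
transition kernel R = I + Q/mu -- and immediately reduced to those
statistics.  The kernel is JIT-compiled with numba when available; the pure
Python path runs the identical code.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


_NMAX_CAP = 400


def build_uniformization(Q: np.ndarray, max_dt: float):
    """Precompute (mu, R, Rpow) for a generator; Rpow[n] = R^n up to a jump
    count that covers the Poisson(mu * max_dt) distribution far into the
    tail."""
    K = Q.shape[0]
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return 0.0, np.eye(K), np.eye(K)[None, :, :]
    R = np.eye(K) + Q / mu
    lam = mu * max_dt
    nmax = int(min(_NMAX_CAP, np.ceil(lam + 12.0 * np.sqrt(lam + 1.0) + 25)))
    Rpow = np.empty((nmax + 1, K, K))
    Rpow[0] = np.eye(K)
    for n in range(1, nmax + 1):
        Rpow[n] = Rpow[n - 1] @ R
    return mu, R, Rpow


@njit(cache=True)
def _interval_stats_kernel(R, Rpow, mu, a, b, dt, seed):  # pragma: no cover
    np.random.seed(seed)
    K = R.shape[0]
    nmax = Rpow.shape[0] - 1
    ntrans = np.zeros((K, K))
    dwell = np.zeros(K)
    cum = np.empty(nmax + 1)
    seq = np.empty(nmax + 1, dtype=np.int64)
    for it in range(a.shape[0]):
        ai = a[it]
        bi = b[it]
        lam = mu * dt[it]
        # jump-count distribution: w_n = Pois(lam)(n) * [R^n]_{a,b}
        w = np.exp(-lam)
        pois_cdf = w
        total = 0.0
        n_used = 0
        for n in range(nmax + 1):
            if n > 0:
                w = w * lam / n
                pois_cdf += w
            cum[n] = total + w * Rpow[n, ai, bi]
            total = cum[n]
            n_used = n
            if pois_cdf > 1.0 - 1e-12:
                break
        if total <= 0.0:
            # numerically impossible endpoint pair; treat as pure dwell
            dwell[ai] += dt[it]
            continue
        u = np.random.random() * total
        njump = 0
        for n in range(n_used + 1):
            if u <= cum[n]:
                njump = n
                break
        # sample the dominated bridge sequence
        seq[0] = ai
        for i in range(1, njump):
            tot = 0.0
            for x in range(K):
                tot += R[seq[i - 1], x] * Rpow[njump - i, x, bi]
            v = np.random.random() * tot
            acc = 0.0
            pick = K - 1
            for x in range(K):
                acc += R[seq[i - 1], x] * Rpow[njump - i, x, bi]
                if v <= acc:
                    pick = x
                    break
            seq[i] = pick
        if njump >= 1:
            seq[njump] = bi
        # uniform order statistics for the potential jump times
        times = np.sort(np.random.random(njump)) * dt[it]
        cur = ai
        t_entry = 0.0
        for i in range(njump):
            s = seq[i + 1]
            if s != cur:
                ntrans[cur, s] += 1.0
                dwell[cur] += times[i] - t_entry
                t_entry = times[i]
                cur = s
        dwell[cur] += dt[it] - t_entry
    return ntrans, dwell


def interval_stats(Q: np.ndarray, a: np.ndarray, b: np.ndarray,
                   dt: np.ndarray, rng: np.random.Generator):
    """Aggregate transition counts and dwell times from exact
    endpoint-conditioned draws over a batch of intervals.

    ``a``, ``b`` are 0-based endpoint states; returns (ntrans, dwell).
    """
    K = Q.shape[0]
    if a.size == 0 or K == 1:
        dwell = np.zeros(K)
        if a.size:
            np.add.at(dwell, a, dt)
        return np.zeros((K, K)), dwell
    mu, R, Rpow = build_uniformization(Q, float(dt.max()))
    if mu <= 0:
        dwell = np.zeros(K)
        np.add.at(dwell, a, dt)
        return np.zeros((K, K)), dwell
    seed = int(rng.integers(0, 2**31 - 1))
    return _interval_stats_kernel(
        R, Rpow, mu,
        np.ascontiguousarray(a, dtype=np.int64),
        np.ascontiguousarray(b, dtype=np.int64),
        np.ascontiguousarray(dt, dtype=np.float64),
        seed,
    )
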