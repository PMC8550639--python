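"""Run management: sampler loops, posterior summaries and artifacts.

Three fitting modes share one entry point:

* ``fixed-k``   -- fixed-dimension sampling at a user-chosen K;
* ``rj-states`` -- trans-dimensional sampling of K (split/combine move plus
  a fixed-K sweep per iteration), initialised at K = 1;
* ``rj-cluster``-- the clustering sampler over (M, K_1..K_M), initialised
  at one component with one state.

Every run writes a JSON-lines trace, posterior tables for the model
dimension, parameter summaries (posterior means with equal-tailed 95%
credible intervals, states ordered by intercept), and a reproducibility
manifest (seed, configuration, versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cluster import (ClusterMoveConfig, cluster_sweep, init_cluster_state,
                      mixture_marginal_loglik)
from .fixed import MHState, fixed_k_sweep
from .io import read_dataset, write_jsonl
from .model import (GLMFamily, PackedData, ThetaK, forward_filter,
                    pack_subjects)
from .priors import BetaCoefPrior, PriorSpec, theta_log_prior
from .rj import MoveConfig, rj_state_step

__all__ = ["RunConfig", "RunResult", "init_theta", "fit_fixed_k",
           "fit_rj_states", "fit_cluster", "posterior_dimension_table",
           "parameter_summary", "run"]


def init_theta(K: int, D: int, family: GLMFamily, prior: PriorSpec,
               rng: np.random.Generator, sigma0: float = 1.0) -> ThetaK:
    """Initial parameters at a given K, drawn from the priors (the
    dispersion starts at ``sigma0``; its full conditional takes over after
    the first sweep).

    Under the noninformative coefficient prior the raw prior draw can place
    log-link linear predictors beyond floating-point range, so coefficient
    initialisation caps the draw variance at 1; the samplers' own updates
    take over immediately.
    """
    if K == 1:
        Q = np.zeros((1, 1))
    else:
        Q = rng.gamma(prior.q_shape, 1.0 / prior.q_rate, size=(K, K))
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = rng.dirichlet(np.full(K, prior.pi_dirichlet))
    bp = prior.beta_prior
    if bp.kind == "normal":
        bp = BetaCoefPrior("normal", bp.mean, np.minimum(bp.var, 1.0))
    B = np.column_stack([bp.sample_column(D, rng) for _ in range(K)])
    return ThetaK(pi, Q, B, GLMFamily(family.family, sigma0))


@dataclass
class RunResult:
    trace: list
    snapshots: list          # (iteration, theta) or (iteration, state summary)
    mode: str
    extra: dict = field(default_factory=dict)

    def dimension_series(self, key: str = "K") -> np.ndarray:
        return np.array([rec[key] for rec in self.trace])


def fit_fixed_k(packed: PackedData, K: int, family: GLMFamily,
                prior: PriorSpec, n_iter: int, rng: np.random.Generator,
                thin: int = 10, fix_sigma: bool = False,
                init: ThetaK | None = None) -> RunResult:
    theta = init if init is not None else init_theta(K, packed.D, family,
                                                     prior, rng)
    mh = MHState.fresh(K)
    trace, snaps = [], []
    for it in range(n_iter):
        ll_vec, alphas, P = forward_filter(theta, packed)
        theta, _, mh = fixed_k_sweep(theta, packed, prior, rng, mh=mh,
                                     fix_sigma=fix_sigma, alphas=alphas, P=P)
        trace.append({"iteration": it, "K": K,
                      "log_marginal": float(ll_vec.sum())})
        if (it + 1) % thin == 0:
            snaps.append((it, theta.copy()))
    return RunResult(trace, snaps, "fixed-k")


def fit_rj_states(packed: PackedData, family: GLMFamily, prior: PriorSpec,
                  cfg: MoveConfig, n_iter: int, rng: np.random.Generator,
                  thin: int = 10, fix_sigma: bool = False,
                  init: ThetaK | None = None,
                  log_every: int = 0) -> RunResult:
    theta = init if init is not None else init_theta(1, packed.D, family,
                                                     prior, rng)
    mh = MHState.fresh(theta.K)
    k_logpmf = prior.k_prior.log_pmf(cfg.Kmax)
    trace, snaps = [], []
    for it in range(n_iter):
        ll_vec, alphas, P = forward_filter(theta, packed)
        llh = float(ll_vec.sum())
        terms = llh + theta_log_prior(theta, prior) + float(k_logpmf[theta.K - 1])
        new_theta, rec = rj_state_step(theta, packed, prior, cfg, rng,
                                       ll_terms_old=terms, k_logpmf=k_logpmf)
        if rec["accepted"]:
            alphas = P = None  # dimensions changed; refresh the filter
            mh = mh.resize(new_theta.K)
        theta, _, mh = fixed_k_sweep(new_theta, packed, prior, rng, mh=mh,
                                     fix_sigma=fix_sigma, alphas=alphas, P=P)
        trace.append({"iteration": it, "K": rec["K"], "move": rec["move"],
                      "accepted": bool(rec["accepted"]),
                      "log_alpha": float(rec["log_alpha"]),
                      "log_marginal": llh})
        if (it + 1) % thin == 0:
            snaps.append((it, theta.copy()))
        if log_every and (it + 1) % log_every == 0:
            acc = np.mean([r["accepted"] for r in trace[-log_every:]])
            print(f"iter {it + 1}: K={theta.K} "
                  f"jump-acceptance={acc:.3f} loglik={llh:.1f}")
    return RunResult(trace, snaps, "rj-states")


def fit_cluster(packed: PackedData, family: GLMFamily, prior: PriorSpec,
                cluster_cfg: ClusterMoveConfig, state_cfg: MoveConfig,
                n_iter: int, rng: np.random.Generator, thin: int = 10,
                fix_sigma: bool = False, log_every: int = 0) -> RunResult:
    state = init_cluster_state(packed, family, prior, rng)
    trace, snaps = [], []
    for it in range(n_iter):
        state, rec = cluster_sweep(state, packed, prior, cluster_cfg,
                                   state_cfg, rng, fix_sigma=fix_sigma)
        llh = mixture_marginal_loglik(state.model, packed, state.LL)
        trace.append({"iteration": it, "M": rec["M"], "M_star": rec["M_star"],
                      "K": rec["K"], "weights": rec["weights"],
                      "log_marginal": float(llh)})
        if (it + 1) % thin == 0:
            snaps.append((it, {
                "M": state.model.M,
                "K": state.model.state_counts(),
                "memberships": state.memberships.copy(),
                "components": [c.copy() for c in state.model.components],
                "weights": state.model.weights.copy(),
            }))
        if log_every and (it + 1) % log_every == 0:
            print(f"iter {it + 1}: M={rec['M']} M*={rec['M_star']} "
                  f"K={rec['K']} loglik={llh:.1f}")
    return RunResult(trace, snaps, "rj-cluster")


def posterior_dimension_table(trace: list, key: str, burn_in: int = 0,
                              thin: int = 1) -> pd.DataFrame:
    """Posterior distribution of a model dimension (K or M) from the trace
    after burn-in and thinning."""
    vals = np.array([rec[key] for rec in trace[burn_in:]][::thin])
    if vals.size == 0:
        raise ValueError("no post-burn-in iterations")
    counts = np.bincount(vals)
    rows = [{key: k, "probability": c / vals.size}
            for k, c in enumerate(counts) if c > 0]
    return pd.DataFrame(rows)


def _ordered(theta: ThetaK) -> ThetaK:
    """States reordered by increasing intercept (a deterministic labelling
    for summaries across label-switching)."""
    order = np.argsort(theta.B[0])
    return ThetaK(theta.pi[order], theta.Q[np.ix_(order, order)],
                  theta.B[:, order], theta.family)


def parameter_summary(snapshots: list, K: int, burn_in: int = 0) -> pd.DataFrame:
    """Posterior means and equal-tailed 95% credible intervals of all
    parameters, over snapshots at the given K (states ordered by
    intercept)."""
    draws = {}
    for it, theta in snapshots:
        if it < burn_in or not isinstance(theta, ThetaK) or theta.K != K:
            continue
        th = _ordered(theta)
        vals = {}
        for k in range(K):
            vals[f"pi_{k + 1}"] = th.pi[k]
            for d in range(th.D):
                vals[f"beta_{d + 1},{k + 1}"] = th.B[d, k]
            for j in range(K):
                if j != k:
                    vals[f"q_{k + 1},{j + 1}"] = th.Q[k, j]
        if th.family.family == "normal":
            vals["sigma"] = th.family.sigma
        for name, v in vals.items():
            draws.setdefault(name, []).append(v)
    rows = []
    for name, v in draws.items():
        v = np.asarray(v)
        rows.append({"parameter": name, "mean": v.mean(),
                     "sd": v.std(ddof=1) if v.size > 1 else 0.0,
                     "ci_2.5": np.percentile(v, 2.5),
                     "ci_97.5": np.percentile(v, 97.5),
                     "n_draws": v.size})
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Declarative run description (see the CLI for the file format)."""

    data: str
    mode: str = "rj-states"          # fixed-k | rj-states | rj-cluster
    family: str = "normal"
    iterations: int = 5000
    burn_in: int = 1000
    thinning: int = 10
    seed: int = 0
    out_dir: str = "cthmm-run"
    K: int = 3                        # fixed-k mode only
    prior: PriorSpec = field(default_factory=PriorSpec)
    move: MoveConfig = field(default_factory=MoveConfig)
    cluster_move: ClusterMoveConfig = field(default_factory=ClusterMoveConfig)
    fix_sigma: bool = False
    sigma0: float = 1.0

    def validate(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("iterations > burn_in >= 0 required")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.mode not in ("fixed-k", "rj-states", "rj-cluster"):
            raise ValueError(f"unknown mode {self.mode!r}")


def run(config: RunConfig) -> Path:
    """Execute a run and write its artifacts; returns the output directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = read_dataset(config.data)
    packed = pack_subjects(subjects)
    rng = np.random.default_rng(config.seed)
    family = GLMFamily(config.family, config.sigma0)
    if config.mode == "fixed-k":
        result = fit_fixed_k(packed, config.K, family, config.prior,
                             config.iterations, rng, thin=config.thinning,
                             fix_sigma=config.fix_sigma)
    elif config.mode == "rj-states":
        result = fit_rj_states(packed, family, config.prior, config.move,
                               config.iterations, rng, thin=config.thinning,
                               fix_sigma=config.fix_sigma,
                               log_every=max(config.iterations // 10, 1))
    else:
        result = fit_cluster(packed, family, config.prior,
                             config.cluster_move, config.move,
                             config.iterations, rng, thin=config.thinning,
                             fix_sigma=config.fix_sigma,
                             log_every=max(config.iterations // 10, 1))
    write_jsonl(result.trace, out / "trace.jsonl")
    if config.mode == "rj-cluster":
        tab = posterior_dimension_table(result.trace, "M", config.burn_in)
        tab.to_csv(out / "posterior_M.csv", index=False)
        _cluster_membership_summary(result, config).to_csv(
            out / "membership.csv", index=False)
    else:
        key = "K"
        tab = posterior_dimension_table(result.trace, key, config.burn_in)
        tab.to_csv(out / "posterior_K.csv", index=False)
        modal_K = int(tab.loc[tab["probability"].idxmax(), key]) \
            if config.mode == "rj-states" else config.K
        summary = parameter_summary(result.snapshots, modal_K,
                                    burn_in=config.burn_in)
        summary.to_csv(out / "params_summary.csv", index=False)
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "iterations": config.iterations,
        "burn_in": config.burn_in,
        "thinning": config.thinning,
        "data": str(config.data),
        "config_hash": hashlib.sha256(
            repr(config).encode()).hexdigest()[:16],
        "version": __version__,
        "numpy": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _cluster_membership_summary(result: RunResult,
                                config: RunConfig) -> pd.DataFrame:
    """Subjects assigned to their modal component among post-burn-in
    snapshots at the modal M."""
    Ms = [s["M"] for it, s in result.snapshots
          if it >= config.burn_in] or [1]
    modal_M = int(np.bincount(Ms).argmax())
    members = [s["memberships"] for it, s in result.snapshots
               if it >= config.burn_in and s["M"] == modal_M]
    if not members:
        return pd.DataFrame(columns=["subject", "cluster", "probability"])
    arr = np.stack(members)  # (draws, N)
    rows = []
    for n in range(arr.shape[1]):
        counts = np.bincount(arr[:, n], minlength=modal_M)
        c = int(counts.argmax())
        rows.append({"subject": n + 1, "cluster": c + 1,
                     "probability": counts[c] / arr.shape[0]})
    return pd.DataFrame(rows)
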