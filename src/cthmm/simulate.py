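"""Synthetic-data generation for CTHMM-GLM studies.

The generator reproduces the standard study design for irregularly observed
disease-progression trajectories: each subject's latent CTMC runs on
[0, horizon]; the number of observations T is drawn uniformly from an
integer range; the first observation is pinned at time 0 (so the initial
law is identifiable) and the remaining T - 1 times are i.i.d. uniform on
(0, horizon), sorted; covariates are drawn per observation; outcomes come
from the state-specific GLM.  Built-in scenarios carry the exact parameter
fixtures of the three benchmark configurations (a 4-state model with
covariates, a 3-state intercept-only model, and a 4-cluster mixture with
state counts 3/2/3/4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctmc import GeneratorMatrix, LatentPath, simulate_ctmc
from .model import GLMFamily, Subject

__all__ = ["ScenarioConfig", "builtin_scenario", "generate", "GroundTruth"]


@dataclass
class CovariateSpec:
    """One covariate column: 'normal' (mean, sd) or 'bernoulli' (p), drawn
    independently per observation (time-varying)."""

    kind: str
    a: float = 0.0
    b: float = 1.0

    def draw(self, size, rng):
        if self.kind == "normal":
            return rng.normal(self.a, self.b, size=size)
        if self.kind == "bernoulli":
            return rng.binomial(1, self.a, size=size).astype(float)
        raise ValueError(f"unknown covariate law {self.kind!r}")


@dataclass
class ScenarioConfig:
    """Data-generating configuration; lists with one entry per cluster for
    mixture scenarios (a single-cluster scenario is a 1-element list)."""

    Q: list
    B: list
    pi: list
    family: str = "normal"
    sigma: float = 1.0
    n_subjects: list = field(default_factory=lambda: [1000])
    horizon: float = 15.0
    obs_count_range: tuple = (20, 60)
    covariates: list = field(default_factory=list)  # CovariateSpec, excl. intercept
    name: str = ""

    @property
    def n_clusters(self) -> int:
        return len(self.Q)

    def validate(self) -> None:
        if not (len(self.Q) == len(self.B) == len(self.pi) == len(self.n_subjects)):
            raise ValueError("per-cluster parameter lists must align")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")
        lo, hi = self.obs_count_range
        if lo < 1 or hi < lo:
            raise ValueError("observation count bounds must satisfy 1 <= lo <= hi")
        for Q, B, pi in zip(self.Q, self.B, self.pi):
            GeneratorMatrix(np.asarray(Q, dtype=float))
            K = np.asarray(pi).size
            if np.atleast_2d(np.asarray(B)).shape[1] != K:
                raise ValueError("B columns must match the state count")

    def scaled(self, factor: float) -> "ScenarioConfig":
        """Copy with subject counts multiplied by ``factor`` (rounded,
        minimum 1 per cluster); everything else unchanged."""
        n = [max(1, int(np.floor(v * factor + 0.5))) for v in self.n_subjects]
        return ScenarioConfig(self.Q, self.B, self.pi, self.family, self.sigma,
                              n, self.horizon, self.obs_count_range,
                              self.covariates, self.name)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        """Build a scenario from a plain mapping (YAML/JSON-friendly); see
        the built-in scenarios for the expected keys.  Single-cluster
        scenarios may give Q/B/pi directly instead of 1-element lists."""
        Q = d["Q"] if isinstance(d["Q"][0][0], (list, tuple)) else [d["Q"]]
        B = d["B"] if isinstance(d["B"][0], (list, tuple)) else [d["B"]]
        pi = d["pi"] if isinstance(d["pi"][0], (list, tuple)) else [d["pi"]]
        n = d.get("n_subjects", [1000])
        if isinstance(n, (int, float)):
            n = [int(n)]
        covs = [CovariateSpec(**c) for c in d.get("covariates", [])]
        cfg = cls(Q, B, pi, d.get("family", "normal"),
                  float(d.get("sigma", 1.0)), list(n),
                  float(d.get("horizon", 15.0)),
                  tuple(d.get("obs_count_range", (20, 60))), covs,
                  d.get("name", ""))
        cfg.validate()
        return cfg


_SIM1_Q = [
    [-3.00, 2.00, 1.00, 0.00],
    [1.00, -1.80, 0.75, 0.05],
    [0.15, 0.55, -1.05, 0.35],
    [0.00, 0.25, 0.40, -0.65],
]
_SIM1_B = [
    [-1.28, -0.55, -1.05, 0.99],
    [-0.88, 1.15, 1.36, 1.73],
    [0.70, 0.68, -1.12, -1.20],
]
_SIM1_PI = [0.35, 0.25, 0.2, 0.2]

_SIM2_Q = [
    [-1.0, 0.6, 0.4],
    [0.7, -1.2, 0.5],
    [0.3, 0.6, -0.9],
]
_SIM2_PI = [0.5, 0.4, 0.1]

_SIM3_Q = [
    [[-2.5, 2.0, 0.5], [0.5, -1.5, 1.0], [0.1, 0.9, -1.0]],
    [[-1.20, 1.20], [0.25, -0.25]],
    [[-0.50, 0.49, 0.01], [0.25, -0.30, 0.05], [0.01, 0.10, -0.11]],
    [[-3.00, 2.00, 1.00, 0.00], [1.00, -1.80, 0.75, 0.05],
     [0.15, 0.55, -1.05, 0.35], [0.00, 0.25, 0.40, -0.65]],
]
_SIM3_PI = [[0.5, 0.4, 0.1], [0.6, 0.4], [0.45, 0.45, 0.1],
            [0.35, 0.25, 0.2, 0.2]]
_SIM3_B_NORMAL = [[-3.0, 0.0, 2.0], [-3.5, 3.5], [-3.8, 1.0, 4.0],
                  [-2.0, -1.2, 0.7, 1.8]]
_SIM3_B_POISSON = [
    list(np.log([1.5, 4.0, 5.0])),
    list(np.log([2.0, 6.0])),
    list(np.log([1.3, 4.2, 7.5])),
    list(np.log([0.15, 0.5, 2.0, 6.2])),
]
_SIM3_N = [400, 500, 450, 550]


def builtin_scenario(name: str, family: str = "normal",
                     sigma: float = 1.0) -> ScenarioConfig:
    """The benchmark data-generating configurations.

    * ``SIM1-4state``: 4 latent states, two time-varying covariates
      (Z1 ~ N(-1, 1), Z2 ~ Bernoulli(0.6)), 1000 subjects.
    * ``SIM2-3state-intercept``: 3 latent states, intercept only; normal
      means (-4, 0, 5) or Poisson means (1.5, 4, 5); 1000 subjects.
    * ``SIM3-4cluster``: four clusters with state counts (3, 2, 3, 4) and
      subject counts (400, 500, 450, 550), intercept only.
    """
    if name == "SIM1-4state":
        return ScenarioConfig(
            [_SIM1_Q], [_SIM1_B], [_SIM1_PI], family, sigma, [1000],
            covariates=[CovariateSpec("normal", -1.0, 1.0),
                        CovariateSpec("bernoulli", 0.6)],
            name=name)
    if name == "SIM2-3state-intercept":
        B = [-4.0, 0.0, 5.0] if family == "normal" \
            else list(np.log([1.5, 4.0, 5.0]))
        return ScenarioConfig([_SIM2_Q], [B], [_SIM2_PI], family, sigma,
                              [1000], name=name)
    if name == "SIM3-4cluster":
        Bs = _SIM3_B_NORMAL if family == "normal" else _SIM3_B_POISSON
        return ScenarioConfig(_SIM3_Q, Bs, _SIM3_PI, family, sigma,
                              list(_SIM3_N), name=name)
    raise ValueError(f"unknown scenario {name!r}")


@dataclass
class GroundTruth:
    """Latent truth stored beside a generated dataset; never read by the
    fitters."""

    memberships: np.ndarray
    paths: list

    def to_dict(self) -> dict:
        return {
            "memberships": self.memberships.tolist(),
            "paths": [
                {"horizon": p.horizon, "states": p.states.tolist(),
                 "times": p.times.tolist()} for p in self.paths
            ],
        }


def generate(config: ScenarioConfig, rng: np.random.Generator):
    """Generate a dataset from a scenario.

    Returns ``(subjects, truth)`` where ``subjects`` is a list of
    :class:`~cthmm.model.Subject` and ``truth`` holds the latent paths and
    cluster memberships.
    """
    config.validate()
    counts = np.asarray(config.n_subjects, dtype=float)
    n_total = int(counts.sum())
    probs = counts / counts.sum()
    fam = GLMFamily(config.family, config.sigma)
    lo, hi = config.obs_count_range
    D = 1 + len(config.covariates)
    subjects = []
    paths = []
    memberships = np.empty(n_total, dtype=np.int64)
    for n in range(n_total):
        m = int(rng.choice(config.n_clusters, p=probs))
        memberships[n] = m + 1
        Q = np.asarray(config.Q[m], dtype=float)
        pi = np.asarray(config.pi[m], dtype=float)
        B = np.atleast_2d(np.asarray(config.B[m], dtype=float))
        path = simulate_ctmc(Q, pi, config.horizon, rng)
        T = int(rng.integers(lo, hi + 1))
        times = np.concatenate([[0.0],
                                np.sort(rng.uniform(0.0, config.horizon,
                                                    size=T - 1))])
        Z = np.ones((T, D))
        for j, spec in enumerate(config.covariates):
            Z[:, j + 1] = spec.draw(T, rng)
        states = path.state_at(times) - 1
        eta = np.einsum("td,dt->t", Z, B[:, states])
        if config.family == "normal":
            y = rng.normal(eta, config.sigma)
        else:
            y = rng.poisson(np.exp(eta)).astype(float)
        subjects.append(Subject(times, y, Z, subject_id=n + 1))
        paths.append(path)
    return subjects, GroundTruth(memberships, paths)
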