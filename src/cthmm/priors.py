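"""Prior specifications and log-density helpers.

The hierarchical prior mirrors the model: independent Gamma(a, b) rates on
the off-diagonal generator entries, a symmetric Dirichlet on the initial
law, a (proper) normal prior on the GLM coefficients -- or a Gamma prior on
the state means via change of variables for intercept-only Poisson models --
an inverse-gamma prior on the normal dispersion, and a discrete prior on the
number of hidden states (and of mixture components) truncated to
{1, ..., Kmax}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln

__all__ = [
    "BetaCoefPrior",
    "DiscreteDimensionPrior",
    "PriorSpec",
    "log_gamma_pdf",
    "log_beta_pdf",
    "log_normal_pdf",
    "log_dirichlet_sym",
    "theta_log_prior",
]


def log_gamma_pdf(x, shape, rate):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        return shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x


def log_beta_pdf(w, a=2.0, b=2.0):
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore"):
        return (a - 1) * np.log(w) + (b - 1) * np.log1p(-w) - betaln(a, b)


def log_normal_pdf(x, mean, var):
    x = np.asarray(x, dtype=float)
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def log_dirichlet_sym(p, delta: float):
    """Symmetric Dirichlet(delta, ..., delta) log density at simplex point p."""
    p = np.asarray(p, dtype=float)
    K = p.size
    if K == 1:
        return 0.0
    with np.errstate(divide="ignore"):
        return float(gammaln(K * delta) - K * gammaln(delta)
                     + (delta - 1) * np.log(p).sum())


@dataclass
class BetaCoefPrior:
    """Prior on GLM coefficients.

    kind 'normal': independent N(mean, var) on every entry of B ('mean' may
    be a scalar or length-D vector applied per row).  The noninformative
    option is this prior with var = 1e4, which is proper and keeps empty
    states well-defined.

    kind 'gamma-rate': intercept-only Poisson models only; Gamma(shape, rate)
    on the state mean exp(beta), inducing p(beta) = Gamma(e^b) * e^b.
    """

    kind: str = "normal"
    mean: float | np.ndarray = 0.0
    var: float | np.ndarray = 1e4
    shape: float = 10.0
    rate: float = 10.0

    @classmethod
    def noninformative(cls) -> "BetaCoefPrior":
        return cls("normal", 0.0, 1e4)

    def logpdf_column(self, beta_k: np.ndarray) -> float:
        beta_k = np.asarray(beta_k, dtype=float)
        if self.kind == "normal":
            return float(log_normal_pdf(beta_k, self.mean, self.var).sum())
        if beta_k.size != 1:
            raise ValueError("gamma-rate coefficient prior is intercept-only")
        b = float(beta_k[0])
        return float(log_gamma_pdf(np.exp(b), self.shape, self.rate) + b)

    def logpdf(self, B: np.ndarray) -> float:
        return float(sum(self.logpdf_column(B[:, k]) for k in range(B.shape[1])))

    def sample_column(self, D: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "normal":
            mean = np.broadcast_to(np.asarray(self.mean, dtype=float), (D,))
            sd = np.sqrt(np.broadcast_to(np.asarray(self.var, dtype=float), (D,)))
            return rng.normal(mean, sd)
        if D != 1:
            raise ValueError("gamma-rate coefficient prior is intercept-only")
        return np.array([np.log(rng.gamma(self.shape, 1.0 / self.rate))])


@dataclass
class DiscreteDimensionPrior:
    """Prior mass function on a model dimension (number of states or of
    mixture components), normalised over {1, ..., kmax}.

    kinds: 'poisson' (zero-truncated Poisson(lam)), 'geometric' (success
    prob p on {1, 2, ...}), 'negbin' (zero-truncated Negative Binomial(r, p)),
    'uniform' (discrete uniform on 1..kmax).
    """

    kind: str = "poisson"
    lam: float = 3.5
    p: float = 0.2
    r: float = 2.0

    def log_pmf(self, kmax: int) -> np.ndarray:
        """Normalised log pmf over 1..kmax, returned as an array of length
        kmax (index 0 <-> dimension 1)."""
        k = np.arange(1, kmax + 1, dtype=float)
        if self.kind == "poisson":
            logw = k * np.log(self.lam) - gammaln(k + 1)
        elif self.kind == "geometric":
            logw = np.log(self.p) + (k - 1) * np.log1p(-self.p)
        elif self.kind == "negbin":
            logw = gammaln(k + self.r) - gammaln(k + 1) - gammaln(self.r) \
                + self.r * np.log(self.p) + k * np.log1p(-self.p)
        elif self.kind == "uniform":
            logw = np.zeros(kmax)
        else:
            raise ValueError(f"unknown dimension prior kind {self.kind!r}")
        from scipy.special import logsumexp

        return logw - logsumexp(logw)


@dataclass
class PriorSpec:
    """Hyperparameters of the full hierarchical prior.

    Defaults follow the simulation configuration used throughout:
    Gamma(1, 2) rates, Dirichlet(1) initial laws, noninformative normal
    coefficients, inverse-gamma(0.01, 0.01) dispersion, zero-truncated
    Poisson(3.5) on the number of states, and a uniform Dirichlet (delta=1)
    on mixture weights.
    """

    q_shape: float = 1.0
    q_rate: float = 2.0
    pi_dirichlet: float = 1.0
    beta_prior: BetaCoefPrior = field(default_factory=BetaCoefPrior.noninformative)
    sigma_shape: float = 0.01
    sigma_scale: float = 0.01
    k_prior: DiscreteDimensionPrior = field(default_factory=DiscreteDimensionPrior)
    m_prior: DiscreteDimensionPrior = field(default_factory=DiscreteDimensionPrior)
    delta_mix: float = 1.0

    def validate(self) -> None:
        for name in ("q_shape", "q_rate", "pi_dirichlet", "sigma_shape",
                     "sigma_scale", "delta_mix"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


def theta_log_prior(theta, prior: PriorSpec) -> float:
    """Log prior density of (pi, Q, B) at a given K.

    The dispersion sigma is shared across states, so its prior contribution
    is constant across model dimensions and is omitted from trans-dimensional
    ratios (it cancels); it is handled by its own full conditional update.
    """
    K = theta.K
    off = ~np.eye(K, dtype=bool)
    lp = float(log_gamma_pdf(theta.Q[off], prior.q_shape, prior.q_rate).sum()) if K > 1 else 0.0
    lp += log_dirichlet_sym(theta.pi, prior.pi_dirichlet)
    lp += prior.beta_prior.logpdf(theta.B)
    return lp
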