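"""Inferring the number of hidden states by reversible-jump MCMC.

Runs the trans-dimensional sampler (split/combine moves on the state count,
alternating with fixed-dimension sweeps) on 3-state data, starting from a
single state, and prints the posterior distribution of K.
"""

import numpy as np

from cthmm import (BetaCoefPrior, GLMFamily, MoveConfig, PriorSpec,
                   builtin_scenario, fit_rj_states, generate, pack_subjects)

rng = np.random.default_rng(2)
config = builtin_scenario("SIM2-3state-intercept", sigma=1.0).scaled(0.06)
subjects, _ = generate(config, rng)
packed = pack_subjects(subjects)

prior = PriorSpec(beta_prior=BetaCoefPrior("normal", 0.0, 1.0))
result = fit_rj_states(packed, GLMFamily("normal", 1.0), prior, MoveConfig(),
                       n_iter=1200, rng=rng, thin=10 ** 9)

Ks = result.dimension_series()[300:]
counts = np.bincount(Ks, minlength=7)
print("posterior distribution of the number of hidden states "
      f"(n={packed.N} subjects, {Ks.size} post-burn-in iterations):")
for k, c in enumerate(counts):
    if c:
        print(f"  K = {k}: {c / Ks.size:.4f}")
print("the data were generated from 3 states; the mode should sit at K = 3.")
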