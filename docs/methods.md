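# Methods

## Model and likelihoods

The latent layer is a time-homogeneous CTMC on {1, …, K} with generator Q
(rates in events per unit time, the same unit as the observation times) and
initial law π; the first observation of every subject is made at time 0, so
π is identified. Outcomes are conditionally independent given the path;
state k emits through a GLM with coefficient column β_k. Two families are
implemented: normal-identity with one dispersion σ shared across states
(σ in outcome units), and poisson-log for counts. The architecture keeps
the family pluggable but only these two are wired and tested.

Two likelihoods drive the samplers.

*Complete-data likelihood.* For a subject with latent path
{(x_i, t_i)} on its observation window and outcomes O_t,

log L = log π_{x(0)} + Σ_jumps log q_{x,x'} + Σ_segments q_{x,x} · (dwell)
        + Σ_t log f(O_t | x(τ_t)),

i.e. initial-state, jump-rate, exponential-dwell and emission terms. This
is the target of the fixed-dimension conditional updates once paths are
imputed, and reduces the path to the CTMC sufficient statistics
N_ij (transition counts) and T_i (dwell times).

*Forward marginal likelihood.* The observed-data likelihood integrates the
path out by the forward recursion α_t = (α_{t−1} P(Δt)) ⊙ f_t with
P(Δt) = exp(QΔt). It is implemented with per-step scaling constants
accumulated in log-space (cannot underflow at T = 60; verified against
exhaustive enumeration at K = 3, T = 5 to 1e-8). All subjects are packed
into padded rectangular arrays and the recursion runs vectorised across
subjects; interval transition matrices for all gaps of a dataset are
computed in one batch through an eigendecomposition of Q when the
eigenvector matrix is well-conditioned (condition number < 1e8), with a
fallback to scaling-and-squaring per gap otherwise. The public
`transition_probability` always uses scaling-and-squaring, so defective
generators are handled.

## Endpoint-conditioned path sampling

Latent-path imputation is forward-filtering backward-sampling of the state
skeleton at the observation times, then an exact endpoint-conditioned
bridge on each inter-observation interval. The public
`sample_conditioned_path` uses the classical rejection samplers (direct
simulation when the endpoints agree; first-jump-conditioned simulation when
they differ) and falls back to uniformization after a probe batch of 256
rejected trials, bounding the runtime for unlikely endpoint pairs. Inside
the samplers, where only N_ij and T_i are needed, the bridges are drawn by
uniformization directly (a dominating Poisson process at rate μ = max exit
rate with transition kernel R = I + Q/μ; the jump count is drawn from its
exact conditional series, the dominated state sequence from the
corresponding bridge law, and virtual self-jumps are discarded) and reduced
to the statistics in a single numba-compiled pass over all intervals of all
subjects. Both routes are exact draws from the same law and are
cross-checked against an analytic jump-count series in the tests.

## Fixed-dimension sweep

Order per iteration: latent paths; **B** (and σ); π; Q.

* Q: q_ij | · ~ Gamma(a + N_ij, b + T_i) independently (conjugacy of the
  exponential dwell/jump terms); diagonal recomputed. Defaults a = 1,
  b = 2.
* π: Dirichlet(δ + initial-state counts), δ = 1.
* **B**, normal family: per-state conjugate multivariate-normal draw given
  σ, then σ² from its inverse-gamma full conditional. The noninformative
  coefficient prior is a proper N(0, 1e4) per entry, which keeps empty
  states well-defined (they draw from the prior) and makes the per-state
  precision matrix nonsingular even with fewer observations than
  covariates. σ² gets IG(0.01, 0.01) by default, with a `fix_sigma` switch
  for exact scenario replication.
* **B**, poisson family: per-state random-walk Metropolis with a
  diminishing-adaptation scale targeting ~0.3 acceptance (within the
  0.2–0.5 band); adaptation can be disabled, which makes the kernel exactly
  invariant (used by the joint-distribution test). Intercept-only Poisson
  models support a Gamma(shape, rate) prior on the state mean via change of
  variables (default Gamma(10, 10)).

Correctness of the whole sweep is established by Geweke-style
joint-distribution tests (alternating data simulation and one sweep leaves
the prior invariant) on a K = 2 normal and a K = 1 Poisson configuration;
those tests use proper test priors with finite moments (IG(3, 2) for σ²,
N(0, 4) for coefficients) so the prior moments being compared exist — the
package defaults are unchanged by this.

## Trans-dimensional moves on K

Split (K → K+1), after internally relabelling the split state last: both
children inherit the parent's outgoing rates; incoming rates are divided by
independent Beta(2, 2) weights; the two new cross rates come from the
Gamma rate prior; the initial mass is divided by a Beta(2, 2) weight; the
child intercept is N(parent, c²) with c = 1.0 by default (the benchmark
configurations never state c; it is configurable). This construction
preserves the stationary law exactly — the children's stationary masses sum
to the parent's, all other states keep theirs — which is what makes the
proposal "centered" and the acceptance rates usable. The combine move
merges the L1-nearest pair by stationary-probability-weighted averages
(outgoing rates and coefficients), sums incoming rates and initial masses,
and discards the cross rates; a split whose children are not mutually
nearest in coefficient space is rejected early, mirroring the combine's
pair-selection rule.

Acceptance is evaluated on the forward marginal likelihood times the prior
(latent paths play no role and are re-imputed after an accepted jump,
which the following fixed-K sweep does automatically). The proposal-ratio
bookkeeping includes the split-state choice (1/K), the reverse combine's
pair-selection probability (m/(K+1), m ∈ {1, 2} directions of the
nearest-neighbour rule), the product of Beta(2,2) densities over all K−1
incoming weights, and the intercept-perturbation density in **both**
directions (the combine factor evaluates it at the recovered perturbation,
which is orientation-symmetric). With this bookkeeping the split and
combine log-factors are exact negatives of each other at matched
configurations (reciprocity, tested to 1e-10). Boundary dimensions force
the only legal move, with the b_K/d_{K+1} factors adjusted accordingly;
b_K = 0.5 elsewhere, Kmax = 10 by default.

### Calibration of the trans-dimensional chain

The canonical correctness check for a trans-dimensional sampler runs it
with no data, where the posterior is the prior. Restricted to K ∈ {1, 2}
the split/combine pair above is a dimension-matched bijection and the chain
reproduces the truncated prior essentially exactly (TV ≈ 0.002 over 60k
iterations — this is a regression test). For K ≥ 2, however, the centered
split is dimensionally degenerate: it copies the parent's outgoing rates to
both children deterministically (K−1 missing degrees of freedom per split),
and the stationary-weighted combine is not its functional inverse, so the
pair cannot satisfy detailed balance off the image manifold of the split.
The consequence is a quantifiable downward bias of the flat-likelihood
K-marginal relative to the prior (total-variation distance ≈ 0.3–0.4
against zero-truncated Poisson(3.5) truncated at 10; the component moves,
which copy Q and π wholesale, are more degenerate still). The magnitude is
reported, not hidden: `scripts/acceptance.py` computes the TV distance as
its calibration diagnostic. In data-driven use the likelihood dominates
this O(1)-per-dimension prior-flow bias, and the posterior mode of K (and
of the cluster structure) is recovered reliably — which the mode-recovery
runs demonstrate. Repairing the bias would require adding proposal
randomness in the copied coordinates, destroying the exact stationary-law
preservation that defines the centered construction; we keep the
construction and document the trade-off as a known limitation.

## Clustering layer

Each mixture component is a full CTHMM with its own K_m; weights get a
uniform Dirichlet (δ = 1). One sweep: (i) a state split/combine move inside
every component using only its currently assigned subjects (an empty
component's move is prior-driven, letting K_m mix); (ii) a component
split/combine on the marginalized likelihood Σ_m ϖ_m L(o_n | Θ^(m)) —
the split duplicates a component (same Q, π) and perturbs every state's
intercept, the combine merges the same-K nearest pair state-by-state with
per-state stationary weights; (iii) membership resampling from the
posterior probabilities; (iv) fixed-dimension sweeps per component — at
zero assigned subjects the conjugate updates reduce exactly to prior
draws, which implements the empty-component refresh; (v) a Dirichlet
weight update from the occupancy counts. The combine probability defaults
to 0.7 (a combine only succeeds once two similar components share a state
count, so it must be proposed more often); Mmax = 15. M and the number of
occupied components M* are both reported each iteration, and the summary
assigns each subject its modal component among iterations at the modal M.

Per-subject log-likelihood columns are cached per component and refreshed
whenever a component's parameters change; scoring subjects under arbitrary
components never produces NaN — a component that cannot explain a subject
scores −∞ and gets membership probability 0.

## Synthetic data

The generator reproduces the benchmark study design: latent paths on
[0, 15] (time units arbitrary but shared with Q's rates); T ~ discrete
uniform {20, …, 60} observations per subject, the first pinned at 0 and the
remaining T−1 i.i.d. uniform on (0, 15), sorted; covariates drawn
independently per observation (Z1 ~ N(−1, 1), Z2 ~ Bernoulli(0.6) in the
covariate scenario); outcomes from the state GLM. Three built-in scenarios
carry the exact printed parameter fixtures: a 4-state model with two
covariates (1000 subjects), a 3-state intercept-only model with normal
means (−4, 0, 5) or Poisson means (1.5, 4, 5) (1000 subjects), and a
4-cluster mixture with state counts (3, 2, 3, 4) and cluster sizes
(400, 500, 450, 550). Ground truth (paths, memberships) is written to a
sidecar the fitters never read. What the generator does **not** emulate:
informative observation times (visits triggered by disease state), missing
data, overdispersion, or covariate-dependent transition rates — so passing
tests demonstrate correctness of the inference machinery under the model,
not robustness to real-data violations of it.

## Problem sizes and numerical choices

Test and acceptance runs are desk-scale versions of the benchmark
configurations, chosen so the full suite runs in minutes on one core:
mode recovery uses n = 150 subjects / 5000 iterations (3-state normal) and
n = 250 / 5000 (4-state Poisson) instead of n = 1000 / 20000; the cluster
scenario runs at quarter scale (476 subjects, 2500 sweeps) in the
acceptance script; flat-likelihood calibration chains use 30–50k
iterations. Full-scale runs are a matter of CPU-hours, not methodology.

Other numerical choices: states are labelled 1..K externally and 0-based
internally; σ is initialised at 1.0 (its IG(0.01, 0.01) prior produces
astronomically dispersed draws; the full conditional takes over after one
sweep); coefficient initialisation caps the draw variance at 1 under the
noninformative prior (a raw draw can overflow the log link); generator
row-sum tolerance 1e-10, stationary-law residual tolerance 1e-8; ties in
nearest-neighbour selection break to the smallest index; interval
transition matrices are clipped to [0, 1] and renormalised after the
eigendecomposition route (errors ~1e-12); summaries order states by
increasing intercept (no other label-switching post-processing is
applied).

## Known limitations

* The trans-dimensional moves are exactly those of the centered
  construction and inherit its prior-level flow bias (see "Calibration"
  above); posterior probabilities of K near the mode are trustworthy in
  likelihood-dominated regimes, but tail probabilities of large K inherit
  a downward distortion. At reduced sample sizes this can shave a state
  off weakly separated components — the quarter-scale 4-cluster run in
  `scripts/acceptance.py` recovers the number of clusters but
  under-dimensions its two least-separated components, and reports exactly
  that.
* Label switching within a fixed K is not post-processed beyond
  intercept-ordering in summaries.
* Time-inhomogeneous generators, constrained generators, other
  exponential-family emissions, and dependence between outcomes given the
  path are out of scope.
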