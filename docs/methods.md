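# Methods

## Model

Protein function prediction is cast as inference on a binary Markov random
field over an undirected protein interaction network.  For one functional
term, each protein i carries a state x_i ∈ {0, 1} (performs / does not
perform the function); annotated proteins have fixed states, unannotated
ones are inferred.  The homogeneous pairwise MRF assigns each labeling an
energy built from the count of positive nodes and the counts of
positive–positive, mixed, and negative–negative edges.  Its normalizing
constant is intractable, so all inference uses the pseudolikelihood (PLF):
the product over nodes of the conditional probability of each node's state
given its neighbors.  That conditional is exactly a logistic regression,

    logit P(x_i = 1 | x_N(i)) = α + β·M1_i + γ·M0_i,

with M1_i and M0_i the numbers of neighbors of i currently in state 1 and 0.
θ = (α, β, γ) is the minimal parameterization; the four-parameter pairwise
energy has one redundant degree of freedom and is only materialized as
diagnostic edge-class counts.  Under a global label flip the model maps
(0, β, γ) → (0, −γ, −β), which the tests use as an algebraic check.

## Samplers

**Two-step baseline (`mrf_deng`).**  Step one fits θ by maximum
pseudolikelihood — a logistic regression whose rows are the annotated nodes
and whose predictors are their neighbor counts with unannotated neighbors
removed.  Step two initializes every unknown state by an independent
Bernoulli draw at the annotated positive prevalence and runs sequential
Gibbs sweeps at the fixed θ̂.  Pruning unannotated neighbors shrinks
neighborhoods, which biases the interaction coefficients toward larger
magnitudes on degree-heterogeneous (scale-free) networks; at prediction
time the full neighborhoods are used with the mis-scaled parameters, which
is the weakness the joint sampler removes.

**Joint sampler (`bmrf`).**  A Markov chain over (x_unknown, θ).  Each
iteration runs one Gibbs sweep over the unknown labels at the current θ
(fresh uniform permutation, sequential updates from the current neighbor
counts), then updates θ by one Differential Evolution MCMC (DEMC) step: the
candidate is θ + γ_step·(Z[R1] − Z[R2]) + e, where Z is the archive of all
past parameter states, R1 ≠ R2 are drawn uniformly, γ_step = 2.38/√(2d)
with d = 3, and e has independent components uniform on (−1e−4, +1e−4).
The candidate is accepted by a Metropolis test on the log-PLF of the
current imputed labeling (the proposal is symmetric and the parameter prior
flat, so only the PLF ratio enters).  The current θ is appended to Z every
iteration, so after T iterations the archive holds z_init_size + T rows and
the proposal scale self-tunes to the posterior geometry; on the default
benchmark this lands the acceptance rate near the 0.23 optimum for random
walk Metropolis in moderate dimension.

Initialization: labels are drawn once from the two-step baseline's
posterior (one Bernoulli draw per unknown node, so independent chains start
from genuinely dispersed points); Z starts with 30 (= 10·d) draws from a
normal centered at the Firth-penalized pseudolikelihood estimate with its
covariance.  Penalized estimation is used precisely because sparse terms
with few positives frequently separate, where maximum likelihood diverges.

The posterior probability reported for each unknown protein is the
Rao-Blackwellized average of the conditional probabilities used in its
Gibbs updates after burn-in (not the average of sampled 0/1 states), for
both samplers, which substantially reduces Monte Carlo noise at equal run
length.

### PLF scope

When θ is updated conditionally on a fully imputed labeling, the log-PLF in
the Metropolis ratio can sum over every node (`plf_scope='all'`) or over
the originally-annotated nodes only (`'observed'`).  The PLF is defined as
the product of the conditional probabilities across all nodes, so `'all'`
is the default; it also reproduces the expected DEMC acceptance behavior on
the benchmarks (≈0.25 vs ≈0.35 for `'observed'`).  `'observed'` remains
available for users who want θ anchored exclusively to observed responses;
whichever scope is chosen applies consistently to every Metropolis
evaluation in a run.

### Parameter prior

The parameter prior is flat.  On realistically sized networks the PLF
dominates and the posterior is proper in practice; on tiny graphs, or in
near-saturated regimes with almost no negative examples, the likelihood can
be non-decreasing in a coefficient direction (the Bayesian analogue of
separation) and the chain then drifts along the flat direction.
`McmcConfig.theta_bounds` optionally restricts the prior to a componentwise
box, which restores propriety; the enumeration-oracle test uses the box
[−3, 3]³ to match its parameter grid exactly.  Unbounded remains the
default.

## Estimation

`fit_logistic` is Newton/IRLS to gradient max-norm < 1e−8 or 100 iterations
(a 3-parameter problem converges in far fewer; hitting the cap signals
separation).  Covariance is the inverse observed Fisher information.
Complete separation is detected (perfect classification with diverged
coefficients) and reported as non-convergence with a warning; callers fall
back to `fit_penalized`.  The penalized fit is Firth's modified score —
the Jeffreys-prior penalty ½·log|X'WX| — which removes the leading-order
bias and keeps estimates finite on any finite input, including all-equal
responses.  Constant or collinear predictor columns are dropped and
reported as coefficient 0 with infinite variance rather than an arbitrary
value.

## Kernel logistic regression comparator

KLR replaces raw neighbor counts with diffusion-kernel-weighted sums:
K = expm(β_d·H) with H = A − D the opposite Laplacian, computed densely by
scaling-and-squaring (and refused above a configurable node cap, default
3000, because the dense exponential is what makes KLR impractical at
scale).  For node i the predictors are s1_i = Σ_{j annotated positive, j≠i}
K_ij and s0_i likewise over annotated negatives; unannotated proteins feed
neither predictor, and the diagonal is excluded to mirror the neighbor-sum
form of the MRF conditional.  A logistic model is fit on the annotated
nodes and scores every node.  The diffusion constant must be tuned per
network: the default is 1.0, but on the synthetic benchmarks here values
near 0.1 perform markedly better (larger values oversmooth), and the
`evaluate` command accepts a comma-separated grid.

## Evaluation protocol

Masking experiments hide a stratified sample of the annotated labels
(proportional POS:NEG quotas, largest-remainder rounding, deterministic
given the seed); originally-unannotated proteins are never masked but stay
in the network.  AUC is computed by the Mann–Whitney identity with midranks
(ties count one half) and the ROC curve by a descending sweep over distinct
scores.  PR20R is the precision at the smallest cutoff whose recall first
reaches 20%, non-interpolated, with all items tied at the cutoff included.
Recall is defined on the masked test set only.

## Synthetic benchmarks

The generator composes a random graph (Erdős–Rényi or Barabási–Albert — the
latter reproduces the heavy-tailed degree structure of real interaction
networks), an MRF label draw (all states initialized by fair coins, then
500 full Gibbs sweeps at θ_true; attractive couplings are kept below the
phase-transition regime so the draw stays mixed and the chain mixes fast),
and a stratified mask.  All three stages are sub-seeded from one seed, so a
benchmark is byte-reproducible.

Three condition presets are shipped.  `SATURATED_ER` (ER n=500, p=0.02,
θ=(−1, 0.6, −0.1), 50% masked) sits near the all-positive phase (~97%
positives) and stresses the samplers with severe class imbalance; in this
regime γ is weakly identified and, under the unbounded flat prior, its
posterior mean can drift to large values while α and β are recovered —
coverage of the truth at ±3 posterior SD still holds because the posterior
spread widens accordingly.  `BALANCED_ER_300` (n=300 at mean degree ~11,
typical of high-confidence physical interaction networks, prevalence ~0.5)
is used for between-chain agreement.
`SCALE_FREE_BA_400` (BA n=400, m=5, prevalence ~0.35) is where the
two-step baseline's pruning bias is expressed; on Erdős–Rényi graphs
Poisson splitting makes the hidden part of a neighborhood independent of
the observed part, which largely cancels the bias, so the scale-free preset
is the appropriate testbed for the method comparison.

What the generator does not emulate: overlapping functional modules,
GO-term hierarchy, edge confidence noise, and assortative annotation bias
of real networks.  Passing tests therefore demonstrate correctness of the
inference machinery and the qualitative method ordering under the model's
own assumptions, not real-data AUC levels.

## Problem sizes and run lengths

Default run length is 2000 iterations with a 500-iteration (25%) burn-in,
which between-chain comparisons show is sufficient for these network sizes;
both are flags.  The shipped experiments use networks of 300–500 nodes,
5–30 replicates per statistical check, and 20000 iterations for the tiny
enumeration-oracle comparison.  A single 2000-iteration joint run on a
500-node, ~2500-edge network takes well under a second (the sweep kernel is
numba-compiled; all randomness is pre-drawn from one seeded generator per
run, so results are exactly reproducible).

## Known limitations

- One term at a time; no joint modeling across the GO hierarchy.
- Single network; no multi-source fusion.
- The flat-prior posterior can be improper in saturated or tiny problems
  (see above); use `theta_bounds` there.
- Annotations are taken as already propagated through the ontology; no
  true-path reasoning is performed.
- The negative set for a term is "annotated to at least one other term",
  which is the conventional reading but can mislabel incompletely
  annotated proteins.
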