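# bmrf — Bayesian Markov random field protein function prediction

`bmrf` predicts protein function from interaction networks by
guilt-by-association: proteins that interact tend to share biological
processes.  It is aimed at computational biologists who have an interaction
network (e.g. a purification-enrichment-scored physical interaction set) and
partial GO annotation, and want calibrated per-protein probabilities for
individual terms.

## The model

For one functional term, protein states x_i ∈ {0, 1} form a homogeneous
pairwise Markov random field on the network.  The full likelihood has an
intractable normalizing constant, so inference uses the pseudolikelihood,
whose node conditionals are a logistic regression on neighbor counts:

    logit P(x_i = 1 | x_N(i)) = α + β·M1_i + γ·M0_i

where M1_i / M0_i count the neighbors of i in state 1 / 0 and
θ = (α, β, γ).  Three methods are implemented:

- **BMRF** (`bmrf.bmrf`) — the joint Bayesian sampler: Gibbs sweeps over the
  unknown labels alternate with adaptive Differential Evolution MCMC (DEMC)
  updates of θ on the pseudolikelihood, so predictions average over both
  label and parameter uncertainty.  The DEMC proposal is
  θ* = θ + γ_step·(Z[R1] − Z[R2]) + e with γ_step = 2.38/√(2d) and Z the
  archive of past states.
- **MRF-Deng** (`bmrf.mrf_deng`) — the classic two-step baseline: fit θ once
  on the annotated subnetwork (ignoring unannotated neighbors), then Gibbs
  sample at fixed θ̂.
- **KLR** (`bmrf.klr_predict`) — kernel logistic regression on the diffusion
  kernel K = expm(β_d·(A − D)); accurate but impractical for large networks
  because of the dense matrix exponential.

Masking-based evaluation (stratified hiding of annotated labels, AUC and
precision at 20% recall) and a fully seeded synthetic benchmark generator
(random networks + MRF-distributed labels at known θ) round out the package.
See `docs/methods.md` for the complete methodological account.

## Worked example

`examples/01_simulate_and_predict.py` simulates a 300-protein network with
labels drawn from the MRF at θ = (−0.9, 0.25, −0.1), hides half of the
annotation, and runs the joint sampler:

```
network: 300 proteins, 1597 interactions; 150 labels masked

generating theta: (-0.9, 0.25, -0.1)
posterior theta:  (-0.896±0.688, 0.290±0.113, -0.133±0.119)   DEMC acceptance rate 0.194

top 10 predictions (posterior = probability the protein carries the term):
   1. p175  posterior=0.796  true state=1
   2. p298  posterior=0.765  true state=1
   3. p059  posterior=0.750  true state=1
   ...
```

The posterior mean of every θ component lands within one posterior SD of
the generating value, and the ten highest-posterior proteins are all true
positives.  The other examples compare the three methods under masking
(`02`), run the file-based workflow from edge list to ranked prediction
table (`03`), and demonstrate parameter recovery versus the baseline's
inflated estimates (`04`).

The same workflows are scriptable from the shell:

```sh
bmrf simulate --n 300 --param 0.037 --theta=-0.9,0.25,-0.1 --seed 3 --outdir bench/
bmrf predict  --edges bench/edges.tsv --annotations bench/annotations.tsv \
              --terms GO:SYNTH --method bmrf --output predictions.tsv
bmrf evaluate --edges bench/edges.tsv --annotations bench/annotations.tsv \
              --terms GO:SYNTH --methods bmrf,mrf-deng,klr --output eval.tsv
```

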