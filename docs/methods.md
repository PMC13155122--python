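# Methods

## Problem and model

Spot-level spatial transcriptomics measures, at each capture location
("spot"), the summed expression of an unknown handful of cells. Given a
single-cell reference `X` (genes × N_c) and a spot matrix `Y` (genes × N_s),
`disco` frames deconvolution as a 0/1 combinatorial-optimization problem over
the bipartite assignment matrix `A ∈ {0,1}^{N_c × N_s}`: each row of `A`
carries exactly one 1 (every reference cell is placed in exactly one spot),
and a good assignment minimizes the discrepancy `‖XA − Y‖_F`. Cellular
composition per spot (counts and type proportions) then follows directly
from `A` and the reference cell-type labels.

Rather than optimizing each instance from scratch, the solver is a
*conditional generative model*: a discrete denoising-diffusion process over
the edges of the assignment graph, trained on a corpus of simulated
instances with known solutions, so one pretrained network can be applied to
new `(X, Y)` pairs in a feed-forward manner.

### Forward process

Each edge is an independent two-state Markov chain. At step `t` the edge
flips with probability `β_t` (kernel `Q_t = [[1−β, β], [β, 1−β]]`). The
marginal after `t` steps uses the cumulative kernel `Q̄_t = Q_1⋯Q_t`. The
symmetric kernel contracts toward uniform at rate `(1 − 2β_t)` per step, so
a schedule is *mixing* when `∏(1 − 2β_t) ≈ 0`; the default linear schedule
(`T = 1000`, `β` from 1e−4 to 0.02) leaves `|Q̄_T − 1/2| < 1e−9`.

### Reverse process

The denoising network predicts the clean state `Ã_0` directly
(A0-parameterization); the reverse transition is assembled from the exact
two-state Bayes posterior
`q(A_{t−1} | A_t, A_0) ∝ (Ã_t Q_tᵀ) ⊙ (Ã_0 Q̄_{t−1})`.
Because numerator and denominator are both linear in the one-hot `Ã_0` row,
substituting the network's predicted probabilities is exact and
self-normalizing. Accelerated sampling retains a strictly increasing
subsequence `τ_1 < … < τ_K = T` and replaces the single-step kernel by the
cumulative kernel over each gap. The `t = τ_1` endpoint reads the predicted
`Ã_0` distribution out directly. Denominators are clamped at 1e−12.

### Denoising network

A bipartite anisotropic graph network. Cells and spots are embedded from
their log1p, L2-normalized expression profiles by *unshared* linear maps
(unshared so the two streams can absorb reference/platform batch effects);
edges embed the binary `A_t` value through a learned two-state lookup; the
timestep enters through sinusoidal features and a two-layer MLP. Each layer
applies (i) temporal injection `ẽ = e + ReLU(W h_t)`, (ii) an edge update
`ReLU(LN(ẽE + u_i M + v_j N))`, and (iii) gated node updates in which the
sigmoid of the fresh edge embedding gates a projection of the opposite
partition, aggregated by the mean. A 2-layer MLP decodes final edge
embeddings into two-class probabilities. Design points that the
architecture sketch leaves open, resolved here:

- residuals are post-activation (`e ← e + ReLU(LN(…))`), likewise for nodes;
- aggregation over the opposite partition is the mean (scale-stable in
  `N_c`, `N_s`);
- `h_t` is layer-shared; each layer has its own injection matrix `W`;
- LayerNorm is standard per-embedding with learned gain/offset, ε = 1e−5;
- the final layer omits the node update: only edge embeddings reach the
  decoder, so a last-layer node update would be structurally gradient-dead;
- embedding weights hold `gene_capacity` input rows; datasets with `d <
  capacity` genes use the first `d` rows, larger gene sets are first reduced
  to the top `capacity` highly variable genes (dispersion of log1p pooled
  data);
- a `sqrt(capacity)` gain after the embedding keeps node activations O(1)
  for unit-norm inputs, and the edge-state lookup is initialized small
  (std 0.1) so the expression pathway is not drowned out early in training
  by the shortcut of copying `A_t`;
- cell- and spot-embedding weights start from the same random matrix (they
  remain independent parameters and diverge during training).

The network never receives cell-type labels or spatial coordinates.

### Training objective

`L = L_dpmm + λ1 L_p + λ2 L_f + λ3 L_d`, all λ = 1.

- `L_dpmm`: mean per-edge cross-entropy of the true clean state (the
  variational bound collapses to this under the A0-parameterization);
- `L_p`: RMSE between true per-spot type proportions and *soft* proportions
  computed from the predicted edge probabilities (labels enter only here);
- `L_f`: mean of `A − A²`, zero exactly on binary matrices;
- `L_d`: KL between the (renormalized) column-mass distribution of the soft
  prediction and the uniform distribution over spots, `0·ln 0 := 0`.

The three regularizers act on the soft prediction so the objective is
differentiable end to end. Per update, one (or `batch_size`, by gradient
accumulation) instance is drawn, genes optionally shuffled (one shared
permutation of X and Y rows), multiplicative mean-one log-normal noise
applied to `Y`, `t` drawn uniformly from `1..T`, and `A_t` sampled from the
forward marginal. Optimizer: Adam (full-scale default rate 2e−4).

### Inference

Sample `A_T` i.i.d. Bernoulli(1/2); walk the DDIM subsequence down,
predicting `Ã_0` and sampling the accelerated posterior; decode the final
soft prediction by row-wise argmax (ties to the lowest spot index), which
guarantees feasibility. Proportions are hard counts `q_ij = N_ij / N_i`;
reconstruction is `X·A`; per-spot cosine similarity against `Y` is the
self-diagnostic. Because the CO objective `‖XA − Y‖_F` is computable
without ground truth, `deconvolve_best_of` samples several candidate
solutions and keeps the lowest-cost one — the natural way to spend extra
inference budget with a stochastic solver.

Uncertainty: repeat the sampling `n_repeats` times, treat each (spot, type)
proportion as an observation, and build percentile-bootstrap intervals of
the mean (default 1000 resamples, α = 0.05). Intervals are clamped to
contain the observed mean, which raw percentile intervals can miss by a
hair on tiny skewed samples.

Fine-tuning for a new dataset (the starred variant) updates *only* the
2-layer decoder for 30 epochs at rate 1e−4, descending the negative mean
per-spot cosine between `X·Ã_0` (soft, from a short K = 10 rollout with
gradients through the final prediction only) and `Y`; zero-norm spots are
excluded from the mean.

## Synthetic oracle data

The generator emulates spatially resolved single-cell simulation followed
by spot binning:

- per-type gene means are log-normal(0, 1); per-cell counts are
  negative-binomial around the type mean via a gamma–Poisson mixture
  (dispersion 0.5);
- spatial patterns: `clustered` (types in Gaussian blobs, σ = 0.16 on the
  unit square), `mosaic` (checkerboard patches), `uniform`;
- spots are half-open grid squares of side `window` anchored at the
  coordinate bounding-box minimum; empty squares yield no spot;
  `Y = X·A` exactly at noise level 0, with optional multiplicative
  log-normal noise on `Y`;
- the reference geometry (1224 cells, 4 types, default window 1/16) yields
  on the order of 255 spots (≈4.8 cells per occupied spot);
- corpus instance `i` uses seed `corpus_seed + i`; splits are positional,
  so test instances are disjoint from training by construction.

What the simulator does *not* model: platform dropout, segmentation errors,
cell-type-specific library-size differences, spatial gradients within a
type, or real marker-gene structure. Passing the desk-scale tests shows the
solver recovers composition when the reference and spots come from the same
generative process; it does not certify performance under real cross-
platform batch effects.

## Problem sizes used by the test suite and reproduction script

Full-scale pretraining (10⁴ large instances, 6-layer width-256 network,
days of GPU time) is out of scope for this package's own checks. The
package ships a *tiny preset* chosen as its standard desk-scale experiment:

- corpus: 300 instances of 60 cells × 40 genes × 3 types (~12 spots),
  split 240/30/30;
- network: 2 layers, width 32, gene capacity 64, time features 16;
- schedule: `T = 50` with `β` from 1e−3 to 0.1 — rescaled so the shorter
  chain still mixes (`∏(1−2β_t) ≈ 0.006`); the full-scale β range at
  `T = 50` would leave `Q̄_T` far from uniform and break the uniform-prior
  initialization at inference;
- training: 2000 Adam updates at rate 3e−3, gradient accumulation over 8
  instances per update, Y-noise 0.1, gene shuffling off (at this scale the
  permutation-robustness it buys is not learnable and it slows
  convergence);
- inference: K = 2 retained steps with 4 best-of-cost candidates for the
  held-out evaluation; K = 10 with 20 repeats for the bootstrap task.

On this preset the solver's held-out mean proportion RMSE is ≈ 0.19 — about
0.42× the random feasible-assignment baseline — with mean reconstruction
cosine ≈ 0.86 (values recomputed by `scripts/acceptance.py`, not asserted
here). A direct profile-similarity matching rule reaches ≈ 0.12 RMSE on the
same instances, so part of the remaining gap is optimization capacity of
the deliberately small network, not an identifiability limit. Hard argmax
decoding also quantizes proportions on 1–4-cell spots, which inflates RMSE
relative to the soft prediction by ≈ 0.02–0.03.

## Numerical choices

- all computation in float64; posteriors exact to 1e−12 against brute-force
  enumeration;
- log/divide guards at 1e−12 (cross-entropy clamp, KL renormalization,
  cosine norms);
- argmax tie-breaks to the lowest index; empty spots produce all-zero
  proportion rows everywhere;
- gradients flow through a small reverse-mode autodiff engine
  (`disco.autodiff`) whose operations are checked against central finite
  differences in the test suite.

## Known limitations

- The assignment space places *every* reference cell somewhere; when the
  reference dwarfs the tissue content, subsample the reference first.
- Desk-scale training does not produce a foundational, dataset-agnostic
  solver; gene shuffling and noise augmentation recover their value only at
  much larger corpus sizes and widths.
- Per-spot JSD is reported as the mean over spots; spots with an all-zero
  row in both matrices contribute zero.
- The bootstrap quantifies sampling variability of the solver, not model
  misspecification; intervals can undercover when the true proportion sits
  at the simplex boundary.
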