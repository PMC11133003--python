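# Methods

## Model

The network is a four-stage feed-forward map. A gene layer takes
standardized expression (samples × genes). A *sex-specific pathway layer*
follows: a pair of weight matrices `W_G^male`, `W_G^female` (q × r) with a
shared binary gene–pathway mask `M_G`, and per-sex bias vectors of length
r (one entry per pathway node; biases live on target nodes throughout).
Each sample is routed through the branch of its sex; `route_as` can force
either branch, which never touches stored parameters and is the mechanism
for cross-sex counterfactuals. The remaining layers are shared by sex:
one or more masked hidden layers (masks start dense) and a linear output.
The survival head omits the bias because a Cox partial likelihood is
invariant to an intercept; the risk head applies a sigmoid with a bias.
ReLU is the only supported activation. Samples are rows everywhere, so
the output stage computes `H·W_H` with shapes (n×s)(s×1).

Assumptions inherited from this design: expression is standardized per
gene before entering the model; only pathway-annotated genes participate
(genes in no retained gene set are dropped when the mask is built);
pathway membership is taken at face value from the GMT input; and the
male/female difference is expressed entirely in the first layer — the
hidden layers model pathway interactions common to both sexes.

## Losses and training

* Survival: average negative Cox log partial likelihood,
  `-(1/d) Σ_{i:δ=1} [z_i − log Σ_{j: t_j ≥ t_i} e^{z_j}]`, Breslow
  handling of tied event times (tied events share a risk set). The
  analytic gradient is implemented alongside and is finite-difference
  checked in the tests.
* Binary: mean binary cross-entropy; risks at the (0,1) boundary are
  clamped at 1e-7 and logged.

Optimization is full-batch Adam (lr 1e-2) with L2 penalty on the masked
effective weights, early stopping on validation loss (patience 80, at most
500 epochs), retaining the best-validation parameters. Two strategies are
run and the one with the lower validation loss is kept:

* **standard** — seeded masked-fan-in uniform initialization, all
  parameters trained jointly (L2 = 5e-2);
* **warm start** — both sex branches initialized as literal pathway
  enrichment scores (every member gene of a pathway gets the same weight,
  scaled to roughly unit node variance, bias +2 so the ReLU starts in its
  linear regime); the gene layer is frozen while the shared tail trains
  for up to 300 epochs, then everything trains jointly (L2 = 5e-2).

Rationale: at the sample sizes this model targets (hundreds of samples,
hundreds of genes), learning the gene→pathway aggregation from scratch is
the statistical bottleneck — a per-sex regression on raw genes is near
chance while the same regression on pathway mean scores is not. Starting
from the enrichment representation recovers most of that gap, but a pooled
warm-up is blind to effects whose sign flips between sexes, where the
standard run does better; validation selects between them per dataset.
The warm-start L2 of 5e-2 is deliberately strong: with weaker penalties the
joint phase drifts null-pathway weights toward training-label noise, which
inflates the false-discovery rate of the global importance procedure.

Weight initialization scales each node's uniform range by its unmasked
fan-in. Determinism: all randomness flows from explicit integer seeds
(model init, splits, subsampling, permutation sampling); two runs with the
same seeds produce bitwise-identical loss traces.

## Data handling

Splitting is 80% development / 20% test with stratified sampling — by sex
for survival, by sex × disease status for the binary task — and the
development set is split 80/20 again into training/validation. Partition
sizes per stratum follow the fractions to within rounding (half-up); a
stratum too small to appear in all three partitions is an error.
Normalization is per-gene standardization with training-set mean and
*population* standard deviation; constant training genes are dropped with
a warning, and transforming an already-normalized dataset is rejected so
training statistics cannot be applied twice.

## Sparse coding of the hidden masks

Hidden-layer masks are sparsified by magnitude pruning selected on
validation loss: for each fraction ρ in a grid, the ⌊ρ·#entries⌋
smallest-magnitude effective weights of the layer are masked (ties broken
by row-major index, which makes pruned sets nested across ρ); the ρ with
the lowest validation loss wins, ties going to the larger ρ. Layers are
processed in order, each conditioned on the previous choices; the
gene–pathway mask is fixed by annotation and never pruned. After pruning
the model is briefly fine-tuned and kept only if validation improves.
Pruning is per layer; a joint cross-layer budget was considered and
rejected for simplicity.

## Global interpretation

Importance of a feature (gene or pathway) in a sex is the mean over that
sex's samples of |∂output/∂node × node value| at the feature's layer,
computed with the model's own backward pass. Significance is a two-sided
rank-sum test of node values between outcome groups within the sex —
cases vs controls for the binary task; top vs bottom tertile of the
predicted prognostic index for survival (the middle tertile is unused) —
followed by Benjamini–Hochberg FDR within each (level, sex) family.
A feature is *shared* if significant in both sexes at the adjusted
threshold (default 1e-5, configurable; the simulation studies in this
repository use 0.05), *male-/female-specific* if significant in exactly
one, otherwise *none*. A feature with exactly zero importance in a sex is
never called significant there: a node with no influence on the prediction
is not part of the predictive mechanism regardless of its marginal
association. A rank test was chosen over permutation because it can
certify very small p-values at feasible cost and is distribution-free.

Two caveats are documented rather than hidden. For survival, the outcome
grouping is model-derived (prognostic tertiles), which can make null
features mildly significant through the model itself; the binary grouping
is external and does not have this issue. And when interpretation is run
on data that includes training rows, overfitting can leak label noise into
node values — the strong warm-start penalty above keeps the measured null
FDR at its nominal level under the defaults, which the acceptance checks
verify empirically.

## Local interpretation

Shapley values are computed over the pathway nodes of the shared
sub-network pathway layer → output. The value of a coalition S is the
mean model output over a background of reference pathway activations with
the features in S replaced by the explained sample's activations; the base
value is the mean background prediction. With r ≤ 15 pathways the exact
subset enumeration is used; otherwise antithetic permutation sampling
(default 64 permutations) whose telescoping makes attributions sum to
`f(x) − E[f(x)]` already, with any float residual spread uniformly.
The default background is up to 200 training samples (seeded subsample)
routed through the same branch as the explained sample. Enrichment
direction (the waterfall arrow) is the sample's activation relative to the
background mean for that pathway. Waterfall tables list the top-k
pathways by |φ| plus one aggregate term for the rest; summary tables keep
every (group, pathway, sample) point; the cohort contrast pairs each
sample's attributions under both routings and flags sign flips.

## Synthetic data

The generator emulates the structure the model assumes: i.i.d. standard
normal expression per gene; r pathways of fixed size laid consecutively
over the gene universe with a small overlap between adjacent pathways (so
the mask is not orthogonal); a *pathway score* defined as the mean
expression of member genes; and a linear predictor per sample that sums
sex-signed planted effects times pathway scores. Survival times are
exponential with hazard `λ₀·exp(η)` and independent uniform censoring
whose upper bound is solved by bisection to hit the target censoring rate;
binary labels are Bernoulli(σ(η)) with optional label flipping.

Defaults (one choice, used throughout): n = 600 samples, q = 500 genes,
r = 30 pathways of 15 genes with 2-gene overlap, equal sex ratio, 30%
censoring, baseline hazard 0.1 (time unit arbitrary), 5% label noise.
The matched-pair scenario plants a single pathway at β = +1 in males and
−1 in females against a twin with +1 in both, sharing every random draw
and the censoring bound so the pair differs only through the female
coefficient. The interpretation-recovery scenario plants one male-only,
one female-only and one shared pathway at β = 3: a pathway score has
standard deviation 1/√15 ≈ 0.26, so β = 3 is ≈ 0.8 linear-predictor
standard deviations per pathway — strong but within the range of a
realistic driver pathway, and the smallest round value at which within-sex
rank tests have adequate power at n = 600.

What the generator does *not* emulate: count-data marginals, library-size
or batch effects, gene–gene correlation beyond pathway co-membership, real
pathway topology, or covariates. Passing tests therefore demonstrate
correctness of the machinery and behavior under the stated statistical
structure, not performance on real cohorts.

## Numerical choices and degenerate inputs

Breslow ties in the Cox loss; log-sum-exp stabilization with the global
maximum; population (ddof = 0) standard deviation in the normalizer;
pruning ties broken by stable row-major order; equal prediction scores in
stratification keep original order; the five risk groups absorb the
remainder into the highest-risk groups (n = 81 → 17/16/16/16/16); the
ideal disease ratios fill groups with all true cases first. Errors are
raised for: no events, empty pathway collections after filtering, missing
genes at alignment, single-class AUC, no admissible C-index pairs, strata
too small to split, unfitted or re-applied normalizers, and unknown sex
labels or tasks.

## Problem sizes used in the checks

The test suite and the acceptance script run everything on synthetic data
at the default scenario sizes above (n = 600 for the comparison studies;
smaller n for unit fixtures), with 10–20 simulation seeds for the
repeat-level studies and exact Shapley checks at r ≤ 8. These sizes are
the package's chosen desk-scale study conditions.

## Known limitations

* With a weak single-pathway signal (β = ±1 → ≈ 0.26 sd of linear
  predictor), the network's test C-index trails an oracle given the true
  pathway scores by a few points; the sex-routed advantage over a
  sex-blind ablation at n = 600 is real but small (≈ 0.01–0.03 C-index
  over 10 seeds), and seed-to-seed variance is of the same order.
* Validation-loss strategy selection occasionally prefers the warm start
  on opposite-direction data, where it is the weaker choice.
* The survival-task significance grouping (prognostic tertiles) is
  model-derived; see the caveat under global interpretation.
* Exact Shapley cost grows as 2^r; above 15 pathways the sampling
  approximation is used, whose per-pathway values (not their sum) carry
  Monte-Carlo error.
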