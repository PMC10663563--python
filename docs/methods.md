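# Methods

This note records the modelling assumptions, the parameters that matter, and
the numerical choices behind each module, in the order the pipeline runs.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and normalization

Coordinates are real-valued micrometres in a planar Cartesian frame
throughout; no pixel or array-index convention is exposed, because all of the
alignment mathematics is metric. Counts are nonnegative integers; duplicate
gene names are collapsed by summation (conservative and deterministic, logged).
Gene-space harmonization restricts the reference and every slice to the sorted
intersection of their gene sets and is idempotent.

Model inputs are library-size normalized to the median spot total and
log1p-transformed. For the deconvolution model we additionally z-score each
gene over the pooled simulated-plus-real data (statistics stored in the model
and reapplied at prediction time). Without this step the autoencoder's squared
error is dominated by a handful of high-variance genes and the latent space
loses cell-type information; with it, held-out recovery improves from partial
(two to three of five types) to complete. Raw counts are used wherever counts
are the object being manipulated (pseudo-spot summation, downsampling).

One global seed drives derived per-module seeds (fixed offsets), so every
stage is bit-reproducible on a given platform without coupling modules.

## Pseudo-spot simulation

The generator emulates a sequencing-based ST experiment: each spot receives
`N_c ~ Normal(mu_c, delta_c)` cells of `N_t ~ Normal(mu_t, delta_t)` types
(defaults 10, 5, 5, 2.5). Draws are rounded and clamped (`N_c >= 1`,
`1 <= N_t <= min(N_c, #types)`) rather than redrawn, keeping the procedure a
deterministic function of the seed. One uniform `r_c` per spot selects the
type-sampling rule — empirical frequency, normalized inverse frequency, or
normalized square-root frequency — so rare types still appear in the training
set; types with zero frequency are excluded before inversion. The `N_t` types
are drawn without replacement under that rule, renormalized over the chosen
subset, and cells are then sampled with replacement (small references cannot
be exhausted). The ground-truth label of a spot is the fraction of sampled
cells per type, which lies on the simplex by construction.

Downsampling to a target library size is multivariate hypergeometric: draw
`target_total` of the spot's existing transcripts without replacement. This
preserves expected gene proportions, never increases a count, and hits the
target exactly. Per-spot targets are `Normal(mu_L, sigma_L)` draws (estimated
from a real slice) rounded and clamped to `[1, total]`.

The synthetic single-cell reference is gamma-Poisson (negative binomial) with
a log-normal baseline across genes and disjoint per-type marker blocks
overexpressed by `exp(marker_logfc)`; type frequencies come from a Dirichlet
draw so the composition is uneven but reproducible. The 3D stack generator
places jittered-grid spots in a 1400 × 1700 µm field, assigns parallel banded
domains whose boundaries drift slowly with depth, gives each domain a
composition signature (spots draw Dirichlet noise around it), and synthesizes
counts from type-specific gene programs. A slice-level batch effect is a
multiplicative log-normal distortion of compositions, renormalized. The
perturbation protocol mirrors serial sectioning: every slice after the first
is randomly mirrored, rotated uniformly on 0–360°, translated 300–2000 µm per
axis with random sign, and every slice loses a `crop_ratio` fraction of its
spots from one randomly oriented edge. True transforms and retained indices
are recorded, and the perturbation is exactly invertible on retained spots.

What the generator does *not* emulate: spatial expression gradients within a
domain, platform-specific noise (optical crowding, segmentation errors),
nonrigid tissue deformation, and partial z-overlap between sections. Passing
tests therefore demonstrate correctness of the algorithms under the stated
generative assumptions, not performance on any real platform.

## Deconvolution

Architecture follows the fixed design: VAE hidden layers 128–64–128 (Gaussian
latent, mean-squared reconstruction, KL weight 1e-4, He initialization),
predictor and recovery heads with three 512-unit ReLU layers, softmax output
for proportions. The VAE is pretrained for 500 full-batch epochs (Adam,
lr 3e-3) on the union of simulated and real spots; the encoder mean is then
used as a fixed embedding. Training alternates (1) a predictor step minimizing
the composition loss `(1 − cosine) + KL(truth ‖ pred)` on simulated spots
(KL floored at 1e-8, natural log) and (2) a joint step on both datasets
minimizing the latent-recovery loss plus the squared MMD between the
predictor's last-hidden activations, with the kernel bandwidth set to that
layer's width (512). Training stops when Loss-change per epoch falls below
1e-3 (after a 150-epoch minimum, capped at 600).

Two choices deserve emphasis. First, the recovery loss compares R's output to
the latent vectors with `(1 − cosine) + MSE`; a divergence term is not
applicable to unconstrained reals, so the magnitude constraint is mean squared
error. Second, the joint step runs at one tenth of the predictor's learning
rate (predictor lr 1e-3): the alignment terms are auxiliary, and at equal
rates they visibly degrade the supervised fit. Batches are full-batch up to
8192 spots, minibatched with per-epoch reshuffling beyond that.

The model's gene space is the union of the top `n_markers_per_type` reference
markers by a one-vs-rest rank-sum z-score, intersected with the slice's genes.

## Spatial domains

Per-slice graphs connect each spot to its k nearest neighbours (k = 6 for
spot arrays, 25 for single-cell resolution), symmetrized by `max(A, Aᵀ)`, and
are block-diagonal in one global graph — no cross-slice edges; cross-slice
correspondence is the alignment stage's job. The scaled Laplacian
`L̃ = 2L/λ_max − I` uses a deterministic power-iteration estimate of `λ_max`
(tolerance 1e-10, inflated by 1e-7 relative so the spectrum stays inside
[−1, 1] despite iteration error). Chebyshev filtering uses the standard
recurrence with order K = 2 by default; each layer carries one coefficient
block per order (Xavier initialization).

The network is composition → 64 → 16 (latent) → 64 → composition, with a
softmax on the output layer so reconstruction lives on the simplex. Losses:
cosine reconstruction `mean(1 − cos(H0, H4))`; smoothness
`mean |H2 − neighbour-mean(H2)|`; discriminator cross-entropy on the latent
(two 64-unit hidden layers). Adversarial training is standard two-player
min-max: the discriminator minimizes its cross-entropy on the detached
latent, the GCN minimizes `α_C·L_C + α_S·L_S − α_D·L_D` (defaults 1, 1, 0.5)
with RMSProp (lr 2e-3). With a single slice the adversarial branch is
disabled automatically. Every epoch, K-means (seeded) clusters the latent
and the Davies–Bouldin score is recorded; training stops once the total loss
change is below 1e-4 *and* the DBS has not reached a new minimum within a
10-epoch patience window (40-epoch minimum, 300 cap). Final labels come from
K-means with 10 restarts on the last epoch's latent.

## Rigid alignment

Slices are first centered at the origin. For each consecutive pair the
moving slice is transformed by `S′ = R·M·S + T`; the objective averages, over
the overlapped moving spots, the fraction of their mutual nearest neighbours
in the fixed slice sharing their domain label, plus the penalty
`−(n_o/n_j − 1)^p` (p = 2 by default). A moving spot counts as overlapped
when its nearest *mutual* neighbour lies within the threshold distance
(median distance to the 2k-th neighbour within the fixed slice). Mutuality
already prunes the k-NN lists, and a spot can retain fewer than k mutual
neighbours, so the nearest-mutual reading is the permissive one; it makes
"identical slices → all spots overlap" hold exactly. `n_o` is counted on the
transformed moving slice, consistently with how the overlap set is defined.

Differential evolution (population multiplier 20, up to 60 generations,
seeded, no gradient polish) searches `(θ, dx, dy)` with translation bounds
set to the sum of the two slices' bounding-box half-diagonals — any physical
overlap is feasible. The mirror flag is handled by solving both branches and
keeping the better optimum, so the continuous optimizer stays continuous. The
population is seeded with the identity pose: after centering it is the
natural initial guess, and without it self-alignment of identical slices can
settle on a mirrored local optimum.

The agreement term is piecewise constant, so the optimizer stops anywhere on
a plateau roughly one neighbourhood radius wide — and a near-perfect pose can
even score slightly *below* a shifted one, because misalignment decouples
mutual-neighbour pairs that straddle domain boundaries. Each DE optimum is
therefore polished by a domain-gated rigid ICP (nearest same-domain neighbour
matching within the overlap threshold, then a least-squares
rotation/translation via Kabsch, iterated), accepted when its objective is
within 0.05 of the DE value. The polish recovers known transforms to below
one median nearest-neighbour spacing; the unpolished argmax leaves roughly a
third more residual. Exact saturation of the objective at 1 requires that
every spot's mutual neighbours share its domain — true for spatially
separated domain clusters, not for banded tissue, where boundary spots always
mix neighbourhoods.

Stacking is sequential: slice j is aligned to the already-transformed slice
j−1, z is index × spacing, and no global refinement pass is applied.
Nonrigid deformation is out of scope.

## Continuous 3D expression and spatial variability

Expression values are assumed Gaussian after log-normalization. The GP has a
constant mean `mu`, squared-exponential covariance with process variance `δ²`
and length scale `l`, and additive noise. Coordinates are centered and
divided by their root-mean-square radius before fitting — a single isotropic
scale, so likelihood ratios are invariant to rigid transforms of the input —
and the length scale is reported in those units. Initialization follows
`mu = mean(y)`, `δ = 4`, `l = λ·var(y)` with `λ` picked from
{1e-3, 1e-2, 1e-1, 1, 10} by marginal likelihood; all hyperparameters are
then refined by 200 Adam steps (lr 0.05) on the analytic gradients of the
log marginal likelihood, with Cholesky factorization and jitter escalation
(1e-8 → 1e-4) on near-singular kernels. The noise standard deviation is
floored at 1e-4 of the data's spread: the likelihood is unbounded as the
noise collapses on interpolable data, and the floor keeps the two models of
the Bayes factor on the same footing. Flat priors are used (the MAP estimate
coincides with maximum likelihood; no prior scale is specified by the model).

The null model of the Bayes factor is the analytic `l → ∞` limit: covariance
`δ²·ones + noise·I`, i.e. a shared random offset plus noise, refitted from
the same initialization. The factor is computed in log space; a constant gene
short-circuits to BF = 1, since both models coincide there. Prediction
surfaces come from an alpha-shape of the aligned cloud (Delaunay tetrahedra
kept below the circumradius threshold, boundary triangles extracted, Loop
subdivision optional); in the large-alpha limit this is the convex hull.
Surface sampling is area-weighted and seeded; the nominal budget of 500,000
points is a knob, and predictions are pointwise independent of it.

## Evaluation metrics

All statistics are implemented from their definitions and verified against
brute-force evaluations in the tests. Per-type deconvolution metrics are
columnwise PCC, RMSE, Jensen–Shannon divergence (natural log, on the spot
distribution of each type), and SSIM computed on min-max-scaled columns with
C1 = 0.01, C2 = 0.03 — the constants only make sense on a unit dynamic
range. The accuracy score ranks methods on each metric (ties averaged),
averages the four ranks and divides by the method count, so a dominating
method scores 1.0. Domain predictions are scored by per-domain Jaccard index
against the best-matching annotation layer, a shifting distance (mean
point-to-set distance from the domain's spots to that layer, nearest-spot
reading), and ARI. Batch mixing is the cluster-stratified average of
`1 − |silhouette|` over batch labels; clusters containing a single batch are
skipped and logged. Spatially variable genes use a per-domain one-vs-rest
two-sided rank-sum test with a natural-log fold-change filter (defaults 0.5
and p < 0.01). Alignment quality grids the common bounding box 10 × 10,
averages compositions per cell occupied in both slices, and compares the
fields by SSIM/PCC, after registering the aligned stack to ground truth with
a least-squares affine map estimated on the previous slice's shared spots.

## Problem sizes and limitations

The shipped studies use a five-type, 200-gene reference with 1,000 training
and 500 held-out pseudo-spots for deconvolution; three 300-spot slices for
domain identification; ten 300-spot slices for alignment; and 50 points with
20 null replicates for the GP calibration — sizes chosen so the full suite
exercises every stage end to end on a single CPU while leaving the algorithms
unchanged at larger scale. Known limitations: graphs and Laplacians are
dense, which is comfortable up to a few thousand spots per run but would need
sparse filtering beyond that; alignment is strictly rigid and sequential, so
errors can accumulate along very long stacks; the GP fits one gene at a time
with an `O(n³)` likelihood; and the adversarial domain model, like all such
models, equalizes distributions rather than proving the absence of batch
signal.
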