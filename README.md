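# spacelkit

A toolkit for multi-slice spatial transcriptomics (ST) analysis. Sequencing-based
ST platforms such as 10X Visium capture mRNA at spots that each contain several
cells; imaging-based platforms (MERFISH, STARmap) resolve single cells but are
collected as independent 2D sections. `spacelkit` provides the four stages
needed to turn such data into an annotated 3D tissue model:

1. **Spot deconvolution** — estimate the cell-type composition of every spot
   from a single-cell reference, by training on simulated pseudo-spots and
   aligning the simulated and real expression distributions.
2. **Joint spatial domains** — cluster spots from *all* slices at once into
   spatially coherent domains, removing slice-level batch effects
   adversarially.
3. **Rigid 3D alignment** — recover the mirror/rotation/translation of each
   serial section by maximizing a domain-agreement objective, and stack the
   slices along z.
4. **Continuous 3D expression** — fit a Gaussian process over the aligned
   coordinates and score each gene's spatial variability with a Bayes factor.

A synthetic-data module generates all the inputs needed to exercise and
validate the pipeline: multi-type single-cell references with planted
markers, pseudo-spot mixtures, layered 3D stacks with known domains and
batch shifts, and rigidly perturbed stacks with recorded ground truth.

## The models

**Deconvolution.** Pseudo-spots are built by sampling `N_c ~ N(mu_c, delta_c)`
cells of `N_t ~ N(mu_t, delta_t)` types from the reference (defaults
`mu_c = 10, delta_c = 5, mu_t = mu_c/2, delta_t = delta_c/2`), with per-spot
type sampling probabilities that switch between the empirical frequency `f_t`,
the normalized inverse `1/f_t`, and the normalized `sqrt(f_t)` so that rare
types are represented. Spot totals are thinned to match the real slice's
library-size distribution. A VAE (hidden layers 128–64–128) embeds simulated
and real spots; a predictor `E` (three 512-unit layers, softmax output) maps
latents to proportions under the loss `(1 − cosine(p̂, p)) + KL(p ‖ p̂)`; a
recovery head `R` and a squared maximum mean discrepancy
`MMD²(E₂(z), E₂(z′))` with kernel `exp(−|u − v|²/σ)`, `σ` = hidden width,
keep the two latent distributions exchangeable so the predictor transfers to
the real slice.

**Spatial domains.** Cell-type compositions are passed through a Chebyshev
graph convolutional network on per-slice k-NN graphs (k = 6 for Visium-like
arrays, 25 for single-cell resolution; filter order K = 2, so each spot sees
its first- and second-order neighbourhood). The total loss
`α_C·Loss_C + α_S·Loss_S − α_D·Loss_D` (defaults 1, 1, 0.5) combines a
cosine reconstruction of the input compositions, a latent neighbour-smoothness
term, and an adversarial slice discriminator trained min-max so the shared
latent carries no slice identity. K-means on the bottleneck yields domain
labels; the Davies–Bouldin score of that clustering doubles as a convergence
criterion.

**Alignment.** Each slice is centered and rigidly transformed
(`S′ = R·M·S + T`, `M = diag(flip, 1)`). The alignment objective function
scores, over the overlapped spots of the moving slice, the fraction of mutual
nearest neighbours in the fixed slice that share the spot's domain label, and
penalizes partial overlap with `f(x) = −(x − 1)^p`. Differential evolution
searches the pose (both mirror branches), and a domain-gated rigid ICP polish
centers the result within the objective's plateau.

**Spatial variability.** For each gene, a GP with constant mean and
squared-exponential covariance `δ²·exp(−|x − x′|²/(2l²))` plus Gaussian noise
is fitted by marginal-likelihood ascent (grid-searched length-scale
initialization, then Adam on analytic gradients). The Bayes factor compares
this model against its `l → ∞` reduction (shared offset plus noise); BF > 1
indicates spatial structure. Prediction surfaces come from an alpha-shape
mesh of the aligned point cloud with Loop subdivision.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from spacelkit import (
    generate_stack3d, perturb_stack, build_graph, train_splane, assign_domains,
    align_stack, SplaneConfig, ScubeConfig,
)
from spacelkit.metrics import alignment_recovery

# three serial sections with three banded domains and a slice batch effect
stack = generate_stack3d(n_slices=3, spots_per_slice=300, n_domains=3,
                         batch_shift=0.6, seed=7)
graphs = [build_graph(sl.coords, k=6) for sl in stack.slices]
model = train_splane(stack.compositions, graphs, SplaneConfig(n_domains=3, seed=0))
labels = assign_domains(model)
truth = np.concatenate(stack.domain_sets)
print(f"domain recovery ARI = {adjusted_rand_score(truth, labels.labels):.3f}")
print(f"slice discriminator accuracy = {model.disc_accuracy:.3f} (chance 0.333)")

# perturb a 10-slice stack per the sectioning protocol and re-align it
stack10 = generate_stack3d(n_slices=10, spots_per_slice=300, n_domains=3, seed=1)
pert, record = perturb_stack(stack10, crop_ratio=0.25, seed=2)
aligned = align_stack([sl.coords for sl in pert.slices], pert.domain_sets,
                      ScubeConfig(seed=3, z_spacing=stack10.z_spacing))
truth_coords = [stack10.slices[i].coords[record.retained[i]] for i in range(10)]
ssim, pcc = alignment_recovery(aligned.coords, truth_coords,
                               [c.proportions for c in pert.compositions])
print(f"alignment vs ground truth: grid SSIM = {ssim:.3f}, PCC = {pcc:.3f}")
```

Output:

```
domain recovery ARI = 1.000
slice discriminator accuracy = 0.372 (chance 0.333)
alignment vs ground truth: grid SSIM = 0.964, PCC = 0.964
```

The ARI of 1.0 means the planted domains are recovered exactly despite the
batch shift; the discriminator ends near chance, confirming the latent no
longer encodes slice identity; and after perturbing every slice by a random
mirror, 0–360° rotation, 300–2000 µm translation and a 25% edge crop, the
re-aligned stack matches the ground-truth geometry with gridded
composition similarity ≈ 0.96.

A command-line interface mirrors the library:
`spacelkit <simulate|deconvolute|domains|align|gpr|evaluate> --help`.

## Layout

```
src/spacelkit/
  core_data.py   data containers, I/O, gene harmonization, normalization
  simdata.py     pseudo-spots, synthetic references, 3D stacks, perturbations
  spoint.py      deconvolution (VAE + predictor + recovery + MMD)
  splane.py      Chebyshev GCN spatial domains with adversarial batch removal
  scube.py       rigid serial-section alignment and 3D stacking
  gpr3d.py       Gaussian-process 3D expression and Bayes-factor scoring
  metrics.py     every evaluation statistic (PCC/SSIM/RMSE/JSD/AS, JI/SD/ARI,
                 batch ASW, overlap, SVG tests, gridded alignment similarity)
  nn/            minimal reverse-mode autodiff, layers, Adam/RMSProp
  cli.py         command-line entry points
docs/methods.md  modelling assumptions, parameter choices, limitations
```
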