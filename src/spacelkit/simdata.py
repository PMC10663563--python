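"""Synthetic data generation.

Covers the pseudo-spot construction used to train the deconvolution model
(cells sampled from a single-cell reference with spot-dependent type
sampling probabilities, summed, then downsampled to match a target library
size distribution), fully synthetic negative-binomial references with
planted marker blocks, layered 3D slice stacks with contiguous spatial
domains and optional slice-level batch effects, and rigid perturbations of
those stacks with a recorded ground truth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_data import CompositionMatrix, DomainAssignment, SingleCellReference, SliceData
from .scube import RigidTransform2D

logger = logging.getLogger("spacelkit")

__all__ = [
    "SpotSimConfig",
    "DownsampleTarget",
    "PerturbationRecord",
    "Stack3D",
    "sampling_probs",
    "downsample_counts",
    "simulate_pseudospots",
    "generate_reference",
    "generate_stack3d",
    "perturb_stack",
]


@dataclass
class SpotSimConfig:
    """Pseudo-spot sampling parameters.

    Cells per spot N_c ~ Normal(mu_c, delta_c) and types per spot
    N_t ~ Normal(mu_t, delta_t); draws are rounded and clamped to
    N_c >= 1 and 1 <= N_t <= min(N_c, #types).
    """

    n_spots: int = 1000
    mu_c: float = 10.0
    delta_c: float = 5.0
    mu_t: float | None = None  # default mu_c / 2
    delta_t: float | None = None  # default delta_c / 2
    seed: int = 0

    def __post_init__(self):
        if self.mu_c <= 0:
            raise ValueError("mu_c must be positive")
        if self.mu_t is None:
            self.mu_t = self.mu_c / 2
        if self.delta_t is None:
            self.delta_t = self.delta_c / 2


@dataclass
class DownsampleTarget:
    """Mean/sd of per-spot total counts estimated from a real slice."""

    mu_L: float
    sigma_L: float

    def __post_init__(self):
        if self.mu_L <= 0 or self.sigma_L < 0:
            raise ValueError("require mu_L > 0 and sigma_L >= 0")

    @staticmethod
    def from_slice(sl: SliceData) -> "DownsampleTarget":
        totals = np.asarray(sl.counts).sum(axis=1)
        return DownsampleTarget(float(totals.mean()), float(totals.std()))


@dataclass
class PerturbationRecord:
    """Ground truth of a perturbed stack: per-slice transform and crop."""

    transforms: list
    crop_ratio: float
    retained: list = field(default_factory=list)  # per-slice retained indices


@dataclass
class Stack3D:
    """A stack of consecutive slices with known domains and compositions."""

    slices: list
    domains: DomainAssignment
    compositions: list
    z_spacing: float

    @property
    def domain_sets(self) -> list[np.ndarray]:
        return [self.domains.for_slice(sl.slice_id) for sl in self.slices]


# ---------------------------------------------------------------------------
# pseudo-spot construction
# ---------------------------------------------------------------------------

def sampling_probs(f: np.ndarray, r_c: float) -> np.ndarray:
    """Per-type sampling probability P_t for one spot.

    Identity for r_c < 1/3, normalized inverse frequency for
    1/3 <= r_c < 2/3, and normalized sqrt frequency for 2/3 <= r_c < 1.
    Types with zero frequency are excluded before inversion rather than
    dividing by zero.
    """
    f = np.asarray(f, dtype=float)
    if not (0 <= r_c < 1):
        raise ValueError("r_c must lie in [0, 1)")
    if np.any(f < 0) or not np.isclose(f.sum(), 1.0):
        raise ValueError("f must be a probability vector")
    if r_c < 1 / 3:
        return f.copy()
    if r_c < 2 / 3:
        p = np.zeros_like(f)
        nz = f > 0
        p[nz] = 1.0 / f[nz]
        return p / p.sum()
    p = np.sqrt(f)
    return p / p.sum()


def downsample_counts(counts_row: np.ndarray, target_total: int,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Thin a count vector to exactly ``target_total`` transcripts.

    Sampling is multivariate hypergeometric (draw target_total of the
    existing transcripts without replacement), which preserves expected
    gene proportions and never increases any count.
    """
    counts_row = np.asarray(counts_row)
    total = int(counts_row.sum())
    if target_total > total:
        warnings.warn("target exceeds available counts; returning row unchanged")
        return counts_row.copy()
    if target_total == total:
        return counts_row.copy()
    rng = np.random.default_rng() if rng is None else rng
    return rng.multivariate_hypergeometric(counts_row.astype(np.int64), int(target_total))


def simulate_pseudospots(
    ref: SingleCellReference,
    cfg: SpotSimConfig,
    target: DownsampleTarget | None = None,
) -> tuple[np.ndarray, CompositionMatrix]:
    """Build pseudo-spots from reference cells with known type proportions.

    Per spot: draw N_c and N_t, draw one r_c, restrict to N_t types sampled
    by P_t (renormalized over the chosen subset), sample N_c cells with
    replacement, sum their counts, record sampled-cell type fractions as the
    ground truth, then downsample the spot total towards
    Normal(mu_L, sigma_L) if a target is given.
    """
    rng = np.random.default_rng(cfg.seed)
    n_types = ref.n_types
    type_cells = {t: np.nonzero(ref.cell_types == t)[0] for t in ref.type_names}

    counts = np.zeros((cfg.n_spots, ref.counts.shape[1]), dtype=np.int64)
    truth = np.zeros((cfg.n_spots, n_types))
    for i in range(cfg.n_spots):
        n_c = max(1, int(np.rint(rng.normal(cfg.mu_c, cfg.delta_c))))
        n_t = int(np.rint(rng.normal(cfg.mu_t, cfg.delta_t)))
        n_t = int(np.clip(n_t, 1, min(n_c, n_types)))
        r_c = rng.uniform(0.0, 1.0)
        p_t = sampling_probs(ref.type_freq, r_c)
        available = np.nonzero(p_t > 0)[0]
        if n_t > len(available):
            warnings.warn("N_t exceeds available types; clamped")
            n_t = len(available)
        chosen = rng.choice(
            available, size=n_t, replace=False, p=p_t[available] / p_t[available].sum()
        )
        p_sub = p_t[chosen] / p_t[chosen].sum()
        cell_types_drawn = rng.choice(chosen, size=n_c, replace=True, p=p_sub)
        for t_idx in cell_types_drawn:
            cell = rng.choice(type_cells[ref.type_names[t_idx]])
            counts[i] += ref.counts[cell].astype(np.int64)
            truth[i, t_idx] += 1
        truth[i] /= n_c
    if target is not None:
        for i in range(cfg.n_spots):
            total = int(counts[i].sum())
            goal = int(np.clip(np.rint(rng.normal(target.mu_L, target.sigma_L)), 1, total))
            counts[i] = downsample_counts(counts[i], goal, rng)
    return counts, CompositionMatrix(proportions=truth, type_names=ref.type_names)


# ---------------------------------------------------------------------------
# synthetic references
# ---------------------------------------------------------------------------

def generate_reference(
    n_types: int = 5,
    n_genes: int = 200,
    n_cells: int = 500,
    marker_genes_per_type: int = 20,
    marker_logfc: float = 2.0,
    seed: int = 0,
) -> SingleCellReference:
    """Negative-binomial single-cell reference with disjoint marker blocks.

    Each type overexpresses its own block of ``marker_genes_per_type`` genes
    by a factor exp(marker_logfc). Counts are gamma-Poisson with moderate
    overdispersion; type frequencies are drawn once from a Dirichlet so the
    reference has an uneven but reproducible composition.
    """
    if n_types * marker_genes_per_type > n_genes:
        raise ValueError("marker blocks exceed the number of genes")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=0.8, size=n_genes)
    means = np.tile(base, (n_types, 1))
    for t in range(n_types):
        block = slice(t * marker_genes_per_type, (t + 1) * marker_genes_per_type)
        means[t, block] *= np.exp(marker_logfc)

    freq = rng.dirichlet(np.full(n_types, 5.0))
    labels_idx = rng.choice(n_types, size=n_cells, p=freq)
    # guarantee every type keeps >= 2 cells
    for t in range(n_types):
        if (labels_idx == t).sum() < 2:
            labels_idx[rng.choice(n_cells, size=2, replace=False)] = t

    dispersion = 2.0  # gamma shape; smaller = more overdispersed
    gamma_noise = rng.gamma(dispersion, 1.0 / dispersion, size=(n_cells, n_genes))
    counts = rng.poisson(means[labels_idx] * gamma_noise * 5.0)
    gene_names = np.array([f"gene{i}" for i in range(n_genes)], dtype=object)
    type_names = np.array([f"type{t}" for t in range(n_types)], dtype=object)
    return SingleCellReference(
        counts=counts, gene_names=gene_names, cell_types=type_names[labels_idx]
    )


# ---------------------------------------------------------------------------
# 3D stacks
# ---------------------------------------------------------------------------

def _layered_domain(y: np.ndarray, z: float, extent_y: float, n_domains: int) -> np.ndarray:
    """Parallel bands along y whose boundaries drift linearly with z."""
    drift = 0.05 * z  # um of boundary shift per slice depth
    frac = np.clip((y + drift) / extent_y, 0.0, 1.0 - 1e-9)
    return np.floor(frac * n_domains).astype(int)


def generate_stack3d(
    n_slices: int = 10,
    thickness_um: float = 100.0,
    domain_layout: str = "layered",
    spots_per_slice: int = 400,
    n_domains: int = 3,
    n_types: int | None = None,
    n_genes: int = 60,
    batch_shift: float = 0.0,
    extent_um: tuple[float, float] = (1400.0, 1700.0),
    seed: int = 0,
) -> Stack3D:
    """Synthetic 3D tissue: jittered-grid slices with contiguous banded domains.

    Spots carry a cell-type composition drawn around their domain's
    signature (Dirichlet noise), counts generated from type-specific gene
    programs, and optionally a per-slice multiplicative batch shift applied
    to compositions before renormalization.
    """
    if domain_layout != "layered":
        raise ValueError("only the 'layered' domain layout is implemented")
    if n_domains < 2:
        raise ValueError("need at least 2 domains")
    rng = np.random.default_rng(seed)
    n_types = n_domains + 2 if n_types is None else n_types
    z_spacing = thickness_um / n_slices
    ex, ey = extent_um

    # one signature per domain: dominant own type plus shared background
    signatures = np.full((n_domains, n_types), 1.0)
    for d in range(n_domains):
        signatures[d, d % n_types] = 8.0
        signatures[d, (d + 1) % n_types] = 3.0
    signatures /= signatures.sum(axis=1, keepdims=True)

    # type-specific gene programs with disjoint marker blocks
    block = n_genes // n_types
    profiles = np.full((n_types, n_genes), 1.0)
    for t in range(n_types):
        profiles[t, t * block:(t + 1) * block] = 6.0
    profiles /= profiles.sum(axis=1, keepdims=True)

    nx = int(np.ceil(np.sqrt(spots_per_slice * ex / ey)))
    ny = int(np.ceil(spots_per_slice / nx))
    gx, gy = ex / nx, ey / ny

    slices, comps, labels, slice_of_spot = [], [], [], []
    gene_names = np.array([f"gene{i}" for i in range(n_genes)], dtype=object)
    type_names = np.array([f"type{t}" for t in range(n_types)], dtype=object)
    for s in range(n_slices):
        z = s * z_spacing
        xs, ys = np.meshgrid(
            (np.arange(nx) + 0.5) * gx, (np.arange(ny) + 0.5) * gy, indexing="ij"
        )
        coords = np.column_stack([xs.ravel(), ys.ravel()])[:spots_per_slice]
        coords = coords + rng.uniform(-0.3, 0.3, size=coords.shape) * np.array([gx, gy])
        dom = _layered_domain(coords[:, 1], z, ey, n_domains)

        comp = rng.dirichlet(np.ones(n_types), size=len(coords))
        comp = 0.15 * comp + 0.85 * signatures[dom]
        if batch_shift > 0:
            shift = np.exp(rng.normal(0.0, batch_shift, size=n_types))
            comp = comp * shift
        comp /= comp.sum(axis=1, keepdims=True)

        lib = rng.normal(1000.0, 100.0, size=len(coords)).clip(200)
        counts = rng.poisson(comp @ profiles * lib[:, None])
        slices.append(
            SliceData(
                counts=counts, gene_names=gene_names, coords=coords,
                slice_id=f"slice{s}", z=z,
            )
        )
        comps.append(CompositionMatrix(proportions=comp, type_names=type_names))
        labels.append(dom)
        slice_of_spot.extend([f"slice{s}"] * len(coords))

    domains = DomainAssignment(
        labels=np.concatenate(labels), slice_of_spot=np.array(slice_of_spot, dtype=object)
    )
    return Stack3D(slices=slices, domains=domains, compositions=comps, z_spacing=z_spacing)


def perturb_stack(
    stack: Stack3D, crop_ratio: float, seed: int = 0
) -> tuple[Stack3D, PerturbationRecord]:
    """Rigidly perturb every slice after the first and crop all slice edges.

    Each slice except the first is randomly mirrored, rotated uniformly on
    0-360 degrees and translated 300-2000 um (random sign) per axis. Every
    slice loses a ``crop_ratio`` fraction of its spots from one randomly
    oriented edge (the spots most extreme along a random direction). True
    transforms and retained indices are recorded.
    """
    if not 0 <= crop_ratio <= 0.25:
        raise ValueError("crop_ratio must lie in [0, 0.25]")
    rng = np.random.default_rng(seed)
    transforms, retained = [], []
    new_slices, new_comps, labels, slice_of_spot = [], [], [], []
    for j, sl in enumerate(stack.slices):
        n = sl.n_spots
        if j == 0:
            t = RigidTransform2D()
        else:
            flip = int(rng.choice([-1, 1]))
            theta = rng.uniform(0.0, 2 * np.pi)
            shift = rng.uniform(300.0, 2000.0, size=2) * rng.choice([-1.0, 1.0], size=2)
            t = RigidTransform2D(theta=theta, flip=flip, dx=shift[0], dy=shift[1])
        n_drop = int(np.rint(crop_ratio * n))
        if n_drop > 0:
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            proj = sl.coords @ direction
            keep = np.argsort(proj)[: n - n_drop]
            keep = np.sort(keep)
        else:
            keep = np.arange(n)
        coords = t.apply(sl.coords[keep])
        dom = stack.domains.for_slice(sl.slice_id)[keep]
        new_slices.append(
            SliceData(
                counts=sl.counts[keep], gene_names=sl.gene_names, coords=coords,
                slice_id=sl.slice_id, z=sl.z,
                spot_ids=sl.spot_ids[keep],
            )
        )
        new_comps.append(
            CompositionMatrix(
                proportions=stack.compositions[j].proportions[keep],
                type_names=stack.compositions[j].type_names,
            )
        )
        labels.append(dom)
        slice_of_spot.extend([sl.slice_id] * len(keep))
        transforms.append(t)
        retained.append(keep)
    domains = DomainAssignment(
        labels=np.concatenate(labels), slice_of_spot=np.array(slice_of_spot, dtype=object)
    )
    perturbed = Stack3D(
        slices=new_slices, domains=domains, compositions=new_comps,
        z_spacing=stack.z_spacing,
    )
    return perturbed, PerturbationRecord(
        transforms=transforms, crop_ratio=crop_ratio, retained=retained
    )
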