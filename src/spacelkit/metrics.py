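"""Evaluation statistics for deconvolution, domain identification and alignment.

Deconvolution is scored per cell type with PCC, SSIM (on min-max-scaled
columns, C1 = 0.01, C2 = 0.03), RMSE and Jensen-Shannon divergence, and
methods are ranked into an accuracy score (AS) normalized so the best
method scores 1. Domain predictions are scored with per-domain Jaccard
index against the best-matching reference layer, a shifting distance (mean
distance of a domain's spots to the nearest spot of that layer) and ARI.
Batch mixing uses the cluster-stratified average silhouette width on batch
labels. Alignments are compared through gridded cell-type composition
fields (SSIM/PCC) after an affine registration to ground truth.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from .core_data import CompositionMatrix

logger = logging.getLogger("spacelkit")

__all__ = [
    "deconv_metrics",
    "accuracy_score",
    "jsd",
    "domain_metrics",
    "asw",
    "percentage_overlap",
    "find_svgs",
    "grid_similarity",
    "register_to_truth",
]

_EPS = 1e-12


def _kl(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float) + _EPS
    b = np.asarray(b, float) + _EPS
    return float(np.sum(a * np.log(a / b)))


def jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence (natural log, bounded by ln 2)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    m = (p + q) / 2
    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


def _ssim_column(pred: np.ndarray, truth: np.ndarray,
                 c1: float = 0.01, c2: float = 0.03) -> float:
    """Global SSIM between two vectors, each min-max scaled to [0, 1]."""

    def scale(v):
        rng = v.max() - v.min()
        return (v - v.min()) / rng if rng > 0 else np.zeros_like(v)

    x, y = scale(np.asarray(truth, float)), scale(np.asarray(pred, float))
    ux, uy = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    cov = ((x - ux) * (y - uy)).mean()
    return float(
        (2 * ux * uy + c1**2) * (2 * cov + c2**2)
        / ((ux**2 + uy**2 + c1**2) * (sx**2 + sy**2 + c2**2))
    )


def deconv_metrics(pred: CompositionMatrix, truth: CompositionMatrix) -> dict:
    """Per-cell-type PCC, SSIM, RMSE and JSD between predicted and true
    proportions. A zero-variance truth column yields PCC = nan (reported as
    missing)."""
    p, t = np.asarray(pred.proportions, float), np.asarray(truth.proportions, float)
    if p.shape != t.shape:
        raise ValueError("prediction and truth shapes differ")
    n_types = p.shape[1]
    out = {"PCC": [], "SSIM": [], "RMSE": [], "JSD": []}
    for i in range(n_types):
        x, y = t[:, i], p[:, i]
        if x.std() == 0 or y.std() == 0:
            out["PCC"].append(np.nan)
        else:
            out["PCC"].append(float(np.corrcoef(x, y)[0, 1]))
        out["SSIM"].append(_ssim_column(y, x))
        out["RMSE"].append(float(np.sqrt(np.mean((y - x) ** 2))))
        # spatial distribution of the type: column normalized over spots
        px = x / x.sum() if x.sum() > 0 else np.full_like(x, 1 / len(x))
        py = y / y.sum() if y.sum() > 0 else np.full_like(y, 1 / len(y))
        out["JSD"].append(jsd(py, px))
    return {k: np.array(v) for k, v in out.items()}


def accuracy_score(per_method_metrics: dict[str, dict]) -> dict[str, float]:
    """Rank-based accuracy score across methods.

    PCC/SSIM are ranked ascending and RMSE/JSD descending so higher rank is
    better everywhere; AS is the mean of the four ranks divided by the
    number of methods (the dominating method scores 1). Ties get average
    ranks.
    """
    methods = list(per_method_metrics)
    if len(methods) < 2:
        raise ValueError("need at least two methods to rank")
    summary = {
        m: {k: float(np.nanmean(v[k])) for k in ("PCC", "SSIM", "RMSE", "JSD")}
        for m, v in per_method_metrics.items()
    }
    n = len(methods)
    ranks = np.zeros(n)
    for key, higher_better in (("PCC", True), ("SSIM", True), ("RMSE", False), ("JSD", False)):
        vals = np.array([summary[m][key] for m in methods])
        r = rankdata(vals if higher_better else -vals)
        ranks += r
    return {m: float(ranks[i] / 4 / n) for i, m in enumerate(methods)}


def domain_metrics(
    pred_labels: np.ndarray,
    truth_labels: np.ndarray,
    coords: np.ndarray,
) -> dict:
    """Per-domain Jaccard index with best-matching layer, shifting distance
    and overall ARI.

    JI(d, l) = |P_d intersect P_l| / |P_d union P_l|; the layer maximizing
    JI is the domain's corresponding layer; SD is the mean distance of the
    domain's spots to the nearest spot of that layer.
    """
    pred_labels = np.asarray(pred_labels)
    truth_labels = np.asarray(truth_labels)
    coords = np.asarray(coords, float)
    domains = np.unique(pred_labels)
    layers = np.unique(truth_labels)
    ji, sd, matched = {}, {}, {}
    for d in domains:
        pd = pred_labels == d
        if pd.sum() == 0:
            logger.warning("empty domain %s skipped", d)
            continue
        best_l, best_ji = None, -1.0
        for l in layers:
            pl = truth_labels == l
            inter = np.logical_and(pd, pl).sum()
            union = np.logical_or(pd, pl).sum()
            val = inter / union if union else 0.0
            if val > best_ji:
                best_ji, best_l = val, l
        ji[d], matched[d] = best_ji, best_l
        layer_coords = coords[truth_labels == best_l]
        tree = cKDTree(layer_coords)
        dists, _ = tree.query(coords[pd], k=1)
        sd[d] = float(np.mean(dists))
    return {
        "JI": ji,
        "SD": sd,
        "layer_of_domain": matched,
        "ARI": float(adjusted_rand_score(truth_labels, pred_labels)),
    }


def asw(features: np.ndarray, batch_labels: np.ndarray,
        cluster_labels: np.ndarray) -> float:
    """Batch-mixing average silhouette width.

    Within each cluster, the silhouette of every spot is computed over
    batch labels; the score averages 1 - |silhouette| per cluster and then
    over clusters, so perfectly interleaved batches approach 1. Clusters
    drawn from a single batch are skipped (logged).
    """
    features = np.asarray(features, float)
    batch_labels = np.asarray(batch_labels)
    cluster_labels = np.asarray(cluster_labels)
    if len(np.unique(batch_labels)) < 2:
        raise ValueError("need at least two batches")
    scores = []
    for k in np.unique(cluster_labels):
        mask = cluster_labels == k
        batches_here = np.unique(batch_labels[mask])
        if len(batches_here) < 2 or mask.sum() <= len(batches_here):
            logger.info("cluster %s has a single batch or too few spots; skipped", k)
            continue
        sil = silhouette_samples(features[mask], batch_labels[mask])
        scores.append(float(np.mean(1 - np.abs(sil))))
    if not scores:
        raise ValueError("no cluster had two or more batches")
    return float(np.mean(scores))


def percentage_overlap(annotated_spots: set, domain_spots: set) -> float:
    """|annotated intersect domain| / |domain|."""
    domain_spots = set(domain_spots)
    if not domain_spots:
        raise ValueError("empty domain")
    return len(set(annotated_spots) & domain_spots) / len(domain_spots)


def find_svgs(
    expression: np.ndarray,
    gene_names: np.ndarray,
    domain_labels: np.ndarray,
    lfc_cut: float = 0.5,
    p_cut: float = 0.01,
) -> dict:
    """Per-domain differential genes by two-sided rank-sum test.

    ``expression`` is log-normalized (spots x genes). For each domain the
    one-vs-rest Wilcoxon rank-sum p-value and the natural-log fold change of
    mean (de-logged) expression are computed; genes passing both cut-offs
    form the domain's list. Returns gene lists plus the per-gene minimum
    p-value ranking used for ROC construction.
    """
    expression = np.asarray(expression, float)
    gene_names = np.asarray(gene_names, dtype=object)
    domain_labels = np.asarray(domain_labels)
    lists, pmin = {}, np.full(expression.shape[1], 1.0)
    for d in np.unique(domain_labels):
        mask = domain_labels == d
        if mask.sum() < 3:
            logger.warning("domain %s has <3 spots; skipped", d)
            continue
        x_in, x_out = expression[mask], expression[~mask]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = mannwhitneyu(x_in, x_out, alternative="two-sided", axis=0)
        mean_in = np.expm1(x_in).mean(axis=0)
        mean_out = np.expm1(x_out).mean(axis=0)
        lfc = np.log((mean_in + 1e-9) / (mean_out + 1e-9))
        hits = (lfc > lfc_cut) & (pvals < p_cut)
        lists[d] = list(gene_names[hits])
        pmin = np.minimum(pmin, pvals)
    order = np.argsort(pmin)
    return {"lists": lists, "pvalues": pmin, "ranking": list(gene_names[order])}


def _grid_fields(
    a_coords, a_comp, b_coords, b_comp, grid: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean composition per grid cell over the common bounding box."""
    lo = np.maximum(a_coords.min(axis=0), b_coords.min(axis=0))
    hi = np.minimum(a_coords.max(axis=0), b_coords.max(axis=0))
    if np.any(hi <= lo):
        raise ValueError("slices share no common area")

    def field(coords, comp):
        rel = (coords - lo) / (hi - lo)
        inside = np.all((rel >= 0) & (rel <= 1), axis=1)
        cell = np.clip((rel[inside] * grid).astype(int), 0, grid - 1)
        flat = cell[:, 0] * grid + cell[:, 1]
        n_types = comp.shape[1]
        sums = np.zeros((grid * grid, n_types))
        counts = np.zeros(grid * grid)
        np.add.at(sums, flat, comp[inside])
        np.add.at(counts, flat, 1)
        with np.errstate(invalid="ignore"):
            means = sums / counts[:, None]
        return means, counts > 0

    fa, occ_a = field(a_coords, np.asarray(a_comp, float))
    fb, occ_b = field(b_coords, np.asarray(b_comp, float))
    both = occ_a & occ_b
    if not both.any():
        raise ValueError("no grid cell occupied in both slices")
    return fa[both], fb[both]


def grid_similarity(
    slice_a: tuple[np.ndarray, np.ndarray],
    slice_b: tuple[np.ndarray, np.ndarray],
    grid: int = 10,
) -> tuple[float, float]:
    """(SSIM, PCC) between gridded composition fields of two slices."""
    fa, fb = _grid_fields(slice_a[0], slice_a[1], slice_b[0], slice_b[1], grid)
    x, y = fa.ravel(), fb.ravel()
    if np.allclose(x, y):
        return 1.0, 1.0
    pcc = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 and y.std() > 0 else np.nan
    return _ssim_column(y, x), pcc


def register_to_truth(aligned: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Least-squares affine map sending aligned coordinates onto truth.

    Returns the 2x3 matrix M such that truth ~= [aligned, 1] @ M.T; raises
    on rank-deficient (e.g. collinear) input.
    """
    aligned = np.asarray(aligned, float)
    truth = np.asarray(truth, float)
    if len(aligned) < 3:
        raise ValueError("need at least 3 shared spots")
    X = np.column_stack([aligned, np.ones(len(aligned))])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("rank-deficient registration system")
    M, *_ = np.linalg.lstsq(X, truth, rcond=None)
    return M.T


def apply_affine(coords: np.ndarray, M: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, float)
    return np.column_stack([coords, np.ones(len(coords))]) @ np.asarray(M, float).T


def alignment_recovery(
    aligned_coords: list[np.ndarray],
    truth_coords: list[np.ndarray],
    compositions: list[np.ndarray],
    grid: int = 10,
) -> tuple[float, float]:
    """Mean gridded SSIM/PCC of an aligned stack against its ground truth.

    For each adjacent pair, the affine map from aligned slice i to truth
    slice i (estimated from their shared spots) is applied to aligned slice
    i+1, which is then grid-compared with truth slice i+1 on cell-type
    compositions.
    """
    ssims, pccs = [], []
    for i in range(len(aligned_coords) - 1):
        M = register_to_truth(aligned_coords[i], truth_coords[i])
        moved = apply_affine(aligned_coords[i + 1], M)
        s, p = grid_similarity(
            (moved, compositions[i + 1]),
            (truth_coords[i + 1], compositions[i + 1]),
            grid=grid,
        )
        ssims.append(s)
        pccs.append(p)
    return float(np.mean(ssims)), float(np.mean(pccs))
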