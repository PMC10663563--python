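"""Continuous 3D expression model and spatial-variability scoring.

A Gaussian process with constant mean and squared-exponential covariance
delta^2 exp(-|x - x'|^2 / (2 l^2)) plus additive Gaussian noise is fitted to
per-spot expression over aligned 3D coordinates; hyperparameters are
initialized as mu = mean(y), delta = 4, l = lambda * var(y) with lambda
chosen from a grid by marginal likelihood, then refined with Adam on the
analytic log-marginal-likelihood gradients. Spatial variability of a gene
is the Bayes factor of this model against its length-scale -> infinity
reduction (a shared random offset plus noise). Surfaces for prediction come
from an alpha-shape mesh of the point cloud with Loop subdivision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial import Delaunay, QhullError

from .nn import Adam

logger = logging.getLogger("spacelkit")

__all__ = [
    "GPRFit",
    "MeshManifold",
    "BayesFactorResult",
    "log_marginal_likelihood",
    "make_gpr",
    "fit_gpr",
    "predict_gpr",
    "bayes_factor",
    "build_mesh",
    "sample_mesh_points",
]

_JITTERS = (0.0, 1e-8, 1e-6, 1e-4)


class _Param:
    """Scalar parameter exposing .data/.grad for the Adam optimizer."""

    def __init__(self, value: float):
        self.data = np.array(float(value))
        self.grad = None


@dataclass
class GPRFit:
    coords: np.ndarray            # training coordinates, rescaled
    y: np.ndarray
    mu: float
    delta: float                  # process standard deviation
    length_scale: float           # in rescaled coordinate units (inf for null model)
    noise: float                  # noise standard deviation
    log_marginal: float
    center: np.ndarray
    scale: float
    _alpha: np.ndarray = field(repr=False, default=None)
    _cho: tuple = field(repr=False, default=None)


@dataclass
class MeshManifold:
    vertices: np.ndarray
    faces: np.ndarray
    watertight: bool
    sampling_budget: int = 500_000

    @property
    def mesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)


@dataclass
class BayesFactorResult:
    bf: float
    log_bf: float
    log_marginal_spatial: float
    log_marginal_null: float


# ---------------------------------------------------------------------------
# marginal likelihood and gradients
# ---------------------------------------------------------------------------

def _kernel(sq_dists: np.ndarray, delta: float, length_scale: float) -> np.ndarray:
    if np.isinf(length_scale):
        return np.full_like(sq_dists, delta**2)
    return delta**2 * np.exp(-sq_dists / (2.0 * length_scale**2))


def _lml_and_grads(sq_dists, y, mu, log_delta, log_l, log_noise):
    """Log marginal likelihood and its gradients in (mu, log d, log l, log s)."""
    n = len(y)
    delta, noise = np.exp(log_delta), np.exp(log_noise)
    length_scale = np.inf if np.isinf(log_l) else np.exp(log_l)
    K_f = _kernel(sq_dists, delta, length_scale)
    K = K_f + noise**2 * np.eye(n)
    cho = None
    for jitter in _JITTERS:
        try:
            cho = cho_factor(K + jitter * np.eye(n), lower=True)
            break
        except np.linalg.LinAlgError:
            continue
    if cho is None:
        raise np.linalg.LinAlgError("kernel matrix not positive definite")
    r = y - mu
    alpha = cho_solve(cho, r)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    lml = -0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)

    K_inv = cho_solve(cho, np.eye(n))
    W = np.outer(alpha, alpha) - K_inv          # d lml / dK = W / 2
    g_mu = float(alpha.sum())
    g_log_delta = 0.5 * float(np.sum(W * (2.0 * K_f)))
    if np.isinf(length_scale):
        g_log_l = 0.0
    else:
        g_log_l = 0.5 * float(np.sum(W * (K_f * sq_dists / length_scale**2)))
    g_log_noise = 0.5 * float(np.trace(W) * 2.0 * noise**2)
    return float(lml), (g_mu, g_log_delta, g_log_l, g_log_noise), cho, alpha


def log_marginal_likelihood(
    coords: np.ndarray, y: np.ndarray, mu: float, delta: float,
    length_scale: float, noise: float,
) -> float:
    """Exact Gaussian log marginal likelihood of the GP at given parameters."""
    coords = np.atleast_2d(np.asarray(coords, float))
    sq = _sq_dists(coords)
    log_l = np.inf if np.isinf(length_scale) else np.log(length_scale)
    lml, _, _, _ = _lml_and_grads(sq, np.asarray(y, float), mu,
                                  np.log(delta), log_l, np.log(noise))
    return lml


def _sq_dists(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _rescale(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center and isotropically scale coordinates to unit RMS radius.

    Isotropic scaling keeps likelihood ratios invariant to rigid transforms
    of the input coordinates.
    """
    coords = np.asarray(coords, float)
    center = coords.mean(axis=0)
    centered = coords - center
    scale = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    scale = scale if scale > 0 else 1.0
    return centered / scale, center, scale


def _optimize(sq_dists, y, mu0, delta0, l0, noise0, n_iter, lr, spatial: bool):
    params = [_Param(mu0), _Param(np.log(delta0))]
    if spatial:
        params.append(_Param(np.log(l0)))
    params.append(_Param(np.log(max(noise0, 1e-6))))
    # keep the noise bounded away from zero: the marginal likelihood is
    # unbounded as the noise collapses on (near-)interpolable data
    log_noise_floor = np.log(max(1e-4 * (float(np.std(y)) + 1e-12), 1e-8))
    opt = Adam(params, lr=lr)
    lml = -np.inf
    for _ in range(n_iter):
        log_l = params[2].data if spatial else np.inf
        log_noise = params[-1].data
        lml, grads, _, _ = _lml_and_grads(
            sq_dists, y, float(params[0].data), float(params[1].data),
            float(log_l), float(log_noise),
        )
        g = [grads[0], grads[1]] + ([grads[2]] if spatial else []) + [grads[3]]
        opt.zero_grad()
        for p, gi in zip(params, g):
            p.grad = -np.array(gi)  # ascend the likelihood
        opt.step()
        params[-1].data = np.maximum(params[-1].data, log_noise_floor)
    log_l = float(params[2].data) if spatial else np.inf
    mu = float(params[0].data)
    delta = float(np.exp(params[1].data))
    noise = float(np.exp(params[-1].data))
    length_scale = np.exp(log_l) if spatial else np.inf
    lml, _, cho, alpha = _lml_and_grads(
        sq_dists, y, mu, np.log(delta),
        log_l if spatial else np.inf, np.log(noise),
    )
    return mu, delta, length_scale, noise, lml, cho, alpha


def fit_gpr(
    coords3d: np.ndarray,
    y: np.ndarray,
    lambda_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 10.0),
    n_iter: int = 200,
    lr: float = 0.05,
) -> GPRFit:
    """Fit the spatial GP to one gene's expression values.

    Coordinates are centered and isotropically rescaled internally; the
    length scale is initialized as lambda * var(y) with lambda chosen from
    ``lambda_grid`` by marginal likelihood, then all hyperparameters are
    refined by gradient ascent.
    """
    coords3d = np.atleast_2d(np.asarray(coords3d, float))
    y = np.asarray(y, float)
    if len(coords3d) != len(y):
        raise ValueError("coords and values must be aligned")
    if len(y) < 3:
        raise ValueError("need at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("expression values must be finite")

    scaled, center, scale = _rescale(coords3d)
    sq = _sq_dists(scaled)
    mu0 = float(y.mean())
    delta0 = 4.0
    var_y = max(float(y.var()), 1e-8)
    noise0 = np.sqrt(0.1 * var_y)

    best_lambda, best_lml = lambda_grid[0], -np.inf
    for lam in lambda_grid:
        l0 = max(lam * var_y, 1e-6)
        lml, _, _, _ = _lml_and_grads(sq, y, mu0, np.log(delta0),
                                      np.log(l0), np.log(max(noise0, 1e-6)))
        if lml > best_lml:
            best_lml, best_lambda = lml, lam
    l0 = max(best_lambda * var_y, 1e-6)

    mu, delta, length_scale, noise, lml, cho, alpha = _optimize(
        sq, y, mu0, delta0, l0, noise0, n_iter, lr, spatial=True
    )
    return GPRFit(
        coords=scaled, y=y, mu=mu, delta=delta, length_scale=length_scale,
        noise=noise, log_marginal=lml, center=center, scale=scale,
        _alpha=alpha, _cho=cho,
    )


def make_gpr(coords3d: np.ndarray, y: np.ndarray, mu: float, delta: float,
             length_scale: float, noise: float) -> GPRFit:
    """GP at fixed hyperparameters, without optimization.

    ``length_scale`` is in the original coordinate units; useful for exact
    posterior checks and as a building block for scripted analyses.
    """
    coords3d = np.atleast_2d(np.asarray(coords3d, float))
    y = np.asarray(y, float)
    scaled, center, scale = _rescale(coords3d)
    ls = length_scale / scale if np.isfinite(length_scale) else np.inf
    sq = _sq_dists(scaled)
    lml, _, cho, alpha = _lml_and_grads(
        sq, y, mu, np.log(delta),
        np.log(ls) if np.isfinite(ls) else np.inf, np.log(noise),
    )
    return GPRFit(coords=scaled, y=y, mu=mu, delta=delta, length_scale=ls,
                  noise=noise, log_marginal=lml, center=center, scale=scale,
                  _alpha=alpha, _cho=cho)


def predict_gpr(fit: GPRFit, points: np.ndarray) -> np.ndarray:
    """Posterior mean at query points (original coordinate units)."""
    points = np.atleast_2d(np.asarray(points, float))
    q = (points - fit.center) / fit.scale
    diff = q[:, None, :] - fit.coords[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    k_star = _kernel(sq, fit.delta, fit.length_scale)
    return fit.mu + k_star @ fit._alpha


def bayes_factor(fit: GPRFit, n_iter: int = 200, lr: float = 0.05) -> BayesFactorResult:
    """Likelihood ratio of the spatial GP against its l -> infinity reduction.

    The null covariance delta^2 * ones + noise^2 * I (a shared random offset
    plus noise) is refit from the same initialization; BF > 1 indicates
    spatial variation. Computed in log space to avoid underflow.
    """
    y = fit.y
    if float(y.var()) < 1e-12:
        # constant expression: spatial and null models coincide exactly
        return BayesFactorResult(
            bf=1.0, log_bf=0.0,
            log_marginal_spatial=fit.log_marginal,
            log_marginal_null=fit.log_marginal,
        )
    sq = _sq_dists(fit.coords)
    var_y = max(float(y.var()), 1e-8)
    mu, delta, _, noise, lml_null, _, _ = _optimize(
        sq, y, float(y.mean()), 4.0, np.inf, np.sqrt(0.1 * var_y),
        n_iter, lr, spatial=False,
    )
    log_bf = fit.log_marginal - lml_null
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf))
    return BayesFactorResult(
        bf=bf, log_bf=float(log_bf),
        log_marginal_spatial=fit.log_marginal, log_marginal_null=lml_null,
    )


# ---------------------------------------------------------------------------
# alpha-shape mesh
# ---------------------------------------------------------------------------

def _circumradii(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Circumradius of each tetrahedron (inf for degenerate ones)."""
    p0 = points[tets[:, 0]]
    rel = points[tets[:, 1:]] - p0[:, None, :]          # (m, 3, 3)
    rhs = 0.5 * np.einsum("ijk,ijk->ij", rel, rel)      # (m, 3)
    radii = np.full(len(tets), np.inf)
    for i in range(len(tets)):
        try:
            c = np.linalg.solve(rel[i], rhs[i])
        except np.linalg.LinAlgError:
            continue
        radii[i] = np.linalg.norm(c)
    return radii


def build_mesh(coords3d: np.ndarray, alpha: float, subdivisions: int = 0) -> MeshManifold:
    """Alpha-shape surface of a 3D point cloud with optional Loop subdivision.

    Delaunay tetrahedra with circumradius below ``alpha`` are kept; the
    boundary triangles (faces used by exactly one kept tetrahedron) form the
    surface. In the large-alpha limit this is the convex hull.
    """
    coords3d = np.asarray(coords3d, float)
    if len(coords3d) < 4:
        raise ValueError("need at least 4 points")
    try:
        tri = Delaunay(coords3d)
    except QhullError as err:
        raise ValueError(
            "degenerate (coplanar) point cloud; consider a 2.5D fallback"
        ) from err
    tets = tri.simplices
    keep = tets[_circumradii(coords3d, tets) < alpha]
    if len(keep) == 0:
        raise ValueError("alpha too small: no tetrahedron retained")
    faces = np.vstack([keep[:, [0, 1, 2]], keep[:, [0, 1, 3]],
                       keep[:, [0, 2, 3]], keep[:, [1, 2, 3]]])
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
    boundary = faces[counts[inverse] == 1]
    mesh = trimesh.Trimesh(vertices=coords3d, faces=boundary, process=True)
    mesh.fix_normals()
    vertices, faces = mesh.vertices, mesh.faces
    for _ in range(subdivisions):
        vertices, faces = trimesh.remesh.subdivide_loop(vertices, faces)
    out = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if not out.is_watertight:
        logger.warning("alpha-shape mesh is not watertight")
    return MeshManifold(
        vertices=np.asarray(out.vertices), faces=np.asarray(out.faces),
        watertight=bool(out.is_watertight),
    )


def sample_mesh_points(manifold: MeshManifold, n: int, seed: int = 0) -> np.ndarray:
    """Area-weighted uniform sampling of points on the mesh surface."""
    rng = np.random.default_rng(seed)
    mesh = manifold.mesh
    areas = mesh.area_faces
    probs = areas / areas.sum()
    chosen = rng.choice(len(probs), size=n, p=probs)
    u, v = rng.uniform(size=n), rng.uniform(size=n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    tri_pts = mesh.vertices[mesh.faces[chosen]]
    return (
        tri_pts[:, 0]
        + u[:, None] * (tri_pts[:, 1] - tri_pts[:, 0])
        + v[:, None] * (tri_pts[:, 2] - tri_pts[:, 0])
    )
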