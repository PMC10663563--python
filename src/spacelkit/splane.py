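"""Joint spatial-domain identification across slices.

Cell-type compositions are propagated through a Chebyshev-filter graph
convolutional network built on per-slice k-NN graphs (block-diagonal across
slices). The bottleneck layer H2 is the shared latent; a reconstruction
head H4 maps back onto the composition simplex under a cosine loss, a
smoothness loss ties each spot's latent to its neighbours' mean, and an
adversarial slice discriminator removes slice-level batch structure from
the latent. K-means on H2 yields the domain labels; the Davies-Bouldin
score of that clustering doubles as a convergence criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score

from . import nn
from .core_data import CompositionMatrix, DomainAssignment
from .nn import MLP, RMSProp, Tensor, xavier_init

logger = logging.getLogger("spacelkit")

__all__ = [
    "SpatialGraph",
    "SplaneConfig",
    "SplaneModel",
    "build_graph",
    "cheb_filter",
    "train_splane",
    "assign_domains",
]


@dataclass
class SpatialGraph:
    """k-NN adjacency with derived scaled Laplacian.

    A is symmetrized (max(A, A^T)) with a zero diagonal; L = I - D^-1/2 A
    D^-1/2 and L_tilde = 2L/lambda_max - I, whose spectrum lies in [-1, 1].
    """

    A: np.ndarray
    k: int
    A_hat: np.ndarray = field(init=False)
    D_hat: np.ndarray = field(init=False)
    L_tilde: np.ndarray = field(init=False)
    lambda_max: float = field(init=False)

    def __post_init__(self):
        A = np.asarray(self.A, float)
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.A_hat = A + np.eye(len(A))
        self.D_hat = np.diag(self.A_hat.sum(axis=1))
        deg = A.sum(axis=1)
        d_inv_sqrt = np.where(deg > 0, deg**-0.5, 0.0)
        L = np.eye(len(A)) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
        self.lambda_max = _power_iteration_lambda_max(L)
        self.L_tilde = 2.0 * L / self.lambda_max - np.eye(len(A))

    @property
    def n_spots(self) -> int:
        return len(self.A)


def _power_iteration_lambda_max(L: np.ndarray, tol: float = 1e-10,
                                max_iter: int = 5000) -> float:
    """Largest eigenvalue of a PSD matrix by deterministic power iteration.

    The estimate is inflated by a tiny relative margin so that the scaled
    Laplacian's spectrum stays within [-1, 1] despite the iteration error.
    """
    v = np.ones(len(L)) / np.sqrt(len(L))
    lam = 0.0
    for _ in range(max_iter):
        w = L @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 1.0  # edgeless graph: L = I
        v_new = w / norm
        lam_new = float(v_new @ L @ v_new)
        if abs(lam_new - lam) < tol:
            lam = lam_new
            break
        v, lam = v_new, lam_new
    return lam * (1.0 + 1e-7)


def build_graph(coords: np.ndarray, k: int) -> SpatialGraph:
    """Symmetrized k-nearest-neighbour graph over spot coordinates.

    Ties in neighbour distance are broken by spot index (cKDTree order),
    making the construction deterministic for duplicate coordinates.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    _, idx = cKDTree(coords).query(coords, k=k + 1)
    A = np.zeros((n, n))
    for u in range(n):
        neighbours = [v for v in idx[u] if v != u][:k]
        A[u, neighbours] = 1.0
    A = np.maximum(A, A.T)
    return SpatialGraph(A=A, k=k)


# ---------------------------------------------------------------------------
# Chebyshev filtering
# ---------------------------------------------------------------------------

def _cheb_forward(L_tilde: np.ndarray, x: Tensor, thetas: list[Tensor]) -> Tensor:
    """sum_k T_k(L_tilde) X theta_k via the Chebyshev recurrence."""
    L = Tensor(L_tilde)
    x_prev, x_cur = x, None
    out = x @ thetas[0]
    if len(thetas) > 1:
        x_cur = L @ x
        out = out + x_cur @ thetas[1]
    for k in range(2, len(thetas)):
        x_next = 2.0 * (L @ x_cur) - x_prev
        out = out + x_next @ thetas[k]
        x_prev, x_cur = x_cur, x_next
    return out


def cheb_filter(L_tilde: np.ndarray, X: np.ndarray, thetas: list[np.ndarray]) -> np.ndarray:
    """Apply a K-order Chebyshev graph filter to node features X.

    ``thetas`` holds one coefficient block per polynomial order; the
    recurrence x_k = 2 L_tilde x_{k-1} - x_{k-2} starts from x_0 = X and
    x_1 = L_tilde X. Equivalent to spectral filtering in the Laplacian
    eigenbasis.
    """
    if len(thetas) < 1:
        raise ValueError("need at least one coefficient block")
    out = _cheb_forward(
        np.asarray(L_tilde, float), Tensor(np.asarray(X, float)),
        [Tensor(np.asarray(t, float)) for t in thetas],
    )
    return out.data


class _ChebConv:
    """Graph-convolution layer: K Chebyshev coefficient blocks plus bias."""

    def __init__(self, fan_in: int, fan_out: int, order: int,
                 rng: np.random.Generator, activation=None):
        self.thetas = [
            Tensor(xavier_init(rng, fan_in, fan_out), requires_grad=True)
            for _ in range(order)
        ]
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)
        self.activation = activation

    def __call__(self, L_tilde: np.ndarray, x: Tensor) -> Tensor:
        out = _cheb_forward(L_tilde, x, self.thetas) + self.b
        return self.activation(out) if self.activation else out

    def parameters(self):
        return [*self.thetas, self.b]


# ---------------------------------------------------------------------------
# configuration / model
# ---------------------------------------------------------------------------

@dataclass
class SplaneConfig:
    k: int = 6                  # 6 for spot-resolution arrays, 25 for single-cell
    cheb_order: int = 2
    latent_dim: int = 16
    hidden_dim: int = 64
    alpha_c: float = 1.0
    alpha_s: float = 1.0
    alpha_d: float = 0.5
    n_domains: int = 3
    lr: float = 2e-3
    conv_tol_loss: float = 1e-4
    dbs_patience: int = 10
    max_epochs: int = 300
    min_epochs: int = 40
    seed: int = 0

    def __post_init__(self):
        if self.cheb_order < 1:
            raise ValueError("cheb_order must be >= 1")
        if self.alpha_d < 0:
            raise ValueError("alpha_d must be nonnegative")
        if self.n_domains < 2:
            raise ValueError("n_domains must be >= 2")


@dataclass
class SplaneModel:
    gcn_layers: list
    discriminator: MLP
    latent: np.ndarray           # H2 at the final epoch, pooled over slices
    slice_of_spot: np.ndarray
    history: dict
    config: SplaneConfig
    L_tilde: np.ndarray
    disc_accuracy: float


def _cross_entropy_t(logp: Tensor, onehot: np.ndarray) -> Tensor:
    return -(Tensor(onehot) * logp).sum(axis=1).mean()


def train_splane(
    compositions: list[CompositionMatrix],
    graphs: list[SpatialGraph],
    cfg: SplaneConfig,
    slice_ids: list[str] | None = None,
) -> SplaneModel:
    """Adversarially train the GCN on all slices jointly.

    Per epoch the discriminator takes one cross-entropy step on the detached
    latent, then the GCN takes one RMSProp step on
    alpha_C * Loss_C + alpha_S * Loss_S - alpha_D * Loss_D. Training stops
    once the total loss settles (|delta| < conv_tol_loss) and the
    Davies-Bouldin score of the K-means clustering has stopped improving
    within the patience window.
    """
    if len(compositions) != len(graphs):
        raise ValueError("one graph per composition matrix required")
    n_slices = len(compositions)
    if slice_ids is None:
        slice_ids = [f"slice{i}" for i in range(n_slices)]
    type_names = compositions[0].type_names
    for c in compositions:
        if not np.array_equal(c.type_names, type_names):
            raise ValueError("slices must share the cell-type vocabulary")

    alpha_d = cfg.alpha_d
    if n_slices == 1 and alpha_d != 0:
        logger.info("single slice: adversarial branch disabled (alpha_D = 0)")
        alpha_d = 0.0

    rng = np.random.default_rng(cfg.seed)
    Q = np.vstack([c.proportions for c in compositions])
    L_tilde = block_diag(*[g.L_tilde for g in graphs])
    # row-normalized neighbour averaging operator for the smoothness loss
    A = block_diag(*[g.A for g in graphs])
    deg = A.sum(axis=1)
    N_op = A / np.where(deg > 0, deg, 1.0)[:, None]
    slice_of_spot = np.concatenate(
        [np.repeat(sid, c.n_spots) for sid, c in zip(slice_ids, compositions)]
    )
    slice_idx = np.concatenate(
        [np.full(c.n_spots, i) for i, c in enumerate(compositions)]
    )
    onehot = np.eye(n_slices)[slice_idx]

    n_types = Q.shape[1]
    dims = (n_types, cfg.hidden_dim, cfg.latent_dim, cfg.hidden_dim, n_types)
    acts = (nn.relu, None, nn.relu, nn.softmax_head)
    layers = [
        _ChebConv(dims[i], dims[i + 1], cfg.cheb_order, rng, activation=acts[i])
        for i in range(4)
    ]
    disc = MLP((cfg.latent_dim, 64, 64, n_slices), rng, init="xavier")
    gcn_params = [p for layer in layers for p in layer.parameters()]
    opt_gcn = RMSProp(gcn_params, lr=cfg.lr)
    opt_disc = RMSProp(disc.parameters(), lr=cfg.lr)

    def gcn_forward(q: Tensor):
        h = q
        hidden = []
        for layer in layers:
            h = layer(L_tilde, h)
            hidden.append(h)
        return hidden  # H1..H4

    q_in = Tensor(Q)
    history = {"loss_C": [], "loss_S": [], "loss_D": [], "total": [], "DBS": []}
    best_dbs, best_dbs_epoch = np.inf, -1
    prev_total = None
    disc_accuracy = float("nan")
    latent = None
    for epoch in range(cfg.max_epochs):
        hidden = gcn_forward(q_in)
        h2, h4 = hidden[1], hidden[3]

        # discriminator step on the detached latent
        if alpha_d > 0:
            logp_d = nn.log_softmax(disc(h2.detach()), axis=1)
            loss_disc = _cross_entropy_t(logp_d, onehot)
            opt_disc.zero_grad()
            loss_disc.backward()
            opt_disc.step()

        # generator step
        cos = (q_in * h4).sum(axis=1) / nn.sqrt(
            nn.sum_sq(q_in, axis=1) * nn.sum_sq(h4, axis=1) + 1e-30
        )
        loss_c = (1.0 - cos).mean()
        loss_s = nn.absolute(h2 - Tensor(N_op) @ h2).mean()
        if alpha_d > 0:
            logits = disc(h2)
            logp = nn.log_softmax(logits, axis=1)
            loss_d = _cross_entropy_t(logp, onehot)
            total = cfg.alpha_c * loss_c + cfg.alpha_s * loss_s - alpha_d * loss_d
            pred_slice = np.argmax(logits.data, axis=1)
            disc_accuracy = float(np.mean(pred_slice == slice_idx))
        else:
            loss_d = Tensor(0.0)
            total = cfg.alpha_c * loss_c + cfg.alpha_s * loss_s
        if not np.isfinite(total.data):
            raise FloatingPointError("non-finite Splane loss")
        opt_gcn.zero_grad()
        total.backward()
        opt_gcn.step()

        latent = h2.data
        km = KMeans(n_clusters=cfg.n_domains, n_init=3,
                    random_state=cfg.seed).fit(latent)
        dbs = float(davies_bouldin_score(latent, km.labels_))
        history["loss_C"].append(float(loss_c.data))
        history["loss_S"].append(float(loss_s.data))
        history["loss_D"].append(float(loss_d.data))
        history["total"].append(float(total.data))
        history["DBS"].append(dbs)
        if dbs < best_dbs - 1e-12:
            best_dbs, best_dbs_epoch = dbs, epoch
        if (
            epoch + 1 >= cfg.min_epochs
            and prev_total is not None
            and abs(prev_total - float(total.data)) < cfg.conv_tol_loss
            and epoch - best_dbs_epoch >= cfg.dbs_patience
        ):
            break
        prev_total = float(total.data)

    return SplaneModel(
        gcn_layers=layers,
        discriminator=disc,
        latent=latent,
        slice_of_spot=slice_of_spot,
        history=history,
        config=cfg,
        L_tilde=L_tilde,
        disc_accuracy=disc_accuracy,
    )


def assign_domains(model: SplaneModel, n_domains: int | None = None,
                   seed: int | None = None) -> DomainAssignment:
    """K-means clustering of the shared latent into spatial domains."""
    n_domains = model.config.n_domains if n_domains is None else n_domains
    seed = model.config.seed if seed is None else seed
    if n_domains > len(model.latent):
        raise ValueError("more domains than spots")
    if n_domains == 1:
        labels = np.zeros(len(model.latent), dtype=int)
    else:
        km = KMeans(n_clusters=n_domains, n_init=10, random_state=seed)
        labels = km.fit_predict(model.latent)
    return DomainAssignment(labels=labels, slice_of_spot=model.slice_of_spot)
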