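"""Per-spot cell-type deconvolution.

Simulated pseudo-spots (with known type proportions) and real spots are
embedded by a variational autoencoder; a predictor network E maps latents
to proportions under a cosine + KL loss against the simulated ground truth,
while a recovery head R and a maximum-mean-discrepancy term align the
simulated and real latent distributions so the predictor transfers to real
spots. Training alternates a predictor step (Loss_E on simulated spots) and
a joint R/E step (Loss_R + Loss_M over both datasets) until Loss_E settles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from . import nn
from .core_data import CompositionMatrix, SingleCellReference, SliceData, normalize_counts
from .nn import MLP, Adam, Dense, Tensor

logger = logging.getLogger("spacelkit")

__all__ = [
    "SpointConfig",
    "SpointModel",
    "mmd2",
    "proportion_loss",
    "select_marker_genes",
    "train_spoint",
    "predict_proportions",
]

_KL_EPS = 1e-8


@dataclass
class SpointConfig:
    vae_hidden: int = 128
    latent_dim: int = 64
    predictor_hidden_dims: tuple = (512, 512, 512)
    recon_hidden_dims: tuple = (512, 512, 512)
    lr: float = 1e-3
    vae_lr: float = 3e-3
    vae_pretrain_epochs: int = 500
    kl_weight: float = 1e-4
    batch_size: int = 8192  # full-batch below this many spots
    max_epochs: int = 600
    min_epochs: int = 150
    align_lr_scale: float = 0.1  # step-2 (R + MMD) rate relative to the predictor step
    conv_tol: float = 1e-3
    n_markers_per_type: int = 200
    n_sim_spots: int = 10000
    seed: int = 0

    def __post_init__(self):
        if self.conv_tol <= 0:
            raise ValueError("conv_tol must be positive")
        dims = (self.vae_hidden, self.latent_dim, *self.predictor_hidden_dims,
                *self.recon_hidden_dims)
        if any(d <= 0 for d in dims):
            raise ValueError("layer dimensions must be positive")

    @property
    def mmd_sigma(self) -> float:
        # kernel bandwidth = dimension of the predictor's last hidden layer
        return float(self.predictor_hidden_dims[-1])


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _pairwise_sq_dists(u: Tensor, v: Tensor) -> Tensor:
    uu = nn.sum_sq(u, axis=1, keepdims=True)
    vv = nn.sum_sq(v, axis=1, keepdims=True)
    return uu + vv.T - 2.0 * (u @ v.T)


def _mmd2_t(u: Tensor, v: Tensor, sigma: float) -> Tensor:
    k_uu = nn.exp(-_pairwise_sq_dists(u, u) / sigma).mean()
    k_vv = nn.exp(-_pairwise_sq_dists(v, v) / sigma).mean()
    k_uv = nn.exp(-_pairwise_sq_dists(u, v) / sigma).mean()
    return k_uu - 2.0 * k_uv + k_vv


def mmd2(U: np.ndarray, V: np.ndarray, sigma: float) -> float:
    """Squared maximum mean discrepancy with kernel exp(-|u-v|^2 / sigma).

    (1/n^2) sum k(u,u') - (2/nm) sum k(u,v) + (1/m^2) sum k(v,v');
    symmetric, nonnegative up to round-off, zero for identical samples.
    """
    U, V = np.atleast_2d(np.asarray(U, float)), np.atleast_2d(np.asarray(V, float))
    if U.size == 0 or V.size == 0:
        raise ValueError("empty sample set")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(_mmd2_t(Tensor(U), Tensor(V), float(sigma)).data)


def _rowwise_cosine(a: Tensor, b: Tensor) -> Tensor:
    num = (a * b).sum(axis=1)
    den = nn.sqrt(nn.sum_sq(a, axis=1) * nn.sum_sq(b, axis=1) + 1e-30)
    return num / den


def _proportion_loss_t(pred: Tensor, truth: Tensor) -> Tensor:
    cos = _rowwise_cosine(pred, truth)
    p = nn.clip_min(truth, _KL_EPS)
    q = nn.clip_min(pred, _KL_EPS)
    kl = (p * (nn.log(p) - nn.log(q))).sum(axis=1)
    return ((1.0 - cos) + kl).mean()


def proportion_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean over rows of (1 - cosine similarity) + KL(truth || pred).

    Both inputs are simplex rows; KL uses a 1e-8 floor on both arguments and
    the natural log. Zero iff pred equals truth row-wise.
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    return float(_proportion_loss_t(Tensor(pred), Tensor(truth)).data)


def _latent_recovery_loss_t(recovered: Tensor, z: Tensor) -> Tensor:
    # cosine pulls directions together; MSE constrains magnitude (latents
    # are unconstrained reals, so a divergence term is not applicable)
    cos = _rowwise_cosine(recovered, z)
    mse = ((recovered - z) ** 2).mean()
    return (1.0 - cos).mean() + mse


# ---------------------------------------------------------------------------
# marker selection
# ---------------------------------------------------------------------------

def select_marker_genes(ref: SingleCellReference, n_per_type: int = 200) -> np.ndarray:
    """Top overexpressed genes per type by a vectorized rank-sum z-score.

    Expression is library-size log-normalized, genes are ranked per column,
    and for each type the one-vs-rest Wilcoxon z statistic picks the
    ``n_per_type`` most type-specific genes; the union is returned in the
    reference gene order.
    """
    x = normalize_counts(ref.counts)
    n_cells, n_genes = x.shape
    ranks = np.apply_along_axis(rankdata, 0, x)
    chosen: set[int] = set()
    for t in ref.type_names:
        mask = ref.cell_types == t
        n1 = int(mask.sum())
        n2 = n_cells - n1
        r1 = ranks[mask].sum(axis=0)
        mu = n1 * (n_cells + 1) / 2.0
        sd = np.sqrt(n1 * n2 * (n_cells + 1) / 12.0)
        z = (r1 - mu) / sd
        top = np.argsort(z)[::-1][: min(n_per_type, n_genes)]
        chosen.update(top.tolist())
    idx = np.sort(np.fromiter(chosen, dtype=int))
    return ref.gene_names[idx]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _VAE:
    """Gaussian-latent autoencoder on log-normalized expression."""

    def __init__(self, n_genes: int, hidden: int, latent: int, rng: np.random.Generator):
        self.enc_h = Dense(n_genes, hidden, rng, activation=nn.relu)
        self.enc_mu = Dense(hidden, latent, rng, activation=None)
        self.enc_logvar = Dense(hidden, latent, rng, activation=None)
        self.dec = MLP((latent, hidden, n_genes), rng)

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = self.enc_h(x)
        return self.enc_mu(h), self.enc_logvar(h)

    def elbo_loss(self, x: Tensor, rng: np.random.Generator, kl_weight: float) -> Tensor:
        mu, logvar = self.encode(x)
        eps = Tensor(rng.standard_normal(mu.shape))
        z = mu + nn.exp(0.5 * logvar) * eps
        recon = self.dec(z)
        mse = ((recon - x) ** 2).mean()
        kl = (-0.5 * (1.0 + logvar - mu**2 - nn.exp(logvar))).mean()
        return mse + kl_weight * kl

    def parameters(self):
        return (
            self.enc_h.parameters() + self.enc_mu.parameters()
            + self.enc_logvar.parameters() + self.dec.parameters()
        )


@dataclass
class SpointModel:
    vae: _VAE
    predictor: MLP
    recovery: MLP
    gene_names: np.ndarray
    type_names: np.ndarray
    target_sum: float
    gene_mean: np.ndarray
    gene_std: np.ndarray
    config: SpointConfig
    history: dict = field(default_factory=dict)

    def _latent(self, counts: np.ndarray) -> np.ndarray:
        x = normalize_counts(counts, target_sum=self.target_sum)
        x = (x - self.gene_mean) / self.gene_std
        mu, _ = self.vae.encode(Tensor(x))
        return mu.data

    def predict(self, counts: np.ndarray) -> np.ndarray:
        pred = self.predictor(Tensor(self._latent(counts)))
        return pred.data


def _restrict_genes(counts: np.ndarray, gene_names, wanted) -> np.ndarray:
    pos = {g: i for i, g in enumerate(gene_names)}
    missing = [g for g in wanted if g not in pos]
    if missing:
        raise ValueError(f"missing genes: {missing[:5]}" +
                         (f" (+{len(missing) - 5} more)" if len(missing) > 5 else ""))
    return counts[:, [pos[g] for g in wanted]]


def train_spoint(
    sim: tuple[np.ndarray, CompositionMatrix],
    real: SliceData,
    cfg: SpointConfig,
    gene_names: np.ndarray | None = None,
) -> SpointModel:
    """Train the deconvolution model on simulated spots plus one real slice.

    ``sim`` is (counts, truth) in the same gene space as ``real`` (after
    harmonization and marker restriction); ``gene_names`` names that space
    (defaults to the real slice's genes). Alternates the predictor step and
    the joint recovery/MMD step each epoch until |dLoss_E| < conv_tol.
    """
    sim_counts, truth = sim
    genes = np.asarray(gene_names if gene_names is not None else real.gene_names,
                       dtype=object)
    if sim_counts.shape[1] != len(genes) or real.counts.shape[1] != len(genes):
        raise ValueError("simulated and real data must share the model gene space")

    rng = np.random.default_rng(cfg.seed)
    n_types = truth.proportions.shape[1]
    real_totals = np.asarray(real.counts, float).sum(axis=1)
    target_sum = float(np.median(np.where(real_totals == 0, 1, real_totals)))
    x_sim = normalize_counts(sim_counts, target_sum=target_sum)
    x_real = normalize_counts(real.counts, target_sum=target_sum)
    # per-gene standardization over the pooled data keeps the VAE's squared
    # error comparable across genes of very different expression levels
    pooled = np.vstack([x_sim, x_real])
    gene_mean = pooled.mean(axis=0)
    gene_std = pooled.std(axis=0) + 1e-8
    x_sim = (x_sim - gene_mean) / gene_std
    x_real = (x_real - gene_mean) / gene_std

    vae = _VAE(len(genes), cfg.vae_hidden, cfg.latent_dim, rng)
    x_all = np.vstack([x_sim, x_real])
    vae_opt = Adam(vae.parameters(), lr=cfg.vae_lr)
    for _ in range(cfg.vae_pretrain_epochs):
        loss = vae.elbo_loss(Tensor(x_all), rng, cfg.kl_weight)
        if not np.isfinite(loss.data):
            raise FloatingPointError("non-finite VAE loss")
        vae_opt.zero_grad()
        loss.backward()
        vae_opt.step()

    z_sim = Tensor(vae.encode(Tensor(x_sim))[0].data)
    z_real = Tensor(vae.encode(Tensor(x_real))[0].data)
    p_true = Tensor(np.asarray(truth.proportions, float))

    predictor = MLP(
        (cfg.latent_dim, *cfg.predictor_hidden_dims, n_types), rng,
        out_activation=nn.softmax_head,
    )
    recovery = MLP((n_types, *cfg.recon_hidden_dims, cfg.latent_dim), rng)
    opt_e = Adam(predictor.parameters(), lr=cfg.lr)
    opt_er = Adam(predictor.parameters() + recovery.parameters(),
                  lr=cfg.lr * cfg.align_lr_scale)

    history = {"loss_E": [], "loss_R": [], "loss_M": []}
    prev_loss_e = None
    converged = False
    for epoch in range(cfg.max_epochs):
        # step 1: predictor on simulated spots
        pred_sim = predictor(z_sim)
        loss_e = _proportion_loss_t(pred_sim, p_true)
        if not np.isfinite(loss_e.data):
            raise FloatingPointError("non-finite Loss_E during training")
        opt_e.zero_grad()
        loss_e.backward()
        opt_e.step()

        # step 2: recovery + distribution alignment on both datasets
        pred_sim2, hid_sim = predictor.forward(z_sim, return_hidden=True)
        pred_real2, hid_real = predictor.forward(z_real, return_hidden=True)
        rec = recovery(nn.concatenate([pred_sim2, pred_real2], axis=0))
        z_both = nn.concatenate([z_sim, z_real], axis=0)
        loss_r = _latent_recovery_loss_t(rec, z_both)
        loss_m = _mmd2_t(hid_sim, hid_real, cfg.mmd_sigma)
        total = loss_r + loss_m
        opt_er.zero_grad()
        total.backward()
        opt_er.step()

        le = float(loss_e.data)
        history["loss_E"].append(le)
        history["loss_R"].append(float(loss_r.data))
        history["loss_M"].append(float(loss_m.data))
        if (
            prev_loss_e is not None
            and epoch + 1 >= cfg.min_epochs
            and abs(prev_loss_e - le) < cfg.conv_tol
        ):
            converged = True
            break
        prev_loss_e = le
    if not converged:
        logger.warning("Spoint did not converge in %d epochs; returning "
                       "best-so-far parameters", cfg.max_epochs)

    return SpointModel(
        vae=vae, predictor=predictor, recovery=recovery, gene_names=genes,
        type_names=truth.type_names, target_sum=target_sum,
        gene_mean=gene_mean, gene_std=gene_std, config=cfg, history=history,
    )


def predict_proportions(model: SpointModel, real: SliceData) -> CompositionMatrix:
    """Predict per-spot proportions for a slice in the model's gene space."""
    counts = _restrict_genes(real.counts, real.gene_names, model.gene_names)
    props = model.predict(counts)
    return CompositionMatrix(proportions=props, type_names=model.type_names)
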