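"""Sparse-supervision training of the mean/variance network.

The model is optimized by minimizing the Gaussian negative log-likelihood

    L = (1/N) sum_i  (mu_i - y_i)^2 / (2 sigma_i^2)  +  (1/2) log sigma_i^2

evaluated *only* at pixels that carry a reference label (sparse
supervision): unlabeled pixels contribute nothing to the loss, while the
network still produces dense output everywhere.

Channels and the target are standardized using training-split statistics;
the variance is rescaled consistently (by the squared target sd) so the
likelihood is optimized in normalized space and reported in metres.

To counter the long-tailed height distribution, a softened
inverse-frequency reweighting over 1-m height bins,

    q_k = sqrt(1/N_k) / sum_j sqrt(1/N_j),

multiplies the per-sample loss during a fine-tuning phase that updates
only the final mean-regression layer — the variance head and the trunk
stay untouched so the uncertainty calibration is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam
from .network import CanopyNet, ModelOutput
from .simulate import SparseLabelRaster

__all__ = [
    "NormalizationStats",
    "BalanceWeights",
    "TrainConfig",
    "TrainResult",
    "sparse_nll_loss",
    "compute_balance_weights",
    "train",
    "finetune_mean_head",
]

_SD_FLOOR = 1e-6  # guards near-constant channels (e.g. geo channels of one scene)


@dataclass
class NormalizationStats:
    """Per-channel and target standardization fitted on the training split."""

    channel_mean: np.ndarray
    channel_sd: np.ndarray
    target_mean: float
    target_sd: float

    def __post_init__(self):
        if np.any(self.channel_sd <= 0) or self.target_sd <= 0:
            raise ValueError("standard deviations must be positive")

    @classmethod
    def fit(cls, x: np.ndarray, y: np.ndarray) -> "NormalizationStats":
        """x: (N, C, H, W) patches; y: labels (any shape, NaN = unlabeled)."""
        cm = x.mean(axis=(0, 2, 3), dtype=np.float64)
        cs = np.maximum(x.std(axis=(0, 2, 3), dtype=np.float64), _SD_FLOOR)
        vals = np.asarray(y, dtype=np.float64)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("no valid labels to fit target statistics")
        return cls(channel_mean=cm, channel_sd=cs,
                   target_mean=float(vals.mean()),
                   target_sd=float(max(vals.std(), _SD_FLOOR)))

    def normalize_channels(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.channel_mean[None, :, None, None])
                / self.channel_sd[None, :, None, None]).astype(np.float32)

    def normalize_target(self, y):
        return (np.asarray(y, dtype=np.float64) - self.target_mean) / self.target_sd

    def denormalize_target(self, y_n):
        return np.asarray(y_n, dtype=np.float64) * self.target_sd + self.target_mean


@dataclass
class BalanceWeights:
    """Softened inverse-frequency weights over 1-m height bins."""

    bin_edges: np.ndarray    # K+1 edges, half-open bins [k, k+1)
    counts: np.ndarray       # N_k per bin
    q: np.ndarray            # normalized weights, 0 for empty bins
    K: int

    def weight_of(self, y) -> np.ndarray:
        """Per-sample weight: q of the bin containing each label."""
        idx = np.clip(np.digitize(np.asarray(y, dtype=float), self.bin_edges) - 1,
                      0, self.K - 1)
        return self.q[idx]


def compute_balance_weights(labels, bin_width: float = 1.0,
                            max_height: float | None = None) -> BalanceWeights:
    """Bin labels into ``bin_width``-m intervals and derive sqrt-inverse-frequency
    weights, normalized over the nonempty bins (empty bins get weight 0)."""
    y = np.asarray(labels, dtype=float).ravel()
    y = y[np.isfinite(y)]
    if y.size == 0:
        raise ValueError("at least one label is required")
    top = max_height if max_height is not None else float(y.max())
    n_bins = max(int(np.ceil(top / bin_width)), 1)
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    idx = np.clip(np.digitize(y, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    q = np.zeros(n_bins)
    nonempty = counts > 0
    inv = np.sqrt(1.0 / counts[nonempty])
    q[nonempty] = inv / inv.sum()
    return BalanceWeights(bin_edges=edges, counts=counts, q=q, K=n_bins)


def _as_arrays(out, labels):
    if isinstance(out, ModelOutput):
        mean, var = out.mean, out.variance
    else:
        mean, var = out
    if isinstance(labels, SparseLabelRaster):
        y, mask = labels.heights, labels.valid
    else:
        y = np.asarray(labels, dtype=float)
        mask = np.isfinite(y)
    return np.asarray(mean, float), np.asarray(var, float), y, mask


def sparse_nll_loss(out, labels, weights: BalanceWeights | None = None) -> float:
    """Gaussian NLL averaged over valid label pixels only.

    ``out`` is a :class:`ModelOutput` (or ``(mean, variance)`` arrays);
    ``labels`` a :class:`SparseLabelRaster` (or an array with NaN at
    unlabeled pixels). With ``weights`` the per-sample term is multiplied
    by the q of the label's 1-m bin. Raises if no pixel is valid — a
    silent 0 would mask upstream masking bugs.
    """
    mean, var, y, mask = _as_arrays(out, labels)
    if mean.shape != y.shape:
        raise ValueError("prediction and label grids must share shape")
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("no valid label pixels: loss undefined")
    mu, v, yy = mean[mask], var[mask], y[mask]
    terms = (mu - yy) ** 2 / (2.0 * v) + 0.5 * np.log(v)
    if weights is not None:
        terms = terms * weights.weight_of(yy)
    return float(terms.mean())


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule.

    The step decay mirrors the production schedule in shape: the learning
    rate drops by ``decay`` at fixed fractions of the total iteration
    budget (0.4 and 0.7 by default), so the schedule scales to any budget.
    """

    iterations: int = 1000
    batch_size: int = 64
    base_lr: float = 1e-4
    milestone_fracs: tuple[float, ...] = (0.4, 0.7)
    decay: float = 0.1
    seed: int = 0
    finetune_iterations: int = 200
    finetune_scope: str = "mean_head"

    def __post_init__(self):
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be positive")
        if self.base_lr <= 0 or not 0 < self.decay <= 1:
            raise ValueError("base_lr must be > 0 and decay in (0, 1]")
        if any(not 0 < f < 1 for f in self.milestone_fracs):
            raise ValueError("milestone fractions must lie strictly in (0, 1)")

    @property
    def milestones(self) -> tuple[int, ...]:
        return tuple(int(f * self.iterations) for f in self.milestone_fracs)

    def lr_at(self, iteration: int) -> float:
        passed = sum(iteration >= m for m in self.milestones)
        return self.base_lr * self.decay ** passed


@dataclass
class TrainResult:
    losses: np.ndarray
    lrs: np.ndarray
    stats: NormalizationStats
    config: TrainConfig
    finetuned: bool = False


def _nll_grads(mean_n, logvar_n, y_n, valid, weights_px):
    """Loss value and gradients w.r.t. mean and log-variance (normalized)."""
    n_valid = int(valid.sum())
    var = np.exp(logvar_n)
    resid = np.where(valid, mean_n - np.where(valid, y_n, 0.0), 0.0)
    w = weights_px if weights_px is not None else 1.0
    terms = np.where(valid, resid ** 2 / (2 * var) + 0.5 * logvar_n, 0.0)
    if weights_px is not None:
        terms = terms * weights_px
    loss = float(terms.sum() / n_valid)
    scale = (w / n_valid) if weights_px is not None else (1.0 / n_valid)
    dmean = np.where(valid, scale * resid / var, 0.0)
    dlogvar = np.where(valid, scale * (0.5 - resid ** 2 / (2 * var)), 0.0)
    return loss, dmean, dlogvar


def _prepare(net, x, y, stats):
    if x.ndim != 4 or y.shape != (x.shape[0],) + x.shape[2:]:
        raise ValueError("expected x (N, C, H, W) and y (N, H, W)")
    if stats is None:
        stats = NormalizationStats.fit(x, y)
    xn = stats.normalize_channels(x)
    valid = np.isfinite(y)
    yn = np.where(valid, stats.normalize_target(np.where(valid, y, 0.0)), 0.0)
    usable = valid.reshape(len(y), -1).any(axis=1)
    if not usable.any():
        raise ValueError("no patch carries a valid label")
    return stats, xn, yn, valid, np.flatnonzero(usable)


def _run_loop(net, opt_params, xn, yn, valid, weights_px, cfg, rng, log_file):
    params = opt_params
    opt = Adam(params, lr=cfg.base_lr)
    name_index = {id(p): i for i, (n, p) in enumerate(net.named_parameters())}
    sel = [name_index[id(p)] for p in params]
    losses = np.empty(cfg.iterations)
    lrs = np.empty(cfg.iterations)
    usable = np.arange(len(xn))
    has_label = valid.reshape(len(xn), -1).any(axis=1)
    usable = usable[has_label]
    for it in range(cfg.iterations):
        idx = rng.choice(usable, size=min(cfg.batch_size, len(usable)),
                         replace=len(usable) < cfg.batch_size)
        xb, yb, vb = xn[idx], yn[idx], valid[idx]
        wb = weights_px[idx] if weights_px is not None else None
        mean_n, logvar_n = net.forward(xb)
        loss, dmean, dlogvar = _nll_grads(mean_n, logvar_n, yb, vb, wb)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss at iteration {it}: loss={loss}, "
                f"logvar range [{logvar_n.min():.3g}, {logvar_n.max():.3g}]")
        net.zero_grad()
        net.backward(dmean, dlogvar)
        grads = [net.gradients()[i] for i in sel]
        opt.lr = cfg.lr_at(it)
        opt.step(grads)
        losses[it] = loss
        lrs[it] = opt.lr
        if log_file is not None:
            log_file.write(f"{it}\t{opt.lr:.8g}\t{loss:.8g}\n")
    return losses, lrs


def train(net: CanopyNet, x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
          stats: NormalizationStats | None = None,
          balance: BalanceWeights | None = None,
          log_path=None) -> TrainResult:
    """Train all network parameters on sparse patches.

    Parameters
    ----------
    x : (N, C, H, W) float patches (raw, un-normalized).
    y : (N, H, W) labels in metres, NaN at unlabeled pixels.
    cfg : TrainConfig
    stats : optional pre-fitted normalization (fitted from x, y otherwise;
        they must then be the training split).
    balance : optional BalanceWeights applied per-sample.

    Deterministic given ``cfg.seed``. Raises on non-finite loss.
    """
    stats, xn, yn, valid, _ = _prepare(net, x, y, stats)
    weights_px = None
    if balance is not None:
        weights_px = np.where(valid, balance.weight_of(np.where(valid, y, 0.0)), 0.0)
    rng = np.random.default_rng(cfg.seed)
    fh = open(log_path, "a") if log_path else None
    try:
        losses, lrs = _run_loop(net, net.parameters(), xn, yn, valid,
                                weights_px, cfg, rng, fh)
    finally:
        if fh:
            fh.close()
    return TrainResult(losses=losses, lrs=lrs, stats=stats, config=cfg)


def finetune_mean_head(net: CanopyNet, x: np.ndarray, y: np.ndarray,
                       weights: BalanceWeights, cfg: TrainConfig,
                       stats: NormalizationStats,
                       log_path=None) -> TrainResult:
    """Height-balanced fine-tuning of the final mean-regression layer only.

    Every parameter outside the mean head is bit-identical before and
    after. ``weights`` are mandatory: unweighted fine-tuning of the mean
    head would merely re-fit the same imbalanced objective.
    """
    if weights is None:
        raise ValueError("balance weights are required for fine-tuning")
    if stats is None:
        raise ValueError("pass the normalization stats used for base training")
    ft_cfg = TrainConfig(iterations=cfg.finetune_iterations,
                         batch_size=cfg.batch_size, base_lr=cfg.base_lr,
                         milestone_fracs=cfg.milestone_fracs, decay=cfg.decay,
                         seed=cfg.seed + 1)
    _, xn, yn, valid, _ = _prepare(net, x, y, stats)
    weights_px = np.where(valid, weights.weight_of(np.where(valid, y, 0.0)), 0.0)
    head_params = [p for name, p in net.named_parameters()
                   if name.startswith("head_mean.")]
    rng = np.random.default_rng(ft_cfg.seed)
    fh = open(log_path, "a") if log_path else None
    try:
        losses, lrs = _run_loop(net, head_params, xn, yn, valid, weights_px,
                                ft_cfg, rng, fh)
    finally:
        if fh:
            fh.close()
    return TrainResult(losses=losses, lrs=lrs, stats=stats, config=ft_cfg,
                       finetuned=True)
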