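"""Deep-ensemble construction and inverse-variance prediction fusion.

Epistemic uncertainty is captured by an ensemble of identically
structured networks trained from independent random initializations.
At inference each acquisition date is processed by one randomly assigned
member; the T per-date Gaussian predictions (mu_t, sigma_t^2) at a pixel
are merged by inverse-variance weighting,

    p_t = (1/sigma_t^2) / sum_j (1/sigma_j^2),      y = sum_t p_t mu_t,

and the fused variance follows the weighted law of total variance,

    Var(y) = sum_t p_t mu_t^2 - (sum_t p_t mu_t)^2 + sum_t p_t sigma_t^2,

i.e. the between-date spread of the means plus the weighted average of
the per-date (aleatoric) variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import CanopyNet, NetworkConfig
from .training import NormalizationStats, TrainConfig, TrainResult, train

__all__ = ["ModelEnsemble", "FusionInput", "assign_members", "fuse"]

logger = logging.getLogger(__name__)

# variances below this floor (m^2) are clipped before inversion to avoid
# overflow; the clip is logged because it slightly rebalances the weights
VARIANCE_FLOOR = 1e-6


@dataclass
class FusionInput:
    """Per-date mean/variance grids with validity masks, stacked over T."""

    means: np.ndarray       # (T, H, W) metres
    variances: np.ndarray   # (T, H, W) m^2, > 0 where valid
    valid: np.ndarray       # (T, H, W) bool

    def __post_init__(self):
        if not (self.means.shape == self.variances.shape == self.valid.shape):
            raise ValueError("means, variances and valid must share shape")
        if self.means.ndim != 3:
            raise ValueError("fusion input must be (T, H, W)")


@dataclass
class ModelEnsemble:
    """Independently initialized/trained networks of identical architecture."""

    members: list[CanopyNet]
    member_seeds: list[int]
    stats: NormalizationStats | None = None
    train_results: list[TrainResult] = field(default_factory=list)

    def __post_init__(self):
        cfgs = {(m.config.in_channels, m.config.n_blocks, m.config.filters)
                for m in self.members}
        if len(cfgs) > 1:
            raise ValueError("ensemble members must share one architecture")
        if len(set(self.member_seeds)) != len(self.member_seeds):
            raise ValueError("member init seeds must be distinct")

    def __len__(self):
        return len(self.members)

    @classmethod
    def create(cls, config: NetworkConfig, n_members: int = 5,
               seed: int = 0) -> "ModelEnsemble":
        seeds = [seed * 1000 + k for k in range(n_members)]
        members = [CanopyNet(NetworkConfig(
            in_channels=config.in_channels, n_blocks=config.n_blocks,
            filters=config.filters, seed=s)) for s in seeds]
        return cls(members=members, member_seeds=seeds)

    def fit(self, x, y, cfg: TrainConfig, balance=None):
        """Train every member on the same data with member-specific seeds."""
        stats = NormalizationStats.fit(x, y)
        self.stats = stats
        self.train_results = []
        for k, net in enumerate(self.members):
            member_cfg = TrainConfig(
                iterations=cfg.iterations, batch_size=cfg.batch_size,
                base_lr=cfg.base_lr, milestone_fracs=cfg.milestone_fracs,
                decay=cfg.decay, seed=cfg.seed + 7919 * (k + 1),
                finetune_iterations=cfg.finetune_iterations,
                finetune_scope=cfg.finetune_scope)
            self.train_results.append(train(net, x, y, member_cfg, stats=stats,
                                            balance=balance))
        return self


def assign_members(t_dates: int, k_members: int, seed: int) -> np.ndarray:
    """Uniform independent member index per acquisition date (deterministic)."""
    if t_dates < 1 or k_members < 1:
        raise ValueError("T and ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.integers(0, k_members, size=t_dates)


def fuse(inp: FusionInput):
    """Inverse-variance fusion of T per-date predictions per pixel.

    Weights are renormalized per pixel over the valid dates only; pixels
    with no valid date are flagged nodata. Raises if any valid variance is
    non-positive.

    Returns
    -------
    (mean, variance, nodata) : three (H, W) arrays; mean/variance are NaN
    where nodata is True.
    """
    means = np.asarray(inp.means, dtype=np.float64)
    variances = np.asarray(inp.variances, dtype=np.float64)
    valid = np.asarray(inp.valid, dtype=bool)
    if np.any(valid & (variances <= 0)):
        raise ValueError("non-positive variance among valid dates")
    n_floored = int(np.sum(valid & (variances < VARIANCE_FLOOR)))
    if n_floored:
        logger.info("fusion: floored %d tiny variances at %g m^2",
                    n_floored, VARIANCE_FLOOR)
    var_safe = np.maximum(variances, VARIANCE_FLOOR)

    w = np.where(valid, 1.0 / var_safe, 0.0)
    w_sum = w.sum(axis=0)
    nodata = w_sum == 0
    denom = np.where(nodata, 1.0, w_sum)
    p = w / denom
    fused_mean = (p * means).sum(axis=0)
    second_moment = (p * means ** 2).sum(axis=0)
    within = (p * var_safe).sum(axis=0)
    fused_var = second_moment - fused_mean ** 2 + within
    # between-date term is a weighted variance: clip the tiny negative
    # round-off that appears when all means coincide
    fused_var = np.maximum(fused_var, within - 1e-12)
    fused_mean = np.where(nodata, np.nan, fused_mean)
    fused_var = np.where(nodata, np.nan, fused_var)
    return fused_mean, fused_var, nodata
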