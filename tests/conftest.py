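"""Shared fixtures.

The expensive end-to-end system (ensemble trained on synthetic sparse
patches, evaluated on held-out scenes before and after height-balanced
fine-tuning) is built once per session and shared by the tests that probe
different aspects of it.
"""

from __future__ import annotations

import numpy as np
import pytest

from canopyfuse.ensemble import ModelEnsemble
from canopyfuse.network import NetworkConfig
from canopyfuse.pipeline import predict_tile
from canopyfuse.simulate import (
    SimConfig,
    build_patch_dataset,
    disc_max_truth,
    simulate_scene,
)
from canopyfuse.training import (
    TrainConfig,
    compute_balance_weights,
    finetune_mean_head,
)

# Desk-scale study conditions: ~4.5k patches of 15x15 from 40 scenes,
# 3-member ensemble of the small profile (2 blocks x 32 filters), a few
# hundred Adam iterations per member.
SIM = SimConfig(grid_size=48, seed=100)
TRAIN = TrainConfig(iterations=500, batch_size=64, base_lr=3e-3, seed=5,
                    finetune_iterations=150)
HELDOUT_SEEDS = (990, 991, 992, 993)


def _evaluate(ens):
    """Fused predictions vs GEDI-like disc-max truth on held-out scenes."""
    preds, truths, stds = [], [], []
    for s in HELDOUT_SEEDS:
        cfg = SimConfig(grid_size=48, seed=s)
        field, stack, _, _ = simulate_scene(cfg, 10)
        pmap = predict_tile(stack, ens, seed=1)
        truth = disc_max_truth(field, cfg.footprint_radius)
        ok = ~pmap.nodata
        preds.append(pmap.mean[ok])
        truths.append(truth[ok])
        stds.append(pmap.std[ok])
    return (np.concatenate(preds), np.concatenate(truths),
            np.concatenate(stds))


@pytest.fixture(scope="session")
def trained_system():
    x, y, _ = build_patch_dataset(SIM, n_scenes=40, n_footprints=220,
                                  base_seed=100)
    ens = ModelEnsemble.create(
        NetworkConfig.small(in_channels=x.shape[1], seed=5),
        n_members=3, seed=5)
    ens.fit(x, y, TRAIN)

    pred0, truth0, std0 = _evaluate(ens)

    frozen = {}
    for k, net in enumerate(ens.members):
        frozen[k] = {name: p.copy() for name, p in net.named_parameters()
                     if not name.startswith("head_mean.")}
    weights = compute_balance_weights(y[np.isfinite(y)])
    for net in ens.members:
        finetune_mean_head(net, x, y, weights, TRAIN, stats=ens.stats)
    pred1, truth1, std1 = _evaluate(ens)

    return {
        "x": x, "y": y, "ensemble": ens, "weights": weights,
        "frozen_params": frozen,
        "before": (pred0, truth0, std0),
        "after": (pred1, truth1, std1),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
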