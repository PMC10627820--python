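"""scikit-learn style estimators wrapping the training and fusion machinery.

`CanopyHeightRegressor` fits one mean/variance network on sparse patches;
`CanopyHeightEnsemble` fits several independently initialized networks
and fuses their per-patch predictions by inverse-variance weighting.
Both follow the sklearn estimator contract (get_params/set_params,
fitted attributes with a trailing underscore, ValueError on bad input),
so they compose with `sklearn.base.clone` and model-selection utilities.

X is image-shaped — ``(n_samples, n_channels, height, width)`` — and y is
``(n_samples, height, width)`` with NaN at unlabeled pixels, mirroring
the sparse-supervision setting.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .ensemble import FusionInput, ModelEnsemble, fuse
from .network import CanopyNet, NetworkConfig
from .training import (
    TrainConfig,
    compute_balance_weights,
    finetune_mean_head,
    train,
)

__all__ = ["CanopyHeightRegressor", "CanopyHeightEnsemble"]


def _validate_xy(X, y=None):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 4:
        raise ValueError("X must be (n_samples, n_channels, height, width)")
    if y is not None:
        y = np.asarray(y, dtype=np.float32)
        if y.shape != (X.shape[0],) + X.shape[2:]:
            raise ValueError("y must be (n_samples, height, width)")
        return X, y
    return X


class CanopyHeightRegressor(RegressorMixin, BaseEstimator):
    """Dense per-pixel height regression with aleatoric uncertainty.

    Parameters
    ----------
    n_blocks, n_filters : architecture size (desk-scale default 2 x 32;
        the deployment profile is 8 x 256).
    iterations, batch_size, learning_rate, milestone_fracs, decay :
        optimizer schedule (step decay at fractions of the budget).
    finetune_iterations : if > 0, run height-balanced fine-tuning of the
        mean head after base training.
    random_state : seed for initialization and batch sampling.
    """

    def __init__(self, n_blocks=2, n_filters=32, iterations=300, batch_size=64,
                 learning_rate=3e-3, milestone_fracs=(0.4, 0.7), decay=0.1,
                 finetune_iterations=0, random_state=0):
        self.n_blocks = n_blocks
        self.n_filters = n_filters
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.milestone_fracs = milestone_fracs
        self.decay = decay
        self.finetune_iterations = finetune_iterations
        self.random_state = random_state

    def _train_config(self):
        return TrainConfig(iterations=self.iterations,
                           batch_size=self.batch_size,
                           base_lr=self.learning_rate,
                           milestone_fracs=tuple(self.milestone_fracs),
                           decay=self.decay, seed=self.random_state,
                           finetune_iterations=max(self.finetune_iterations, 1))

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        cfg = self._train_config()
        net = CanopyNet(NetworkConfig(in_channels=X.shape[1],
                                      n_blocks=self.n_blocks,
                                      filters=self.n_filters,
                                      seed=self.random_state))
        result = train(net, X, y, cfg)
        self.net_ = net
        self.stats_ = result.stats
        self.loss_trace_ = result.losses
        self.n_channels_in_ = X.shape[1]
        if self.finetune_iterations > 0:
            vals = y[np.isfinite(y)]
            self.balance_weights_ = compute_balance_weights(vals)
            finetune_mean_head(net, X, y, self.balance_weights_, cfg,
                               stats=self.stats_)
        return self

    def predict(self, X, return_std: bool = False):
        """Per-pixel mean heights (m); optionally the predictive std (m)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        X = _validate_xy(X)
        if X.shape[1] != self.n_channels_in_:
            raise ValueError("channel count differs from fit time")
        means = np.empty(X.shape[:1] + X.shape[2:])
        stds = np.empty_like(means)
        for i in range(len(X)):
            out = self.net_.predict(X[i], stats=self.stats_)
            means[i] = out.mean
            stds[i] = np.sqrt(out.variance)
        return (means, stds) if return_std else means

    def score(self, X, y):
        """R^2 over the labeled pixels (NaN-sparse y supported)."""
        X, y = _validate_xy(X, y)
        pred = self.predict(X)
        mask = np.isfinite(y)
        yy, pp = y[mask], pred[mask]
        ss_res = np.sum((yy - pp) ** 2)
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        return 1.0 - ss_res / ss_tot


class CanopyHeightEnsemble(RegressorMixin, BaseEstimator):
    """Deep ensemble of height regressors with inverse-variance fusion.

    ``predict`` fuses the members' per-patch Gaussian predictions with
    inverse-variance weights (the same rule used to merge acquisition
    dates in the mapping pipeline).
    """

    def __init__(self, n_members=3, n_blocks=2, n_filters=32, iterations=300,
                 batch_size=64, learning_rate=3e-3, milestone_fracs=(0.4, 0.7),
                 decay=0.1, finetune_iterations=0, random_state=0):
        self.n_members = n_members
        self.n_blocks = n_blocks
        self.n_filters = n_filters
        self.iterations = iterations
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.milestone_fracs = milestone_fracs
        self.decay = decay
        self.finetune_iterations = finetune_iterations
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        cfg = TrainConfig(iterations=self.iterations, batch_size=self.batch_size,
                          base_lr=self.learning_rate,
                          milestone_fracs=tuple(self.milestone_fracs),
                          decay=self.decay, seed=self.random_state,
                          finetune_iterations=max(self.finetune_iterations, 1))
        ens = ModelEnsemble.create(
            NetworkConfig(in_channels=X.shape[1], n_blocks=self.n_blocks,
                          filters=self.n_filters, seed=self.random_state),
            n_members=self.n_members, seed=self.random_state)
        ens.fit(X, y, cfg)
        if self.finetune_iterations > 0:
            vals = y[np.isfinite(y)]
            self.balance_weights_ = compute_balance_weights(vals)
            for net in ens.members:
                finetune_mean_head(net, X, y, self.balance_weights_, cfg,
                                   stats=ens.stats)
        self.ensemble_ = ens
        self.n_channels_in_ = X.shape[1]
        return self

    def predict(self, X, return_std: bool = False):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "ensemble_")
        X = _validate_xy(X)
        if X.shape[1] != self.n_channels_in_:
            raise ValueError("channel count differs from fit time")
        ens = self.ensemble_
        means = np.empty(X.shape[:1] + X.shape[2:])
        stds = np.empty_like(means)
        for i in range(len(X)):
            m = np.stack([net.predict(X[i], stats=ens.stats).mean
                          for net in ens.members])
            v = np.stack([net.predict(X[i], stats=ens.stats).variance
                          for net in ens.members])
            valid = np.ones_like(m, dtype=bool)
            fm, fv, _ = fuse(FusionInput(m, v, valid))
            means[i] = fm
            stds[i] = np.sqrt(fv)
        return (means, stds) if return_std else means
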