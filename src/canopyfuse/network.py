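"""Fully convolutional mean/variance regression network.

A stem 3x3 convolution feeds a sequence of residual blocks built from
depthwise-separable 3x3 convolutions (no downsampling anywhere, so output
resolution always equals input resolution and arbitrarily sized patches
can be processed). Two separate 1x1 convolution heads read the shared
feature map: one predicts the mean height, the other the log-variance,
which is exponentiated so the predictive variance is strictly positive
for any finite weights.

Residual block layout (the exact variant used here):

    t = relu(sep_conv_1(x)); t = sep_conv_2(t); y = relu(x + t)

The network operates in normalized space (channels and target both
standardized); :meth:`CanopyNet.predict` converts back to metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Conv3x3, Conv1x1, SeparableConv3x3, ReLU

__all__ = ["NetworkConfig", "ModelOutput", "CanopyNet"]

# log-variance is clipped to this symmetric range (normalized space) for
# numerical stability; gradients are masked where the clip is active
LOGVAR_CLIP = 8.0


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    The deployment-scale profile uses 8 blocks x 256 filters; the
    desk-scale default for experiments is 2 blocks x 32 filters
    (``NetworkConfig.small()``), which is an efficiency choice, not an
    algorithmic one.
    """

    in_channels: int = 15
    n_blocks: int = 8
    filters: int = 256
    kernel_size: int = 3
    variance_param: str = "log"
    seed: int = 0

    def __post_init__(self):
        if self.n_blocks < 1 or self.filters < 1 or self.in_channels < 1:
            raise ValueError("blocks, filters and in_channels must be >= 1")
        if self.kernel_size != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.variance_param != "log":
            raise ValueError("only log-variance parameterization is supported")

    @classmethod
    def small(cls, in_channels: int = 15, seed: int = 0) -> "NetworkConfig":
        return cls(in_channels=in_channels, n_blocks=2, filters=32, seed=seed)

    @classmethod
    def paper(cls, in_channels: int = 15, seed: int = 0) -> "NetworkConfig":
        return cls(in_channels=in_channels, n_blocks=8, filters=256, seed=seed)


@dataclass
class ModelOutput:
    """Dense per-pixel Gaussian prediction in metres."""

    mean: np.ndarray       # (H, W) metres
    variance: np.ndarray   # (H, W) square metres, strictly positive

    def __post_init__(self):
        if self.mean.shape != self.variance.shape:
            raise ValueError("mean and variance must share shape")
        if np.any(self.variance <= 0):
            raise ValueError("variance must be strictly positive")


class CanopyNet:
    """The mean/variance FCN with explicit forward and backward passes."""

    def __init__(self, config: NetworkConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        f = config.filters
        self.stem = Conv3x3(config.in_channels, f, rng, dtype)
        self.stem_relu = ReLU()
        self.blocks = []
        for _ in range(config.n_blocks):
            self.blocks.append({
                "sep1": SeparableConv3x3(f, f, rng, dtype),
                "relu1": ReLU(),
                "sep2": SeparableConv3x3(f, f, rng, dtype),
                "relu2": ReLU(),
            })
        self.head_mean = Conv1x1(f, 1, rng, dtype)
        self.head_logvar = Conv1x1(f, 1, rng, dtype)

    # ------------------------------------------------------------------ params
    def _named_layers(self):
        yield "stem", self.stem
        for i, blk in enumerate(self.blocks):
            yield f"block{i}_sep1", blk["sep1"]
            yield f"block{i}_sep2", blk["sep2"]
        yield "head_mean", self.head_mean
        yield "head_logvar", self.head_logvar

    def named_parameters(self):
        """Ordered (name, array) pairs; arrays are live references."""
        out = []
        for lname, layer in self._named_layers():
            for pname in sorted(layer.params):
                out.append((f"{lname}.{pname}", layer.params[pname]))
        return out

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def gradients(self):
        out = []
        for lname, layer in self._named_layers():
            for pname in sorted(layer.grads):
                out.append(layer.grads[pname])
        return out

    def zero_grad(self):
        for _, layer in self._named_layers():
            layer.zero_grad()

    @property
    def receptive_margin(self) -> int:
        """Half-width of the receptive field: one pixel per 3x3 convolution."""
        return 1 + 2 * self.config.n_blocks

    # ----------------------------------------------------------------- forward
    def forward(self, x: np.ndarray):
        """Raw forward pass in normalized space.

        Parameters
        ----------
        x : (N, C, H, W)

        Returns
        -------
        mean_n, logvar_n : (N, H, W) arrays
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}")
        t = self.stem_relu.forward(self.stem.forward(x))
        self._block_inputs = []
        for blk in self.blocks:
            self._block_inputs.append(t)
            u = blk["relu1"].forward(blk["sep1"].forward(t))
            u = blk["sep2"].forward(u)
            t = blk["relu2"].forward(t + u)
        self._trunk_out = t
        mean = self.head_mean.forward(t)[:, 0]
        logvar_raw = self.head_logvar.forward(t)[:, 0]
        self._clip_mask = np.abs(logvar_raw) < LOGVAR_CLIP
        logvar = np.clip(logvar_raw, -LOGVAR_CLIP, LOGVAR_CLIP)
        return mean, logvar

    def backward(self, dmean: np.ndarray, dlogvar: np.ndarray):
        """Accumulate parameter gradients for the cached forward pass."""
        dmean = dmean[:, None].astype(self.dtype)
        dlogvar = (dlogvar * self._clip_mask)[:, None].astype(self.dtype)
        dt = self.head_mean.backward(dmean) + self.head_logvar.backward(dlogvar)
        for blk in reversed(self.blocks):
            dsum = blk["relu2"].backward(dt)
            du = blk["sep2"].backward(dsum)
            du = blk["relu1"].backward(du)
            dt = dsum + blk["sep1"].backward(du)
        self.stem.backward(self.stem_relu.backward(dt))

    # ----------------------------------------------------------------- predict
    def predict(self, image: np.ndarray, stats=None) -> ModelOutput:
        """Dense prediction in metres for a single (C, H, W) image.

        ``stats`` is a :class:`canopyfuse.training.NormalizationStats`;
        when omitted the network is assumed to operate in metres directly.
        """
        image = np.asarray(image)
        if image.ndim != 3:
            raise ValueError("image must be (C, H, W)")
        x = image[None]
        if stats is not None:
            x = stats.normalize_channels(x)
        mean_n, logvar_n = self.forward(x)
        var_n = np.exp(logvar_n)
        if stats is not None:
            mean = stats.denormalize_target(mean_n[0])
            var = var_n[0] * stats.target_sd ** 2
        else:
            mean, var = mean_n[0], var_n[0]
        return ModelOutput(mean=np.asarray(mean, dtype=np.float64),
                           variance=np.asarray(var, dtype=np.float64))

    # -------------------------------------------------------------- checkpoint
    def state_dict(self):
        return {name: p.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            if name not in state:
                raise KeyError(f"missing parameter {name}")
            if state[name].shape != p.shape:
                raise ValueError(f"shape mismatch for {name}")
            p[...] = state[name]

    def save(self, path):
        """Single-file checkpoint with the architecture config embedded."""
        arrays = {k.replace(".", "__"): v for k, v in self.state_dict().items()}
        np.savez(path, __config__=np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, dtype=np.float32) -> "CanopyNet":
        data = np.load(path)
        cfg = NetworkConfig(**json.loads(bytes(data["__config__"]).decode()))
        net = cls(cfg, dtype=dtype)
        state = {k.replace("__", "."): v for k, v in data.items()
                 if k != "__config__"}
        net.load_state_dict(state)
        return net
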