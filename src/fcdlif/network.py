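"""FC-DLIF: fully convolutional prediction of the arterial input function.

The model is two stacked sub-networks.  A spatial feature extractor (SFE)
— a small 3D residual network — is applied to every time frame with shared
weights and condenses each frame to a 32-dimensional feature vector.  The
stacked (T, 32) sequence is then processed by a temporal feature extractor
(TFE), a stack of 1-D "same"-padded convolutions that reduces the channel
dimension 32 -> ... -> 1, producing a curve with exactly as many values as
the input has frames.  Because both parts are purely convolutional the
model accepts any number of time frames, and its output shifts with the
input in time (up to the TFE receptive field at the sequence boundaries).

The default configuration follows the published skeleton (residual blocks
interleaved with max-pooling, a 4x2x2 cuboid convolution, adaptive average
pooling to 32 features, a 1-D convolutional head) with channel widths
chosen by an explicit budget search so that the trainable parameter count
is exactly 90 124; see ``scripts/architecture_search.py``.  The published
block widths are not recoverable from the total alone, so this
configuration is one admissible member of the family that meets the budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import Adam, ConvND, GlobalAvgPool, MaxPool3d, Param, ReLU, ResBlock3d
from .formats_io import BloodCurve, DynamicPETImage, CANONICAL_SHAPE
from .phantom import REDUCED_SHAPE


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``sfe_channels`` are the residual-block widths; each block is preceded
    by a 2x max-pool, so three blocks shrink the grid eightfold before the
    ``final_kernel`` (4x2x2) convolution maps to ``feature_dim`` channels
    and global average pooling yields one 32-vector per frame.  The second
    block is deliberately narrower than the first, keeping spatial capacity
    low where temporal modeling is deferred to the TFE.  ``tfe_channels``
    are the hidden widths of the 1-D head (32 -> ... -> 1 overall), with an
    odd ``tfe_kernel`` and zero "same" padding so the temporal length is
    preserved for any input length.
    """

    sfe_channels: tuple[int, ...] = (16, 8, 40)
    feature_dim: int = 32
    final_kernel: tuple[int, int, int] = (4, 2, 2)
    tfe_channels: tuple[int, ...] = (17, 6)
    tfe_kernel: int = 7
    input_shape: tuple[int, int, int] = CANONICAL_SHAPE
    activation: str = "relu"
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.feature_dim != 32:
            raise ValueError("feature dimension is fixed at 32")
        if self.tfe_kernel % 2 == 0 or self.tfe_kernel < 1:
            raise ValueError("TFE kernel width must be a positive odd integer")
        if len(self.sfe_channels) < 1 or any(c < 1 for c in self.sfe_channels):
            raise ValueError("SFE channel widths must be positive")
        if len(self.sfe_channels) >= 2 and self.sfe_channels[1] > self.sfe_channels[0]:
            raise ValueError("second SFE block must not be wider than the first")
        if self.activation != "relu":
            raise ValueError("only ReLU activation is implemented")
        if self.normalization != "none":
            raise ValueError("only norm-free blocks are implemented")
        n_pool = len(self.sfe_channels)
        d, h, w = self.input_shape
        f = 2**n_pool
        if d % f or h % f or w % f:
            raise ValueError(
                f"input shape {self.input_shape} not divisible by the pooling factor {f}"
            )
        kd, kh, kw = self.final_kernel
        if d // f < kd or h // f < kh or w // f < kw:
            raise ValueError(
                f"input shape {self.input_shape} too small for the final {self.final_kernel} kernel"
            )

    @property
    def tfe_receptive_radius(self) -> int:
        """Frames on each side of t that can influence output t."""
        n_layers = len(self.tfe_channels) + 1
        return n_layers * (self.tfe_kernel // 2)


def reduced_config(**overrides) -> NetworkConfig:
    """Default topology on the 32x16x16 desk-scale grid."""
    return NetworkConfig(input_shape=REDUCED_SHAPE, **overrides)


class Network:
    """The assembled predictor: shared-weight per-frame SFE + temporal head."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.stages = []
        c_prev = 1
        for i, c in enumerate(config.sfe_channels):
            self.stages.append((MaxPool3d(), ResBlock3d(c_prev, c, rng, f"sfe.block{i}")))
            c_prev = c
        self.final_conv = ConvND(
            c_prev, config.feature_dim, config.final_kernel, (0, 0, 0), rng, "sfe.final"
        )
        self.final_relu = ReLU()
        self.gap = GlobalAvgPool()
        k = config.tfe_kernel
        pad = k // 2
        chans = (config.feature_dim,) + tuple(config.tfe_channels) + (1,)
        self.tfe_convs = []
        self.tfe_relus = []
        for i, (a, b) in enumerate(zip(chans, chans[1:])):
            self.tfe_convs.append(ConvND(a, b, (k,), (pad,), rng, f"tfe.conv{i}"))
            self.tfe_relus.append(ReLU() if i < len(chans) - 2 else None)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[Param]:
        params: list[Param] = []
        for _, block in self.stages:
            params += block.params
        params += self.final_conv.params
        for conv in self.tfe_convs:
            params += conv.params
        return params

    def freeze(self) -> None:
        for p in self.parameters():
            p.trainable = False

    def unfreeze(self) -> None:
        for p in self.parameters():
            p.trainable = True

    # -- forward / backward -------------------------------------------------

    def _check_spatial(self, values: np.ndarray) -> None:
        if tuple(values.shape[1:]) != tuple(self.config.input_shape):
            raise ValueError(
                f"spatial shape {tuple(values.shape[1:])} does not match the network's "
                f"configured shape {tuple(self.config.input_shape)}; the temporal "
                "dimension is free but the spatial dimensions are not"
            )

    def sfe_forward(self, values: np.ndarray, train: bool = False, chunk: int = 8) -> np.ndarray:
        """Per-frame features: (T, D, H, W) SUV volume -> (T, 32).

        Frames are processed in chunks to bound the im2col working set;
        chunking does not change the result because SFE weights are shared
        across time and each frame is mapped independently.
        """
        self._check_spatial(values)
        T = values.shape[0]
        x = values[:, None].astype(np.float32)
        if train:
            chunk = T  # keep one cache per layer for backprop
        feats = []
        for lo in range(0, T, chunk):
            h = x[lo : lo + chunk]
            for pool, block in self.stages:
                h = block.forward(pool.forward(h, train), train)
            h = self.final_relu.forward(self.final_conv.forward(h, train), train)
            feats.append(self.gap.forward(h, train))
        return np.concatenate(feats, axis=0)

    def tfe_forward(self, feats: np.ndarray, train: bool = False) -> np.ndarray:
        """(T, 32) feature sequence -> (T,) curve."""
        h = feats.T[None]  # (1, 32, T)
        for conv, relu in zip(self.tfe_convs, self.tfe_relus):
            h = conv.forward(h, train)
            if relu is not None:
                h = relu.forward(h, train)
        return h[0, 0]

    def forward(self, values: np.ndarray, train: bool = False) -> np.ndarray:
        return self.tfe_forward(self.sfe_forward(values, train), train)

    def backward(self, dcurve: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the output curve; accumulates grads."""
        d = dcurve.astype(np.float32)[None, None]  # (1, 1, T)
        for conv, relu in zip(reversed(self.tfe_convs), reversed(self.tfe_relus)):
            if relu is not None:
                d = relu.backward(d)
            d = conv.backward(d)
        dfeats = d[0].T  # (T, 32)
        h = self.gap.backward(dfeats)
        h = self.final_conv.backward(self.final_relu.backward(h))
        # the first stage sits directly on the input image, whose gradient
        # is never needed; skipping it saves the widest col2im of the net
        for i in reversed(range(len(self.stages))):
            pool, block = self.stages[i]
            if i == 0:
                block.backward(h, need_dx=False)
            else:
                h = pool.backward(block.backward(h))

    # -- serialization ------------------------------------------------------

    def state_dict(self) -> dict:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            p.value[...] = state[p.name]

    def save(self, path) -> None:
        """Checkpoint: weights plus the embedded config, as compressed .npz."""
        import json

        arrays = {f"param/{p.name}": p.value for p in self.parameters()}
        arrays["config_json"] = np.array(json.dumps(asdict(self.config)))
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        import json

        with np.load(path, allow_pickle=False) as data:
            raw = json.loads(str(data["config_json"]))
            for key in ("sfe_channels", "final_kernel", "tfe_channels", "input_shape"):
                raw[key] = tuple(raw[key])
            net = cls(NetworkConfig(**raw))
            for p in net.parameters():
                p.value[...] = data[f"param/{p.name}"]
        return net

    def describe(self) -> list[tuple[str, str, int]]:
        """Per-parameter (name, shape, size) rows for the `describe` command."""
        return [(p.name, str(tuple(p.value.shape)), p.size) for p in self.parameters()]


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> Network:
    """Instantiate the predictor; the config defaults to the shipped 90 124-parameter one."""
    return Network(config if config is not None else NetworkConfig(), seed=seed)


def count_parameters(network: Network, trainable_only: bool = True) -> int:
    """Total number of (trainable) weights and biases."""
    return sum(p.size for p in network.parameters() if p.trainable or not trainable_only)


def extract_features(network: Network, image: DynamicPETImage) -> np.ndarray:
    """Per-frame SFE feature matrix of shape (T, 32); row t depends only on frame t."""
    return network.sfe_forward(np.asarray(image.values, dtype=np.float32))


def predict_aif(network: Network, image: DynamicPETImage) -> BloodCurve:
    """Predict the input function; times are the schedule's frame midpoints."""
    curve = network.forward(np.asarray(image.values, dtype=np.float32))
    values = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(values)):
        raise FloatingPointError("network produced non-finite values")
    return BloodCurve(times=image.schedule.midpoints, values=values, kind="whole-blood")
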