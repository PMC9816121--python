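"""The embedding-predicting 2D U-Net.

The network maps a stack of five adjacent axial slices (channels) to two
scalar fields on the center slice: the level-set embeddings of the endosteal
and periosteal surfaces.  The sign of each field encodes inside/outside of
the embedded surface and the magnitude encodes distance to it; segmentations
are recovered by thresholding the fields at zero.

The architecture is the classic biomedical encoder-decoder U-Net with skip
connections, modified with 'same'-padded convolutions (so output size equals
input size), group normalization, and dropout.  Each level is a double
3x3-convolution block; downsampling is 2x2 max pooling and upsampling is a
2x2-stride-2 transposed convolution.  A final 1x1 convolution produces the
two output fields, ordered (endosteal, periosteal).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .preprocess import SliceStack


@dataclass
class UNetConfig:
    in_channels: int = 5
    out_fields: int = 2
    base_channels: int = 32
    depth: int = 4  # levels of down/upsampling
    groupnorm_groups: int = 8
    dropout_p: float = 0.1
    conv_padding: str = "same"

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels % self.groupnorm_groups:
            raise ValueError(
                f"base_channels {self.base_channels} must be divisible by "
                f"groupnorm_groups {self.groupnorm_groups}"
            )
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.conv_padding != "same":
            raise ValueError("only 'same' convolution padding is supported")


@dataclass
class EmbeddingFieldPair:
    """Predicted level-set embeddings (voxel units), endosteal and periosteal."""

    endo: np.ndarray
    peri: np.ndarray

    def __post_init__(self) -> None:
        self.endo = np.asarray(self.endo, dtype=np.float64)
        self.peri = np.asarray(self.peri, dtype=np.float64)
        if self.endo.shape != self.peri.shape:
            raise ValueError("endo and peri fields must share a shape")
        if not (np.all(np.isfinite(self.endo)) and np.all(np.isfinite(self.peri))):
            raise ValueError("embedding fields must be finite")


class _ConvBlock:
    """conv3x3 -> group norm -> ReLU -> dropout."""

    def __init__(self, c_in: int, c_out: int, groups: int, dropout_p: float, rng):
        fan_in = c_in * 9
        self.w = Tensor(
            rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.gamma = Tensor(np.ones(c_out), requires_grad=True)
        self.beta = Tensor(np.zeros(c_out), requires_grad=True)
        self.groups = groups
        self.dropout_p = dropout_p

    def __call__(self, x, train: bool, rng):
        x = ad.conv2d(x, self.w, self.b)
        x = ad.group_norm(x, self.gamma, self.beta, self.groups)
        x = ad.relu(x)
        if train and self.dropout_p > 0:
            keep = 1.0 - self.dropout_p
            mask = (rng.random(x.shape) < keep) / keep
            x = ad.mul(x, mask)
        return x

    def parameters(self):
        return [self.w, self.b, self.gamma, self.beta]


class _DoubleConv:
    def __init__(self, c_in, c_out, groups, dropout_p, rng):
        self.block1 = _ConvBlock(c_in, c_out, groups, dropout_p, rng)
        self.block2 = _ConvBlock(c_out, c_out, groups, dropout_p, rng)

    def __call__(self, x, train, rng):
        return self.block2(self.block1(x, train, rng), train, rng)

    def parameters(self):
        return self.block1.parameters() + self.block2.parameters()


class _UpConv:
    """2x2-stride-2 transposed convolution halving the channel count."""

    def __init__(self, c_in, c_out, rng):
        fan_in = c_in  # each output pixel sees one input pixel per channel
        self.w = Tensor(
            rng.standard_normal((c_in, c_out, 2, 2)) * np.sqrt(2.0 / fan_in),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ad.conv_transpose2d_2x2(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class EmbeddingUNet:
    """Encoder-decoder U-Net predicting two embedding fields per slice."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        cfg = config
        widths = [cfg.base_channels * 2**level for level in range(cfg.depth + 1)]
        self.encoder = []
        c_prev = cfg.in_channels
        for c in widths:
            self.encoder.append(
                _DoubleConv(c_prev, c, cfg.groupnorm_groups, cfg.dropout_p, rng)
            )
            c_prev = c
        self.upconvs = []
        self.decoder = []
        for c in reversed(widths[:-1]):
            self.upconvs.append(_UpConv(2 * c, c, rng))
            self.decoder.append(
                _DoubleConv(2 * c, c, cfg.groupnorm_groups, cfg.dropout_p, rng)
            )
        fan_in = cfg.base_channels
        self.head_w = Tensor(
            rng.standard_normal((cfg.out_fields, cfg.base_channels, 1, 1))
            * np.sqrt(1.0 / fan_in),
            requires_grad=True,
        )
        self.head_b = Tensor(np.zeros(cfg.out_fields), requires_grad=True)

    # -- parameters ------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for block in self.encoder + self.decoder:
            params.extend(block.parameters())
        for up in self.upconvs:
            params.extend(up.parameters())
        params.extend([self.head_w, self.head_b])
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- forward ---------------------------------------------------------
    def forward_batch(self, x, train: bool = False, rng=None):
        """Forward an (N, in_channels, H, W) batch; returns (N, 2, H, W).

        In evaluation mode (``train=False``) dropout is off and the output is
        deterministic given the weights.
        """
        xd = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        h, w = xd.shape[2:]
        stride = 2**self.config.depth
        if h % stride or w % stride:
            raise ValueError(
                f"in-plane dims {h}x{w} must be divisible by 2^depth = {stride}"
            )
        if train and rng is None:
            rng = np.random.default_rng()
        skips = []
        for i, block in enumerate(self.encoder):
            if i > 0:
                x = ad.max_pool2d_2x2(x)
            x = block(x, train, rng)
            skips.append(x)
        for up, block, skip in zip(self.upconvs, self.decoder, reversed(skips[:-1])):
            x = up(x)
            x = ad.concat([skip, x], axis=1)
            x = block(x, train, rng)
        return ad.conv2d(x, self.head_w, self.head_b)

    # -- checkpointing ---------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint holds {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"param_{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for param_{i}")
            p.data = arr

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, config=json.dumps(asdict(self.config)), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingUNet":
        with np.load(path, allow_pickle=False) as data:
            config = UNetConfig(**json.loads(str(data["config"])))
            model = cls(config)
            model.load_state_dict(
                {k: data[k] for k in data.files if k.startswith("param_")}
            )
        return model


def build_model(config: UNetConfig | None = None, seed: int = 0) -> EmbeddingUNet:
    """Construct an embedding-predicting U-Net from a configuration."""
    return EmbeddingUNet(config or UNetConfig(), seed=seed)


def forward(model: EmbeddingUNet, stack: SliceStack) -> EmbeddingFieldPair:
    """Predict the (endosteal, periosteal) embedding pair for one slice stack."""
    out = model.forward_batch(stack.slices[None, ...], train=False)
    fields = out.data if isinstance(out, Tensor) else out
    return EmbeddingFieldPair(endo=fields[0, 0], peri=fields[0, 1])
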