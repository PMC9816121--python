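"""Training protocol: shuffling, batching, AdamW, one-cycle scheduling.

Each epoch shuffles the training images, then for each image shuffles its
axial slices and consumes them sequentially in batches of 4 slice stacks
(a full 168-slice scan yields 42 batches).  Optimization uses AdamW
(decoupled weight decay) under the super-convergence one-cycle policy:
the learning rate rises linearly from 1e-4 to 1e-3 over a 10-epoch
half-cycle, falls back over the second half-cycle, then anneals to
lr_min / 25 over 5 convergence epochs, while the first-moment momentum
moves inversely between 0.95 and 0.85.  One inferential pass over the
validation set closes every epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .losses import LossBreakdown, LossWeights, total_loss_fields
from .preprocess import make_slice_stack
from .unet import EmbeddingUNet
from .volume import NormalizedVolume, SegmentationPair

#: Final-annealing divisor of the one-cycle convergence phase.
FINAL_LR_DIVISOR = 25.0


@dataclass
class TrainingConfig:
    epochs_halfcycle: int = 10
    epochs_converge: int = 5
    lr_min: float = 1e-4
    lr_max: float = 1e-3
    momentum_max: float = 0.95
    momentum_min: float = 0.85
    batch_size_slices: int = 4
    weight_decay: float = 1e-2  # AdamW default
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if not 0 < self.momentum_min < self.momentum_max < 1:
            raise ValueError("need 0 < momentum_min < momentum_max < 1")
        if self.batch_size_slices < 1:
            raise ValueError("batch_size_slices must be >= 1")

    @property
    def total_epochs(self) -> int:
        return 2 * self.epochs_halfcycle + self.epochs_converge


@dataclass
class TrainingHistory:
    lrs: list[float] = field(default_factory=list)
    momentums: list[float] = field(default_factory=list)
    train_loss: list[LossBreakdown] = field(default_factory=list)
    val_loss: list[LossBreakdown] = field(default_factory=list)


def one_cycle_schedule(
    cfg: TrainingConfig, iteration: int, total_iterations: int
) -> tuple[float, float]:
    """Learning rate and momentum at a given iteration of the one-cycle policy."""
    if not 0 <= iteration < total_iterations:
        raise ValueError(f"iteration {iteration} out of range [0, {total_iterations})")
    t = iteration / total_iterations  # position in [0, 1)
    f_half = cfg.epochs_halfcycle / cfg.total_epochs
    if t < f_half:  # warm-up half-cycle
        u = t / f_half
        lr = cfg.lr_min + (cfg.lr_max - cfg.lr_min) * u
        mom = cfg.momentum_max - (cfg.momentum_max - cfg.momentum_min) * u
    elif t < 2 * f_half:  # cool-down half-cycle
        u = (t - f_half) / f_half
        lr = cfg.lr_max - (cfg.lr_max - cfg.lr_min) * u
        mom = cfg.momentum_min + (cfg.momentum_max - cfg.momentum_min) * u
    else:  # convergence epochs: anneal toward lr_min / 25
        u = (t - 2 * f_half) / max(1.0 - 2 * f_half, 1e-12)
        lr = cfg.lr_min + (cfg.lr_min / FINAL_LR_DIVISOR - cfg.lr_min) * u
        mom = cfg.momentum_max
    return lr, mom


@dataclass
class Batch:
    """A batch of slice stacks and their reference slice masks."""

    stacks: np.ndarray  # (N, 5, H, W)
    cortical: np.ndarray  # (N, H, W) bool
    trabecular: np.ndarray  # (N, H, W) bool


def _batch_from_indices(
    nv: NormalizedVolume, seg: SegmentationPair, indices: list[int]
) -> Batch:
    stacks = np.stack([make_slice_stack(nv, i).slices for i in indices])
    cort = np.stack([seg.cortical.voxels[i] for i in indices])
    trab = np.stack([seg.trabecular.voxels[i] for i in indices])
    return Batch(stacks, cort, trab)


def iterate_batches(
    dataset: list[tuple[NormalizedVolume, SegmentationPair]],
    cfg: TrainingConfig,
    epoch_seed: int,
):
    """Yield shuffled batches: images shuffled, slices shuffled within image.

    Batches of ``cfg.batch_size_slices`` stacks are drawn from one image at a
    time; a trailing partial batch is kept.
    """
    if not dataset:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(epoch_seed)
    order = rng.permutation(len(dataset))
    b = cfg.batch_size_slices
    for image_idx in order:
        nv, seg = dataset[image_idx]
        slice_order = rng.permutation(nv.n_slices)
        for start in range(0, len(slice_order), b):
            indices = [int(i) for i in slice_order[start : start + b]]
            yield _batch_from_indices(nv, seg, indices)


def n_batches_per_image(n_slices: int, batch_size: int = 4) -> int:
    return math.ceil(n_slices / batch_size)


class AdamW:
    """Decoupled-weight-decay Adam with externally scheduled lr and beta1."""

    def __init__(self, params: list[Tensor], cfg: TrainingConfig):
        self.params = params
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float, beta1: float) -> None:
        cfg = self.cfg
        self.t += 1
        b2, eps = cfg.beta2, cfg.adam_eps
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            p.data *= 1.0 - lr * cfg.weight_decay  # decoupled decay
            self.m[i] = beta1 * self.m[i] + (1.0 - beta1) * g
            self.v[i] = b2 * self.v[i] + (1.0 - b2) * g * g
            m_hat = self.m[i] / (1.0 - beta1**self.t)
            v_hat = self.v[i] / (1.0 - b2**self.t)
            p.data -= lr * m_hat / (np.sqrt(v_hat) + eps)


def _mean_breakdown(parts: list[LossBreakdown]) -> LossBreakdown:
    names = ("l_ce", "l_kappa_endo", "l_kappa_peri", "l_grad_endo", "l_grad_peri", "l_total")
    return LossBreakdown(
        *(float(np.mean([getattr(p, name) for p in parts])) for name in names)
    )


def validate(
    model: EmbeddingUNet,
    val_set: list[tuple[NormalizedVolume, SegmentationPair]],
    loss_weights: LossWeights | None = None,
    batch_size: int = 4,
) -> LossBreakdown:
    """Mean loss breakdown over every slice of the validation set (eval mode)."""
    loss_weights = loss_weights or LossWeights()
    parts: list[LossBreakdown] = []
    for nv, seg in val_set:
        for start in range(0, nv.n_slices, batch_size):
            indices = list(range(start, min(start + batch_size, nv.n_slices)))
            batch = _batch_from_indices(nv, seg, indices)
            out = model.forward_batch(batch.stacks, train=False)
            out_data = out.data if isinstance(out, Tensor) else out
            bd = total_loss_fields(
                out_data[:, 0], out_data[:, 1], batch.cortical, batch.trabecular, loss_weights
            )
            parts.append(bd.as_floats())
    return _mean_breakdown(parts)


def fit(
    model: EmbeddingUNet,
    train_set: list[tuple[NormalizedVolume, SegmentationPair]],
    val_set: list[tuple[NormalizedVolume, SegmentationPair]],
    cfg: TrainingConfig | None = None,
    loss_weights: LossWeights | None = None,
    log_fn=None,
) -> tuple[EmbeddingUNet, TrainingHistory]:
    """Train the model under the full shuffled-batch one-cycle protocol.

    Fully seeded: two runs with the same config and data on one device
    produce identical histories.  Aborts with a diagnostic on a non-finite
    loss.
    """
    if not train_set:
        raise ValueError("empty training set")
    cfg = cfg or TrainingConfig()
    loss_weights = loss_weights or LossWeights()
    master_rng = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(master_rng.integers(2**31))
    epoch_seeds = master_rng.integers(2**31, size=cfg.total_epochs)

    iters_per_epoch = sum(
        n_batches_per_image(nv.n_slices, cfg.batch_size_slices) for nv, _ in train_set
    )
    total_iterations = cfg.total_epochs * iters_per_epoch
    optimizer = AdamW(model.parameters(), cfg)
    history = TrainingHistory()
    iteration = 0
    for epoch in range(cfg.total_epochs):
        epoch_parts: list[LossBreakdown] = []
        for batch in iterate_batches(train_set, cfg, int(epoch_seeds[epoch])):
            out = model.forward_batch(batch.stacks, train=True, rng=dropout_rng)
            bd = total_loss_fields(
                out[:, 0], out[:, 1], batch.cortical, batch.trabecular, loss_weights
            )
            loss_value = float(bd.l_total.data)
            if not np.isfinite(loss_value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, iteration "
                    f"{iteration}: {bd.as_floats()}"
                )
            model.zero_grad()
            bd.l_total.backward()
            lr, momentum = one_cycle_schedule(cfg, iteration, total_iterations)
            optimizer.step(lr, momentum)
            history.lrs.append(lr)
            history.momentums.append(momentum)
            epoch_parts.append(bd.as_floats())
            iteration += 1
        history.train_loss.append(_mean_breakdown(epoch_parts))
        history.val_loss.append(validate(model, val_set, loss_weights, cfg.batch_size_slices))
        if log_fn is not None:
            log_fn(epoch, history.train_loss[-1], history.val_loss[-1])
    return model, history
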