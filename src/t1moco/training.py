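"""Training-data synthesis, pre-processing and the supervised training loop.

Training pairs are built from motion-free stacks: draw 7 random smooth
fields, remove their per-pixel frame-mean (relative motion only), deform
the frames with them, and use the mean-removed numerical inverses of the
applied fields as regression targets. By default fresh deformations are
drawn every epoch (``fixed_pairs=False`` re-creates the static alternative).

Pre-processing: per-stack quantile normalisation (all 7 frames pooled, so
the inversion-recovery contrast ordering survives) *then* centred
zero-padding, so the padded border is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dvf as dvfmod
from . import moconet
from .errors import ContractError, TrainingError
from .phantom import IRWStack

__all__ = [
    "TrainConfig",
    "TrainingPair",
    "EarlyStopper",
    "quantile_normalize",
    "pad_to_size",
    "crop_from_pad",
    "make_training_pair",
    "preprocess_stack",
    "train",
]


@dataclass
class TrainConfig:
    lr_init: float = 1e-3
    batch_size: int = 4
    patience_epochs: int = 50
    val_fraction: float = 0.10
    pad_size: tuple[int, int] = (64, 64)  # paper-scale runs use (384, 384)
    max_epochs: int = 1000
    amplitude_px: float = 3.0
    smoothness_px: float = 8.0
    sched_factor: float = 0.5
    sched_patience: int = 10
    min_lr: float = 1e-5
    min_delta: float = 1e-6  # strict-improvement tolerance for plateaus
    q_low: float = 0.01
    q_high: float = 0.99
    fixed_pairs: bool = False
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ContractError(f"val_fraction must be in (0, 1), got {self.val_fraction}")
        if self.batch_size < 1 or self.max_epochs < 1 or self.patience_epochs < 1:
            raise ContractError("batch_size, max_epochs and patience_epochs must be >= 1")

    def validate_for(self, config: moconet.NetworkConfig):
        d = config.divisor
        if self.pad_size[0] % d or self.pad_size[1] % d:
            raise ContractError(
                f"pad_size {self.pad_size} must be divisible by 2^n_scales = {d}"
            )


@dataclass(frozen=True)
class TrainingPair:
    """A synthetically deformed stack with its inverse-field targets."""

    deformed_stack: IRWStack
    gt_inverse: dvfmod.DVFSet
    provenance: dict = field(default_factory=dict)


def quantile_normalize(image: np.ndarray, q_low: float = 0.01, q_high: float = 0.99) -> np.ndarray:
    """Clip at the empirical [q_low, q_high] quantiles, map affinely to [0, 1].

    Degenerate (constant) inputs map to all-zeros. Idempotent up to the
    clipped tail mass.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ContractError("image must be finite")
    if not (0.0 <= q_low < q_high <= 1.0):
        raise ContractError(f"need 0 <= q_low < q_high <= 1, got ({q_low}, {q_high})")
    lo = float(np.quantile(image, q_low))
    hi = float(np.quantile(image, q_high))
    if hi <= lo:
        return np.zeros_like(image)
    return (np.clip(image, lo, hi) - lo) / (hi - lo)


def pad_to_size(image_or_stack: np.ndarray, pad_size: tuple[int, int]):
    """Zero-pad the trailing two dimensions to ``pad_size``, centred.

    Odd leftovers go to the bottom/right. Returns ``(padded, offsets)``
    where ``offsets = (row0, col0)`` locates the original data for
    :func:`crop_from_pad`. Inputs larger than ``pad_size`` are rejected —
    this operation never crops.
    """
    arr = np.asarray(image_or_stack)
    H, W = arr.shape[-2:]
    PH, PW = pad_size
    if H > PH or W > PW:
        raise ContractError(f"input {H}x{W} exceeds pad size {PH}x{PW}")
    r0 = (PH - H) // 2
    c0 = (PW - W) // 2
    pad = [(0, 0)] * (arr.ndim - 2) + [(r0, PH - H - r0), (c0, PW - W - c0)]
    return np.pad(arr, pad), (r0, c0)


def crop_from_pad(padded: np.ndarray, offsets: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    r0, c0 = offsets
    H, W = shape
    return np.asarray(padded)[..., r0:r0 + H, c0:c0 + W]


def preprocess_stack(stack: IRWStack, cfg: TrainConfig):
    """Quantile-normalise (frames pooled) then pad; returns the padded
    (7, PH, PW) float array and the crop offsets."""
    norm = quantile_normalize(stack.images, cfg.q_low, cfg.q_high)
    return pad_to_size(norm, cfg.pad_size)


def make_training_pair(
    clean_stack: IRWStack,
    amplitude_px: float,
    smoothness_px: float,
    seed=None,
) -> TrainingPair:
    """Deform a clean stack with 7 mean-removed random fields.

    Targets are the frame-wise numerical inverses of the applied fields
    (*not* their negations, which would be wrong for non-rigid motion). The
    inverses are used as-is: re-removing their frame mean would break the
    defining property ``compose(applied, target) = 0`` and hence the
    round-trip recovery of the clean frames. The inverses of a mean-removed
    set are near-mean-free anyway (residual is second order in the
    displacement), so the zero-mean gauge is preserved to a fraction of a
    pixel. Warping each deformed frame by its target recovers the clean
    frame to interpolation tolerance on interior pixels.
    """
    rng = np.random.default_rng(seed)
    shape = clean_stack.frame_shape
    applied = dvfmod.DVFSet(
        tuple(
            dvfmod.generate_random_dvf(shape, amplitude_px, smoothness_px, seed=rng)
            for _ in range(7)
        )
    )
    applied = dvfmod.remove_mean_displacement(applied)
    deformed = np.stack(
        [dvfmod.warp(frame, f, fill_value=0.0) for frame, f in zip(clean_stack.images, applied)]
    )
    gt_inverse = dvfmod.DVFSet(
        tuple(dvfmod.invert(f, tol_px=0.005, max_iter=200) for f in applied)
    )
    stack = clean_stack.copy_with(
        images=np.clip(deformed, 0.0, None),
        deformation={"amplitude_px": float(amplitude_px), "smoothness_px": float(smoothness_px)},
        applied_dvfs=applied.as_array(),
    )
    return TrainingPair(
        deformed_stack=stack,
        gt_inverse=gt_inverse,
        provenance={"source": clean_stack.meta.get("seed"), "seed": seed,
                    "amplitude_px": float(amplitude_px)},
    )


class EarlyStopper:
    """Stop when the monitored loss has not improved by ``min_delta`` for
    ``patience`` consecutive epochs."""

    def __init__(self, patience: int, min_delta: float = 1e-6):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record an epoch's validation loss; returns True when training
        should stop (this epoch is the ``patience``-th without improvement)."""
        if value < self.best - self.min_delta:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _pair_tensors(pair: TrainingPair, cfg: TrainConfig):
    """Preprocessed input tensor and padded target tensor for one pair."""
    x, offsets = preprocess_stack(pair.deformed_stack, cfg)
    gt = moconet.dvfset_to_tensor(pair.gt_inverse)  # (14, H, W)
    gt_padded, _ = pad_to_size(gt, cfg.pad_size)
    return x.astype(np.float32), gt_padded.astype(np.float32), offsets


def _generate_pairs(stacks, cfg: TrainConfig, rng: np.random.Generator):
    pairs = []
    for stack in stacks:
        amp = rng.uniform(0.0, cfg.amplitude_px)
        pairs.append(
            make_training_pair(stack, amp, cfg.smoothness_px, seed=rng.integers(2**31))
        )
    return pairs


def train(model: moconet.RegistrationModel, clean_stacks, train_config: TrainConfig):
    """Supervised training with Adam, reduce-on-plateau scheduling and
    early stopping on the validation multi-scale loss.

    Returns ``(model, history)``; the model is left at the best-validation
    weights. ``history`` has per-epoch ``train_loss``, ``val_loss`` and
    ``lr`` lists plus the stopping epoch.
    """
    clean_stacks = list(clean_stacks)
    if len(clean_stacks) == 0:
        raise ContractError("no training stacks provided")
    if len(clean_stacks) < 10:
        raise ContractError(f"need at least 10 clean stacks, got {len(clean_stacks)}")
    cfg = train_config
    cfg.validate_for(model.config)

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(clean_stacks))
    n_val = max(1, int(round(cfg.val_fraction * len(clean_stacks))))
    val_stacks = [clean_stacks[i] for i in order[:n_val]]
    trn_stacks = [clean_stacks[i] for i in order[n_val:]]

    # fixed validation pairs -> comparable losses across epochs
    val_rng = np.random.default_rng(rng.integers(2**31))
    val_pairs = _generate_pairs(val_stacks, cfg, val_rng)
    val_data = [_pair_tensors(p, cfg)[:2] for p in val_pairs]

    pair_rng = np.random.default_rng(rng.integers(2**31))
    fixed = _generate_pairs(trn_stacks, cfg, pair_rng) if cfg.fixed_pairs else None

    opt = _make_optimizer(model, cfg)
    sched = _make_scheduler(opt, cfg)
    stopper = EarlyStopper(cfg.patience_epochs, cfg.min_delta)
    history = {"train_loss": [], "val_loss": [], "lr": [], "stopped_epoch": None, "best_epoch": None}
    best_state = None

    for epoch in range(1, cfg.max_epochs + 1):
        pairs = fixed if cfg.fixed_pairs else _generate_pairs(trn_stacks, cfg, pair_rng)
        data = [_pair_tensors(p, cfg)[:2] for p in pairs]
        idx = rng.permutation(len(data))
        epoch_losses = []
        for start in range(0, len(idx), cfg.batch_size):
            batch = [data[i] for i in idx[start:start + cfg.batch_size]]
            x = np.stack([b[0] for b in batch])
            gt = np.stack([b[1] for b in batch])
            preds = model.forward_batch(x, train=True)
            loss, grads = moconet.multiscale_loss_grads(preds, gt)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward_batch(grads)
            opt.step()
            epoch_losses.append(loss)

        val_loss = _evaluate(model, val_data, cfg.batch_size)
        if not np.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(float(val_loss))
        history["lr"].append(float(opt.lr))

        if val_loss < stopper.best - stopper.min_delta:
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        stop = stopper.update(val_loss, epoch)
        sched.step(val_loss)
        if stop:
            history["stopped_epoch"] = epoch
            break

    history["best_epoch"] = stopper.best_epoch
    if history["stopped_epoch"] is None:
        history["stopped_epoch"] = len(history["val_loss"])
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def _make_optimizer(model, cfg: TrainConfig):
    from . import nn

    return nn.Adam(model.parameters(), lr=cfg.lr_init)


def _make_scheduler(opt, cfg: TrainConfig):
    from . import nn

    return nn.ReduceLROnPlateau(
        opt, factor=cfg.sched_factor, patience=cfg.sched_patience,
        min_lr=cfg.min_lr, min_delta=cfg.min_delta,
    )


def _evaluate(model, data, batch_size: int) -> float:
    losses = []
    for start in range(0, len(data), batch_size):
        batch = data[start:start + batch_size]
        x = np.stack([b[0] for b in batch])
        gt = np.stack([b[1] for b in batch])
        preds = model.forward_batch(x, train=False)
        loss, _ = moconet.multiscale_loss_grads(preds, gt)
        losses.append((loss, len(batch)))
    total = sum(l * n for l, n in losses)
    n = sum(n for _, n in losses)
    return total / n
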