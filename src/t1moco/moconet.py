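"""Groupwise multi-scale registration network.

An encoder-decoder over the 7-frame stack. The shared-weight encoder runs
per frame (each frame is a channel of the input stack) through repeated
[3x3 conv -> batch norm -> leaky ReLU] pairs with 2x2 max pooling between
levels. The decoder starts at the coarsest level and refines coarse-to-fine:
at each scale a convolution module consumes (i) the features transposed-
convolved up from the previous step, (ii) the up-sampled displacement
estimate from the coarser scale, and (iii) the encoder features of this
scale warped frame-wise by that estimate; a zero-initialised 1x1 head emits
a residual update, so the untrained network predicts the identity
deformation. The finest output is the full-resolution set of 7 inverse
displacement fields; every intermediate scale's output is kept for the
multi-scale loss.

No frame is designated as a reference — the zero-frame-mean gauge of the
training targets is what pins the solution.
"""

from __future__ import annotations


import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .dvf import DVFSet
from .errors import ConfigurationError, ContractError
from .phantom import IRWStack

__all__ = [
    "NetworkConfig",
    "RegistrationModel",
    "build_network",
    "predict_dvfs",
    "multiscale_loss",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT = "t1moco-checkpoint-v1"


@dataclass(frozen=True)
class NetworkConfig:
    n_scales: int = 4
    base_channels: int = 16
    kernel_size: int = 3
    leaky_slope: float = 0.1
    in_frames: int = 7
    out_channels_per_frame: int = 2

    def __post_init__(self):
        if self.n_scales < 2:
            raise ConfigurationError(f"n_scales must be >= 2, got {self.n_scales}")
        if self.kernel_size != 3:
            raise ConfigurationError(f"kernel_size is fixed at 3, got {self.kernel_size}")
        if self.in_frames != 7:
            raise ConfigurationError(f"in_frames is fixed at 7, got {self.in_frames}")
        if self.base_channels < 1 or self.out_channels_per_frame != 2:
            raise ConfigurationError("base_channels >= 1 and out_channels_per_frame == 2 required")

    @property
    def divisor(self) -> int:
        """Input spatial dimensions must be divisible by this."""
        return 2**self.n_scales


class _ConvBlock:
    """[conv3x3 -> BN -> leaky ReLU] x 2."""

    def __init__(self, cin: int, cout: int, slope: float, rng: np.random.Generator):
        self.layers = [
            nn.Conv2d(cin, cout, 3, rng=rng),
            nn.BatchNorm2d(cout),
            nn.LeakyReLU(slope),
            nn.Conv2d(cout, cout, 3, rng=rng),
            nn.BatchNorm2d(cout),
            nn.LeakyReLU(slope),
        ]

    def forward(self, x, train):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, gy):
        for lyr in reversed(self.layers):
            gy = lyr.backward(gy)
        return gy

    def sublayers(self):
        return self.layers


class RegistrationModel:
    """See module docstring. Build with :func:`build_network`."""

    def __init__(self, config: NetworkConfig, seed=None):
        self.config = config
        rng = np.random.default_rng(seed)
        S = config.n_scales
        slope = config.leaky_slope
        c = [config.base_channels * 2**l for l in range(S)]
        self._c = c
        self.enc_blocks = []
        self.pools = [nn.MaxPool2() for _ in range(S - 1)]
        for l in range(S):
            cin = 1 if l == 0 else c[l - 1]
            self.enc_blocks.append(_ConvBlock(cin, c[l], slope, rng))
        self.dec_blocks: list = [None] * S
        self.heads: list = [None] * S
        self.upconvs: list = [None] * S  # upconvs[s] lifts scale s+1 -> s
        out_ch = config.in_frames * config.out_channels_per_frame
        for s in range(S - 1, -1, -1):
            if s == S - 1:
                cin = 7 * c[s]
            else:
                cin = c[s] + 7 * c[s] + out_ch
                self.upconvs[s] = nn.ConvTranspose2(c[s + 1], c[s], rng=rng)
            self.dec_blocks[s] = _ConvBlock(cin, c[s], slope, rng)
            self.heads[s] = nn.Conv2d(c[s], out_ch, 1, zero_init=True)
        self._tape = None

    # -- parameter bookkeeping ------------------------------------------------

    def _all_layers(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(blk.sublayers())
        S = self.config.n_scales
        for s in range(S - 1, -1, -1):
            if self.upconvs[s] is not None:
                out.append(self.upconvs[s])
            out.extend(self.dec_blocks[s].sublayers())
            out.append(self.heads[s])
        return out

    def parameters(self) -> list[nn.Param]:
        return [p for lyr in self._all_layers() for p in lyr.params()]

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"param_{i:04d}"] = p.value
        j = 0
        for lyr in self._all_layers():
            for name, buf in lyr.buffers().items():
                state[f"buffer_{j:04d}_{name}"] = buf
                j += 1
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]):
        for i, p in enumerate(self.parameters()):
            arr = np.asarray(state[f"param_{i:04d}"], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ContractError(
                    f"checkpoint parameter {i} has shape {arr.shape}, expected {p.value.shape}"
                )
            p.value = arr.copy()
        j = 0
        for lyr in self._all_layers():
            bufs = lyr.buffers()
            if bufs:
                loaded = {name: np.asarray(state[f"buffer_{j + k:04d}_{name}"])
                          for k, name in enumerate(bufs)}
                lyr.load_buffers(loaded)
                j += len(bufs)

    def parameter_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))

    # -- forward / backward ---------------------------------------------------

    def _check_input(self, x: np.ndarray):
        S = self.config.n_scales
        if x.ndim != 4 or x.shape[1] != 7:
            raise ContractError(f"expected input of shape (B, 7, H, W), got {x.shape}")
        H, W = x.shape[2:]
        d = self.config.divisor
        if H % d or W % d:
            raise ContractError(
                f"spatial size {H}x{W} must be divisible by 2^{S} = {d}; pad the input first"
            )
        if not np.all(np.isfinite(x)):
            raise ContractError("input stack contains non-finite values")

    def forward_batch(self, x: np.ndarray, train: bool = False) -> list[np.ndarray]:
        """Run the network on ``x`` (B, 7, H, W).

        Returns per-scale displacement tensors, **coarse to fine**, each of
        shape (B, 14, h_s, w_s) with channel layout (frame, component).
        In training mode a tape is retained for :meth:`backward_batch`.
        """
        self._check_input(x)
        cfg = self.config
        S = cfg.n_scales
        B = x.shape[0]
        f = np.ascontiguousarray(x.reshape(B * 7, 1, *x.shape[2:]), dtype=np.float32)
        feats = []
        for l in range(S):
            if l > 0:
                f = self.pools[l - 1].forward(f, train)
            f = self.enc_blocks[l].forward(f, train)
            feats.append(f)

        warp_caches: list = [None] * S
        preds: list = [None] * S  # index by scale s (0 = finest)
        s = S - 1
        h, w = feats[s].shape[2:]
        X = feats[s].reshape(B, 7 * self._c[s], h, w)
        F = self.dec_blocks[s].forward(X, train)
        d = self.heads[s].forward(F, train)
        preds[s] = d
        for s in range(S - 2, -1, -1):
            up_d = nn.upsample2_forward(d)
            h, w = up_d.shape[2:]
            flows = up_d.reshape(B * 7, 2, h, w)
            warped, warp_caches[s] = nn.warp_features_forward(feats[s], flows)
            up_f = self.upconvs[s].forward(F, train)
            X = np.concatenate(
                [up_f, warped.reshape(B, 7 * self._c[s], h, w), up_d], axis=1
            )
            F = self.dec_blocks[s].forward(X, train)
            delta = self.heads[s].forward(F, train)
            d = up_d + delta
            preds[s] = d
        if train:
            self._tape = {"B": B, "warp_caches": warp_caches, "feat_shapes": [f.shape for f in feats]}
        return [preds[s] for s in range(S - 1, -1, -1)]

    def backward_batch(self, grads_coarse_to_fine: list[np.ndarray]):
        """Backpropagate per-scale loss gradients recorded by the last
        training-mode :meth:`forward_batch`."""
        if self._tape is None:
            raise ContractError("backward_batch requires a preceding training-mode forward_batch")
        cfg = self.config
        S = cfg.n_scales
        B = self._tape["B"]
        warp_caches = self._tape["warp_caches"]
        gpreds = [np.asarray(grads_coarse_to_fine[S - 1 - s], dtype=np.float32) for s in range(S)]

        genc = [np.zeros(shape, dtype=np.float32) for shape in self._tape["feat_shapes"]]
        g_d_finer = 0.0
        gF_carry = 0.0
        for s in range(S - 1):
            g_d = gpreds[s] + g_d_finer
            gF = self.heads[s].backward(g_d)
            if s > 0:
                gF = gF + gF_carry
            gX = self.dec_blocks[s].backward(gF)
            cs = self._c[s]
            g_up_f = gX[:, :cs]
            g_warped = gX[:, cs:cs + 7 * cs]
            g_up_d = g_d + gX[:, cs + 7 * cs:]
            h, w = g_warped.shape[2:]
            genc[s] += nn.warp_features_backward(
                np.ascontiguousarray(g_warped).reshape(B * 7, cs, h, w), warp_caches[s]
            )
            gF_carry = self.upconvs[s].backward(np.ascontiguousarray(g_up_f))
            g_d_finer = nn.upsample2_backward(g_up_d)

        s = S - 1
        g_d = gpreds[s] + g_d_finer
        gF = self.heads[s].backward(g_d)
        if S > 1:
            gF = gF + gF_carry
        gX = self.dec_blocks[s].backward(gF)
        h, w = gX.shape[2:]
        genc[s] += gX.reshape(B * 7, self._c[s], h, w)

        gA = genc[S - 1]
        for l in range(S - 1, 0, -1):
            gin = self.enc_blocks[l].backward(gA)
            gA = genc[l - 1] + self.pools[l - 1].backward(gin)
        self.enc_blocks[0].backward(gA)
        self._tape = None

    def forward(self, x: np.ndarray) -> list[DVFSet]:
        """Inference on one stack array (7, H, W): per-scale DVF sets,
        coarse to fine."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3:
            raise ContractError(f"expected a single (7, H, W) stack, got shape {x.shape}")
        preds = self.forward_batch(x[None], train=False)
        return [_tensor_to_dvfset(p[0]) for p in preds]


def _tensor_to_dvfset(d: np.ndarray) -> DVFSet:
    """(14, h, w) channel-major tensor -> DVFSet of 7 (h, w, 2) fields."""
    h, w = d.shape[1:]
    arr = d.reshape(7, 2, h, w).transpose(0, 2, 3, 1).astype(np.float64)
    return DVFSet.from_array(arr)


def dvfset_to_tensor(ds: DVFSet | np.ndarray) -> np.ndarray:
    """DVFSet (or (7, H, W, 2) array) -> (14, H, W) float32 tensor."""
    arr = ds.as_array() if isinstance(ds, DVFSet) else np.asarray(ds, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[0] != 7 or arr.shape[-1] != 2:
        raise ContractError(f"expected (7, H, W, 2) fields, got {arr.shape}")
    return arr.transpose(0, 3, 1, 2).reshape(14, *arr.shape[1:3]).astype(np.float32)


def build_network(config: NetworkConfig | None = None, seed=None) -> RegistrationModel:
    """Construct a registration model with seed-deterministic initialisation."""
    return RegistrationModel(config or NetworkConfig(), seed=seed)


def predict_dvfs(model: RegistrationModel, irw_stack: IRWStack | np.ndarray) -> DVFSet:
    """Full-resolution inverse fields for a (normalised, padded) stack."""
    x = irw_stack.images if isinstance(irw_stack, IRWStack) else np.asarray(irw_stack)
    return model.forward(x)[-1]


# ---------------------------------------------------------------------------
# multi-scale loss
# ---------------------------------------------------------------------------

def resample_gt_to_scale(gt: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool a (..., H, W) displacement tensor by ``factor`` and
    divide the displacement values by it, so each scale's field stays in
    units of its own grid's pixels."""
    if factor == 1:
        return gt
    *lead, H, W = gt.shape
    g = gt.reshape(*lead, H // factor, factor, W // factor, factor).mean(axis=(-3, -1))
    return g / factor


def _loss_tensor(obj) -> np.ndarray:
    """DVFSet or (F, H, W, 2) array -> (F*2, H, W) float64 tensor.

    The loss accepts any frame count so single-frame worked examples can be
    checked directly; the network itself always emits 7 frames.
    """
    arr = obj.as_array() if isinstance(obj, DVFSet) else np.asarray(obj, dtype=np.float64)
    if arr.ndim != 4 or arr.shape[-1] != 2:
        raise ContractError(f"expected (F, H, W, 2) fields, got {arr.shape}")
    F, H, W = arr.shape[:3]
    return arr.transpose(0, 3, 1, 2).reshape(F * 2, H, W).astype(np.float64)


def multiscale_loss(per_scale_predictions, gt_dvf_set) -> float:
    """Average over scales of the MSE between each scale's prediction and
    the ground truth resampled to that scale.

    ``per_scale_predictions``: DVF sets (or (F, h, w, 2) arrays) ordered
    coarse to fine, the finest at full resolution; ``gt_dvf_set``: the
    full-resolution truth. MSE is over (frames, pixels, components).
    """
    preds = [_loss_tensor(p) for p in per_scale_predictions]
    gt = _loss_tensor(gt_dvf_set)
    S = len(preds)
    if preds[-1].shape != gt.shape:
        raise ContractError(
            f"finest prediction shape {preds[-1].shape} does not match truth {gt.shape}"
        )
    total = 0.0
    for i, p in enumerate(preds):
        factor = gt.shape[-1] // p.shape[-1]
        if p.shape[-2] * factor != gt.shape[-2] or p.shape[-1] * factor != gt.shape[-1]:
            raise ContractError(f"prediction at index {i} has inconsistent scale {p.shape}")
        target = resample_gt_to_scale(gt, factor)
        total += float(((p - target) ** 2).mean())
    return total / S


def multiscale_loss_grads(preds_coarse_to_fine: list[np.ndarray], gt_batch: np.ndarray):
    """Batched training loss and its per-scale gradients.

    ``preds``: per-scale (B, 14, h, w) tensors coarse to fine;
    ``gt_batch``: (B, 14, H, W) full-resolution truth. Returns
    ``(loss, grads)`` with gradients matching the prediction shapes. The
    scalar agrees with :func:`multiscale_loss` averaged over the batch.
    """
    S = len(preds_coarse_to_fine)
    B = gt_batch.shape[0]
    loss = 0.0
    grads = []
    for p in preds_coarse_to_fine:
        factor = gt_batch.shape[-1] // p.shape[-1]
        target = resample_gt_to_scale(gt_batch, factor)
        diff = p.astype(np.float64) - target
        loss += float((diff**2).mean()) / S
        grads.append((2.0 / (S * diff.size) * diff).astype(np.float32))
    return loss, grads


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: RegistrationModel, extra: dict | None = None):
    """Single-file checkpoint: versioned header + config + weights."""
    header = {
        "format": CHECKPOINT_FORMAT,
        "config": asdict(model.config),
        "extra": extra or {},
    }
    arrays = model.state_arrays()
    np.savez_compressed(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
                        **arrays)


def load_checkpoint(path) -> RegistrationModel:
    with np.load(path) as data:
        if "__header__" not in data:
            raise ContractError(f"{path} is not a t1moco checkpoint")
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format") != CHECKPOINT_FORMAT:
            raise ContractError(f"unsupported checkpoint format {header.get('format')!r}")
        model = RegistrationModel(NetworkConfig(**header["config"]))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__header__"})
    return model
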