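"""Displacement-vector-field (DVF) algebra.

Conventions (used everywhere in this package, stated once):

* displacements are stored in **pixels** as an ``(H, W, 2)`` float array,
  components ordered ``(row, col)``;
* fields are **backward maps**: ``warped(x) = image(x + u(x))`` with bilinear
  interpolation;
* samples falling outside the image domain take a constant fill value
  (``mode="constant"``) or the nearest edge value (``mode="edge"``).

A field is certified *topology preserving* when the finite-difference
Jacobian determinant ``det(I + grad u)`` is strictly positive at every pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ContractError, GenerationError, InversionError

__all__ = [
    "DVF",
    "DVFSet",
    "generate_random_dvf",
    "remove_mean_displacement",
    "warp",
    "compose",
    "invert",
    "jacobian_determinant",
]

N_FRAMES = 7


@dataclass(frozen=True)
class DVF:
    """A dense 2-D displacement field, ``u[r, c] = (du_row, du_col)`` pixels."""

    u: np.ndarray

    def __post_init__(self):
        u = np.asarray(self.u, dtype=np.float64)
        if u.ndim != 3 or u.shape[-1] != 2:
            raise ContractError(f"DVF array must have shape (H, W, 2), got {u.shape}")
        if not np.all(np.isfinite(u)):
            raise ContractError("DVF contains non-finite displacements")
        object.__setattr__(self, "u", u)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape[:2]

    def max_displacement(self) -> float:
        """Maximum Euclidean displacement magnitude, in pixels."""
        return float(np.sqrt((self.u**2).sum(axis=-1)).max())

    def is_topology_preserving(self) -> bool:
        return bool(jacobian_determinant(self).min() > 0.0)

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DVF":
        return cls(np.zeros((*shape, 2)))


@dataclass(frozen=True)
class DVFSet:
    """One displacement field per IRW frame (always 7 of them)."""

    fields: tuple[DVF, ...]
    mean_removed: bool = False

    def __post_init__(self):
        fields = tuple(f if isinstance(f, DVF) else DVF(np.asarray(f)) for f in self.fields)
        if len(fields) != N_FRAMES:
            raise ContractError(f"DVFSet needs exactly {N_FRAMES} fields, got {len(fields)}")
        shapes = {f.shape for f in fields}
        if len(shapes) != 1:
            raise ContractError(f"DVFSet fields have mismatched shapes: {sorted(shapes)}")
        object.__setattr__(self, "fields", fields)

    @property
    def shape(self) -> tuple[int, int]:
        return self.fields[0].shape

    def as_array(self) -> np.ndarray:
        """Stack the set as a ``(7, H, W, 2)`` array."""
        return np.stack([f.u for f in self.fields])

    @classmethod
    def from_array(cls, arr: np.ndarray, mean_removed: bool = False) -> "DVFSet":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.ndim != 4 or arr.shape[0] != N_FRAMES or arr.shape[-1] != 2:
            raise ContractError(f"expected array of shape (7, H, W, 2), got {arr.shape}")
        return cls(tuple(DVF(a) for a in arr), mean_removed=mean_removed)

    def __iter__(self):
        return iter(self.fields)


def _as_u(dvf) -> np.ndarray:
    if isinstance(dvf, DVF):
        return dvf.u
    u = np.asarray(dvf, dtype=np.float64)
    if u.ndim != 3 or u.shape[-1] != 2:
        raise ContractError(f"displacement array must have shape (H, W, 2), got {u.shape}")
    return u


def bilinear_sample(
    image: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    fill_value: float = 0.0,
    mode: str = "constant",
) -> np.ndarray:
    """Sample ``image`` at fractional coordinates with bilinear weights.

    ``mode="constant"``: out-of-domain corners contribute ``fill_value``.
    ``mode="edge"``: coordinates are clamped to the image domain.

    This single primitive backs :func:`warp`, field composition/inversion and
    the network's warping layers, so the interpolation convention cannot
    drift between training and inference.
    """
    H, W = image.shape[-2:]
    if mode == "edge":
        rows = np.clip(rows, 0.0, H - 1.0)
        cols = np.clip(cols, 0.0, W - 1.0)
    r0 = np.floor(rows).astype(np.int64)
    c0 = np.floor(cols).astype(np.int64)
    dr = rows - r0
    dc = cols - c0
    out = np.zeros(image.shape[:-2] + rows.shape, dtype=np.float64)
    for (ri, ci, w) in (
        (r0, c0, (1 - dr) * (1 - dc)),
        (r0, c0 + 1, (1 - dr) * dc),
        (r0 + 1, c0, dr * (1 - dc)),
        (r0 + 1, c0 + 1, dr * dc),
    ):
        valid = (ri >= 0) & (ri < H) & (ci >= 0) & (ci < W)
        rs = np.clip(ri, 0, H - 1)
        cs = np.clip(ci, 0, W - 1)
        vals = image[..., rs, cs]
        if mode == "constant":
            vals = np.where(valid, vals, fill_value)
        out += w * vals
    return out


def _sample_coords(shape: tuple[int, int], u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    H, W = shape
    gr, gc = np.meshgrid(np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij")
    return gr + u[..., 0], gc + u[..., 1]


def warp(image: np.ndarray, dvf, fill_value: float = 0.0, mode: str = "constant") -> np.ndarray:
    """Backward-warp ``image`` by ``dvf``: ``out(x) = image(x + u(x))``.

    ``image`` may be ``(H, W)`` or a leading-dimension stack ``(..., H, W)``;
    the same field is applied to every leading slice.
    """
    image = np.asarray(image, dtype=np.float64)
    u = _as_u(dvf)
    if image.shape[-2:] != u.shape[:2]:
        raise ContractError(
            f"image shape {image.shape[-2:]} does not match field shape {u.shape[:2]}"
        )
    rows, cols = _sample_coords(u.shape[:2], u)
    return bilinear_sample(image, rows, cols, fill_value=fill_value, mode=mode)


def jacobian_determinant(dvf) -> np.ndarray:
    """Per-pixel ``det(I + grad u)`` via central finite differences."""
    u = _as_u(dvf)
    dur_dr, dur_dc = np.gradient(u[..., 0])
    duc_dr, duc_dc = np.gradient(u[..., 1])
    return (1.0 + dur_dr) * (1.0 + duc_dc) - dur_dc * duc_dr


def generate_random_dvf(
    shape: tuple[int, int],
    amplitude_px: float,
    smoothness_px: float,
    seed=None,
) -> DVF:
    """Draw a smooth random field with max displacement ``<= amplitude_px``.

    Recipe: per-component white noise, Gaussian smoothing of width
    ``smoothness_px``, rescaling so the largest displacement magnitude equals
    ``amplitude_px``. If the topology certificate (positive Jacobian
    determinant everywhere) fails, the amplitude is shrunk by 0.8 up to five
    times before giving up.
    """
    if amplitude_px < 0:
        raise ContractError(f"amplitude_px must be >= 0, got {amplitude_px}")
    if smoothness_px <= 0:
        raise ContractError(f"smoothness_px must be > 0, got {smoothness_px}")
    H, W = shape
    if amplitude_px == 0:
        return DVF.zero((H, W))
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((H, W, 2))
    u = np.stack(
        [gaussian_filter(noise[..., k], sigma=smoothness_px, mode="reflect") for k in range(2)],
        axis=-1,
    )
    mag = np.sqrt((u**2).sum(axis=-1)).max()
    if mag == 0.0:
        return DVF.zero((H, W))
    u *= amplitude_px / mag
    for _ in range(6):
        if jacobian_determinant(u).min() > 0.0:
            return DVF(u)
        u = u * 0.8
    raise GenerationError(
        f"could not certify topology preservation for amplitude={amplitude_px}, "
        f"smoothness={smoothness_px} after 5 rescaling attempts"
    )


def remove_mean_displacement(dvf_set: DVFSet) -> DVFSet:
    """Subtract the per-pixel mean over the 7 fields from every field.

    Afterwards the frame-mean displacement is zero at every pixel, so the
    set encodes only *relative* motion between frames. Idempotent.
    """
    arr = dvf_set.as_array()
    arr = arr - arr.mean(axis=0, keepdims=True)
    return DVFSet.from_array(arr, mean_removed=True)


def compose(dvf_outer, dvf_inner) -> DVF:
    """Field ``c`` with ``warp(., c) == warp(warp(., dvf_outer), dvf_inner)``.

    ``c(x) = u_inner(x) + u_outer(x + u_inner(x))``; the outer field is
    sampled with edge clamping so composition is stable near the border.
    """
    uo = _as_u(dvf_outer)
    ui = _as_u(dvf_inner)
    if uo.shape != ui.shape:
        raise ContractError(f"field shapes differ: {uo.shape} vs {ui.shape}")
    rows, cols = _sample_coords(ui.shape[:2], ui)
    sampled = np.stack(
        [bilinear_sample(uo[..., k], rows, cols, mode="edge") for k in range(2)],
        axis=-1,
    )
    return DVF(ui + sampled)


def invert(dvf, tol_px: float = 0.01, max_iter: int = 100) -> DVF:
    """Numerically invert a topology-preserving field.

    Fixed-point iteration ``v_{k+1}(x) = -u(x + v_k(x))`` starting from
    ``v_0 = 0``, stopped when the max update falls below ``tol_px``. The
    returned field satisfies ``compose(u, v) ~ 0`` on interior pixels.
    """
    u = _as_u(dvf)
    v = np.zeros_like(u)
    for _ in range(max_iter):
        rows, cols = _sample_coords(u.shape[:2], v)
        v_new = -np.stack(
            [bilinear_sample(u[..., k], rows, cols, mode="edge") for k in range(2)],
            axis=-1,
        )
        delta = np.abs(v_new - v).max()
        v = v_new
        if delta < tol_px:
            return DVF(v)
    residual = float(np.abs(compose(u, v).u).max())
    raise InversionError(
        f"field inversion did not converge within {max_iter} iterations "
        f"(last update {delta:.4g} px, composition residual {residual:.4g} px)",
        residual_px=residual,
    )
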