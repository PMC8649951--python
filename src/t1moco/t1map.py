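"""Pixel-wise inversion-recovery fitting: T1 maps, R^2 maps, motion proxy.

The reconstruction fits the 3-parameter magnitude model
``|A - B exp(-TI/T1*)|`` to the 7 samples of each pixel. Magnitude data
loses the sign of the early samples, so a small polarity search is run: for
each candidate split ``k in {0..3}`` the ``k`` earliest-TI samples are
sign-flipped and the signed model ``A - B exp(-TI/T1*)`` is fitted; the
candidate with the highest R^2 wins. R^2 = 1 - SS_res/SS_tot with SS_tot
taken about the mean of the polarity-restored (signed) samples. The
Look-Locker correction ``T1 = T1* (B/A - 1)`` is applied to the winner.

For a fixed T1* the model is linear in (A, B), so the fit is solved by
variable projection: a coarse log-spaced grid over T1* brackets the optimum
and a golden-section refinement drives it to machine tolerance. Everything
is vectorised over pixels, which keeps whole-map reconstruction at
interactive speed on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError
from .phantom import IRWStack

__all__ = [
    "T1FitResult",
    "T1Map",
    "R2Map",
    "fit_t1_pixel",
    "reconstruct_maps",
    "motion_severity_proxy",
]

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_FAILED = "failed"

T1_STAR_BOUNDS_MS = (50.0, 5000.0)
_N_GRID = 48
_MAX_POLARITY_SPLIT = 3
_GOLDEN_ITERS = 60
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class T1FitResult:
    """Outcome of a single-pixel 3-parameter fit."""

    t1_ms: float
    t1_star_ms: float
    a: float
    b: float
    r2: float
    polarity_split: int
    status: str


@dataclass(frozen=True)
class T1Map:
    t1_ms: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class R2Map:
    r2: np.ndarray
    valid: np.ndarray


def _linear_ab(y: np.ndarray, e: np.ndarray):
    """Best (A, B) of ``y ~ A - B e`` per row, plus the residual SSE.

    ``y``: (P, 7) signed samples; ``e``: (P, 7) basis ``exp(-TI/T1*)``.
    Closed-form 2x2 normal equations, vectorised over P.
    """
    n = y.shape[-1]
    s_e = e.sum(axis=-1)
    s_ee = (e * e).sum(axis=-1)
    s_y = y.sum(axis=-1)
    s_ey = (e * y).sum(axis=-1)
    denom = s_ee - s_e * s_e / n
    denom = np.where(denom <= 0, np.nan, denom)
    b = (s_e * s_y / n - s_ey) / denom
    a = (s_y + b * s_e) / n
    resid = y - (a[..., None] - b[..., None] * e)
    sse = (resid * resid).sum(axis=-1)
    return a, b, sse


def _sse_at(y: np.ndarray, tis: np.ndarray, t1_star: np.ndarray) -> np.ndarray:
    e = np.exp(-tis / t1_star[..., None])
    return _linear_ab(y, e)[2]


def _fit_polarity(y: np.ndarray, tis: np.ndarray):
    """Variable-projection fit of the signed model for every row of ``y``.

    Returns (t1_star, a, b, sse) arrays of shape (P,).
    """
    lo, hi = T1_STAR_BOUNDS_MS
    grid = np.geomspace(lo, hi, _N_GRID)
    e_grid = np.exp(-tis[None, :] / grid[:, None])  # (G, 7)
    sse_grid = np.stack([_linear_ab(y, np.broadcast_to(e, y.shape))[2] for e in e_grid])
    sse_grid = np.where(np.isfinite(sse_grid), sse_grid, np.inf)
    best = np.argmin(sse_grid, axis=0)

    # golden-section refinement inside the bracketing grid cells
    a_t = grid[np.maximum(best - 1, 0)]
    b_t = grid[np.minimum(best + 1, _N_GRID - 1)]
    c_t = b_t - _INVPHI * (b_t - a_t)
    d_t = a_t + _INVPHI * (b_t - a_t)
    f_c = _sse_at(y, tis, c_t)
    f_d = _sse_at(y, tis, d_t)
    for _ in range(_GOLDEN_ITERS):
        take_c = f_c < f_d
        b_t = np.where(take_c, d_t, b_t)
        a_t = np.where(take_c, a_t, c_t)
        c_t = b_t - _INVPHI * (b_t - a_t)
        d_t = a_t + _INVPHI * (b_t - a_t)
        f_c = _sse_at(y, tis, c_t)
        f_d = _sse_at(y, tis, d_t)
    t1_star = 0.5 * (a_t + b_t)
    e = np.exp(-tis / t1_star[..., None])
    a, b, sse = _linear_ab(y, e)
    return t1_star, a, b, sse


def _fit_block(signals: np.ndarray, tis: np.ndarray):
    """Fit every row of ``signals`` (P, 7) over all polarity splits.

    Returns dict of arrays: t1_ms, t1_star_ms, a, b, r2, polarity, status
    (int codes 0=ok, 1=degenerate, 2=failed).
    """
    P = signals.shape[0]
    best = {
        "r2": np.full(P, -np.inf),
        "t1_star": np.full(P, np.nan),
        "a": np.full(P, np.nan),
        "b": np.full(P, np.nan),
        "k": np.zeros(P, dtype=np.int64),
        "found": np.zeros(P, dtype=bool),
    }
    degenerate = np.ptp(signals, axis=-1) == 0.0

    for k in range(_MAX_POLARITY_SPLIT + 1):
        y = signals.copy()
        y[:, :k] *= -1.0
        ss_tot = ((y - y.mean(axis=-1, keepdims=True)) ** 2).sum(axis=-1)
        t1_star, a, b, sse = _fit_polarity(y, tis)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = 1.0 - sse / ss_tot
        # physically admissible: positive signal scale and B/A > 1 => T1 > 0
        ok = np.isfinite(r2) & (a > 0) & (b > a)
        better = ok & (r2 > best["r2"])
        for key, val in (("r2", r2), ("t1_star", t1_star), ("a", a), ("b", b)):
            best[key] = np.where(better, val, best[key])
        best["k"] = np.where(better, k, best["k"])
        best["found"] |= ok

    status = np.where(degenerate, 1, np.where(best["found"], 0, 2))
    with np.errstate(invalid="ignore"):
        t1_ms = best["t1_star"] * (best["b"] / best["a"] - 1.0)
    bad = status != 0
    t1_ms = np.where(bad, np.nan, t1_ms)
    r2 = np.where(bad, np.nan, best["r2"])
    return {
        "t1_ms": t1_ms,
        "t1_star_ms": np.where(bad, np.nan, best["t1_star"]),
        "a": np.where(bad, np.nan, best["a"]),
        "b": np.where(bad, np.nan, best["b"]),
        "r2": r2,
        "polarity": best["k"],
        "status": status,
    }


def fit_t1_pixel(signals_7, tis_7) -> T1FitResult:
    """Fit one pixel's 7 magnitude samples; see module docstring for model."""
    signals = np.asarray(signals_7, dtype=np.float64).ravel()
    tis = np.asarray(tis_7, dtype=np.float64).ravel()
    if signals.shape != (7,) or tis.shape != (7,):
        raise ContractError(
            f"need 7 signals and 7 inversion times, got {signals.shape} and {tis.shape}"
        )
    if not np.all(np.isfinite(signals)) or np.any(signals < 0):
        raise ContractError("signals must be finite and non-negative (magnitude data)")
    if np.any(tis <= 0) or not np.all(np.isfinite(tis)):
        raise ContractError("inversion times must be finite and positive")
    order = np.argsort(tis, kind="stable")
    res = _fit_block(signals[order][None, :], tis[order])
    status = (STATUS_OK, STATUS_DEGENERATE, STATUS_FAILED)[int(res["status"][0])]
    return T1FitResult(
        t1_ms=float(res["t1_ms"][0]),
        t1_star_ms=float(res["t1_star_ms"][0]),
        a=float(res["a"][0]),
        b=float(res["b"][0]),
        r2=float(res["r2"][0]),
        polarity_split=int(res["polarity"][0]),
        status=status,
    )


def reconstruct_maps(irw_stack: IRWStack, mask: np.ndarray | None = None) -> tuple[T1Map, R2Map]:
    """Per-pixel fit over a stack; pixels outside ``mask`` are marked invalid.

    Invalid pixels (masked out, degenerate or failed fits) carry NaN in both
    maps and ``False`` in the validity masks — they are never silently
    zero-filled.
    """
    H, W = irw_stack.frame_shape
    if mask is None:
        mask = np.ones((H, W), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ContractError(f"mask shape {mask.shape} does not match frames {(H, W)}")
    signals = irw_stack.images.reshape(7, -1).T  # (P, 7), TI-sorted by IRWStack
    flat_mask = mask.ravel()
    res = _fit_block(signals[flat_mask], irw_stack.tis)

    t1 = np.full(H * W, np.nan)
    r2 = np.full(H * W, np.nan)
    valid = np.zeros(H * W, dtype=bool)
    t1[flat_mask] = res["t1_ms"]
    r2[flat_mask] = res["r2"]
    valid[flat_mask] = res["status"] == 0
    t1[~valid] = np.nan
    r2_arr = r2.reshape(H, W)
    return (
        T1Map(t1_ms=t1.reshape(H, W), valid=valid.reshape(H, W)),
        R2Map(r2=r2_arr, valid=valid.reshape(H, W)),
    )


def motion_severity_proxy(r2_map: R2Map | np.ndarray, myocardial_mask: np.ndarray, r2_threshold: float = 0.95) -> float:
    """Fraction of mask pixels whose R^2 falls below ``r2_threshold``.

    A cheap automated surrogate for visual 'dark band' severity; invalid
    (NaN) pixels inside the mask count as below threshold.
    """
    r2 = r2_map.r2 if isinstance(r2_map, R2Map) else np.asarray(r2_map, dtype=np.float64)
    mask = np.asarray(myocardial_mask, dtype=bool)
    if mask.shape != r2.shape:
        raise ContractError(f"mask shape {mask.shape} does not match map {r2.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ContractError("myocardial mask is empty")
    vals = r2[mask]
    below = np.isnan(vals) | (vals < r2_threshold)
    return float(below.sum() / n)
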