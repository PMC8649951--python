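"""Evaluation statistics.

Observer-score pooling uses inverse-variance weighting: observer ``i`` with
intra-observer repeatability SD ``sigma_i`` gets weight ``W_i = 1/sigma_i^2``;
the pooled per-case score is ``Xbar = sum(W_i X_i) / sum(W_i)`` and the
panel-level standard error of the pooled score is
``SE = (sum W_i)^(-1/2)``. Note that although ``sigma_i`` is sometimes
loosely called a variance, the weighting and SE formulas treat it as a
standard deviation (only that reading makes the SE land on the 0-100 score
scale).

Synthetic ground truth is scored with endpoint error (EPE): the Euclidean
norm of the difference between predicted and true displacement vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _sstats

from .dvf import DVFSet
from .errors import ContractError

__all__ = [
    "ObserverPanel",
    "WilcoxonResult",
    "pooled_standard_error",
    "pooled_score",
    "intra_observer_sd",
    "paired_wilcoxon",
    "dvf_recovery_metrics",
]


@dataclass(frozen=True)
class ObserverPanel:
    """Per-case scores from multiple observers with pooling weights."""

    scores: np.ndarray  # (n_observers, n_cases), on the 0-100 scale
    sigmas: np.ndarray  # (n_observers,)
    weights: np.ndarray
    xbar: np.ndarray  # (n_cases,)
    se: float

    @classmethod
    def from_scores(cls, scores_per_observer, sigmas) -> "ObserverPanel":
        xbar, se = pooled_score(scores_per_observer, sigmas)
        scores = np.atleast_2d(np.asarray(scores_per_observer, dtype=np.float64))
        sigmas = np.asarray(sigmas, dtype=np.float64)
        return cls(scores=scores, sigmas=sigmas, weights=1.0 / sigmas**2, xbar=xbar, se=se)


def pooled_standard_error(sigmas) -> float:
    """``SE = (sum 1/sigma_i^2)^(-1/2)`` — panel-level, on the score scale."""
    sigmas = np.asarray(sigmas, dtype=np.float64).ravel()
    if sigmas.size < 2:
        raise ContractError(f"need at least 2 observers, got {sigmas.size}")
    if np.any(sigmas <= 0) or not np.all(np.isfinite(sigmas)):
        raise ContractError("all intra-observer SDs must be finite and > 0")
    return float(1.0 / np.sqrt((1.0 / sigmas**2).sum()))


def pooled_score(scores_per_observer, sigmas) -> tuple[np.ndarray, float]:
    """Inverse-variance weighted mean per case plus the panel SE.

    ``scores_per_observer``: array-like of shape ``(n_observers, n_cases)``
    (a 1-D vector is treated as one score per observer for a single case).
    """
    scores = np.asarray(scores_per_observer, dtype=np.float64)
    if scores.ndim == 1:
        scores = scores[:, None]
    if scores.ndim != 2:
        raise ContractError(f"scores must be (n_observers, n_cases), got shape {scores.shape}")
    sigmas = np.asarray(sigmas, dtype=np.float64).ravel()
    if sigmas.size != scores.shape[0]:
        raise ContractError(
            f"{scores.shape[0]} observers in scores but {sigmas.size} sigmas"
        )
    se = pooled_standard_error(sigmas)  # validates sigmas and count
    w = 1.0 / sigmas**2
    xbar = (w[:, None] * scores).sum(axis=0) / w.sum()
    return xbar, se


def intra_observer_sd(first_scores, repeat_scores) -> float:
    """Within-subject SD from duplicate scorings: ``sqrt(sum d^2 / 2m)``.

    A value of 0 (perfect repeatability) is returned as-is but cannot feed
    :func:`pooled_score`, which requires strictly positive SDs.
    """
    a = np.asarray(first_scores, dtype=np.float64).ravel()
    b = np.asarray(repeat_scores, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ContractError(f"paired score vectors differ in length: {a.size} vs {b.size}")
    if a.size < 2:
        raise ContractError("need at least 2 duplicate pairs")
    d = a - b
    return float(np.sqrt((d**2).sum() / (2.0 * d.size)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    method: str
    no_test: bool = False


def paired_wilcoxon(before, after) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (Wilcoxon's rule). All-zero differences
    yield a ``no_test`` flag instead of a p-value. Exact null distribution
    for small tie-free samples, normal approximation with tie correction
    otherwise.
    """
    x = np.asarray(before, dtype=np.float64).ravel()
    y = np.asarray(after, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ContractError(f"paired samples differ in length: {x.size} vs {y.size}")
    d = y - x
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=np.nan, p_value=np.nan, n_used=0, method="none", no_test=True)
    if d.size < 5:
        raise ContractError(f"need >= 5 non-zero differences, got {d.size}")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "approx" if (has_ties or d.size > 25) else "exact"
    res = _sstats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_used=int(d.size),
        method=method,
    )


def dvf_recovery_metrics(pred_set, gt_set, mask: np.ndarray | None = None) -> dict:
    """Endpoint-error summaries of predicted vs ground-truth field sets.

    Returns ``{"mean_epe_px", "max_epe_px", "frame_epe"}``, all computed
    over ``mask`` only (whole image when ``mask`` is None).
    """
    pred = pred_set.as_array() if isinstance(pred_set, DVFSet) else np.asarray(pred_set, dtype=np.float64)
    gt = gt_set.as_array() if isinstance(gt_set, DVFSet) else np.asarray(gt_set, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ContractError(f"prediction shape {pred.shape} does not match truth {gt.shape}")
    epe = np.sqrt(((pred - gt) ** 2).sum(axis=-1))  # (7, H, W)
    if mask is None:
        mask = np.ones(epe.shape[1:], dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != epe.shape[1:]:
            raise ContractError(f"mask shape {mask.shape} does not match fields {epe.shape[1:]}")
    if not mask.any():
        raise ContractError("mask is empty")
    sel = epe[:, mask]  # (7, n_mask)
    return {
        "mean_epe_px": float(sel.mean()),
        "max_epe_px": float(sel.max()),
        "frame_epe": [float(v) for v in sel.mean(axis=1)],
    }
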