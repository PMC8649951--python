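"""Synthetic short-axis cardiac phantom and inversion-recovery simulation.

Stands in for scanner data: a labelled tissue map (background, body, blood
pool, myocardial ring, a liver-like structure) and the 7 inversion-recovery
weighted (IRW) frames obtained from a magnitude signal model

    S(TI) = | A - B * exp(-TI / T1*) |    with A = M0, B = 2 * M0, T1* = T1,

i.e. perfect inversion efficiency, under which the apparent and true T1
coincide (the Look-Locker correction ``T1 = T1* (B/A - 1)`` is the
identity). Optional noise is a cheap Rician surrogate: Gaussian noise added
before taking the magnitude, preserving non-negativity.

The ground-truth T1/M0 images, label map and seed travel in
``IRWStack.meta`` so downstream evaluation never has to guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DataError, GeometryError

__all__ = [
    "LABELS",
    "TissueMap",
    "IRWStack",
    "make_phantom",
    "simulate_irw",
    "default_ti_schedule",
]

N_FRAMES = 7

#: Label codes used throughout the package.
LABELS = {
    "background": 0,
    "body": 1,
    "blood_pool": 2,
    "myocardium": 3,
    "liver": 4,
}

#: Default per-tissue T1 (ms). 1.5T-like native contrast; configuration
#: defaults, not physiological claims. Background gets a nominal positive T1
#: so the invariant "T1 > 0 for every present label" holds; its M0 of 0
#: makes it signal-free regardless.
DEFAULT_T1_MS = {0: 1.0, 1: 600.0, 2: 1600.0, 3: 950.0, 4: 500.0}
DEFAULT_M0 = {0: 0.0, 1: 80.0, 2: 100.0, 3: 85.0, 4: 70.0}

#: Default 7-point TI schedule (ms): dense early sampling then sparse late
#: samples spanning the recovery curve, ShMOLLI-like in spirit. Chosen so
#: that at most 3 samples precede the signal null for T1 up to ~2000 ms,
#: matching the polarity search of the map fitter.
DEFAULT_TI_MS = (100.0, 180.0, 260.0, 1420.0, 2580.0, 3740.0, 4900.0)


def default_ti_schedule() -> np.ndarray:
    return np.asarray(DEFAULT_TI_MS, dtype=np.float64)


@dataclass(frozen=True)
class TissueMap:
    """Integer label image with per-label T1/M0 lookup tables."""

    labels: np.ndarray
    t1_by_label: dict[int, float]
    m0_by_label: dict[int, float]
    pixel_spacing: float = 1.8

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 2 or not np.issubdtype(labels.dtype, np.integer):
            raise ContractError("labels must be a 2-D integer image")
        present = set(np.unique(labels).tolist())
        for lab in present:
            if lab not in self.t1_by_label or lab not in self.m0_by_label:
                raise DataError(f"label {lab} present in map but missing from T1/M0 tables")
            if self.t1_by_label[lab] <= 0:
                raise DataError(f"label {lab} has non-positive T1 {self.t1_by_label[lab]}")
            if self.m0_by_label[lab] < 0:
                raise DataError(f"label {lab} has negative M0 {self.m0_by_label[lab]}")
        object.__setattr__(self, "labels", labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def lookup(self, table: dict[int, float]) -> np.ndarray:
        """Map the label image through a per-label scalar table."""
        out = np.zeros(self.labels.shape, dtype=np.float64)
        for lab, val in table.items():
            out[self.labels == lab] = val
        return out

    def t1_image(self) -> np.ndarray:
        return self.lookup(self.t1_by_label)

    def m0_image(self) -> np.ndarray:
        return self.lookup(self.m0_by_label)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


@dataclass
class IRWStack:
    """Seven co-located IRW frames with their inversion times.

    ``images`` is ``(7, H, W)`` sorted by ascending TI; intensities are
    magnitude data (finite, non-negative). ``meta`` carries provenance and,
    for synthetic stacks, ground truth.
    """

    images: np.ndarray
    tis: np.ndarray
    pixel_spacing: float = 1.8
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        images = np.asarray(self.images, dtype=np.float64)
        tis = np.asarray(self.tis, dtype=np.float64)
        if images.ndim != 3 or images.shape[0] != N_FRAMES:
            raise ContractError(
                f"IRWStack needs exactly {N_FRAMES} frames of identical shape, "
                f"got array of shape {images.shape}"
            )
        if tis.shape != (N_FRAMES,):
            raise ContractError(f"IRWStack needs {N_FRAMES} inversion times, got {tis.shape}")
        if not np.all(np.isfinite(images)) or np.any(images < 0):
            raise ContractError("IRW intensities must be finite and non-negative")
        if not np.all(np.isfinite(tis)) or np.any(tis <= 0):
            raise ContractError("inversion times must be finite and positive")
        order = np.argsort(tis, kind="stable")
        self.images = images[order]
        self.tis = tis[order]
        if np.any(np.diff(self.tis) <= 0):
            raise ContractError("inversion times must be strictly increasing after sorting")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def copy_with(self, images: np.ndarray | None = None, **meta_updates) -> "IRWStack":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return IRWStack(
            images=self.images.copy() if images is None else images,
            tis=self.tis.copy(),
            pixel_spacing=self.pixel_spacing,
            meta=meta,
        )


def make_phantom(
    shape: tuple[int, int] = (64, 64),
    centre: tuple[float, float] | None = None,
    r_inner: float = 8.0,
    r_outer: float = 14.0,
    jitter_px: float = 0.0,
    seed=None,
    t1_by_label: dict[int, float] | None = None,
    m0_by_label: dict[int, float] | None = None,
    pixel_spacing: float = 1.8,
) -> TissueMap:
    """Rasterize a short-axis slice: body ellipse, liver blob, myocardial
    annulus around a circular blood pool.

    Deterministic for a fixed seed; ``jitter_px > 0`` randomly perturbs the
    heart centre and both radii (uniformly in ``+-jitter_px``).
    """
    H, W = shape
    if H < 32 or W < 32:
        raise GeometryError(f"image must be at least 32x32, got {H}x{W}")
    cr, cc = centre if centre is not None else (H / 2.0, W / 2.0)
    rng = np.random.default_rng(seed)
    if jitter_px > 0:
        cr += rng.uniform(-jitter_px, jitter_px)
        cc += rng.uniform(-jitter_px, jitter_px)
        r_inner += rng.uniform(-jitter_px, jitter_px) * 0.5
        r_outer += rng.uniform(-jitter_px, jitter_px) * 0.5
    if r_inner <= 0 or r_outer <= r_inner:
        raise GeometryError(
            f"need 0 < r_inner < r_outer, got r_inner={r_inner:.2f}, r_outer={r_outer:.2f}"
        )
    if (
        cr - r_outer < 1
        or cc - r_outer < 1
        or cr + r_outer > H - 2
        or cc + r_outer > W - 2
    ):
        raise GeometryError(
            f"heart (centre ({cr:.1f}, {cc:.1f}), outer radius {r_outer:.1f}) "
            f"does not fit inside a {H}x{W} image"
        )

    rr, cc_grid = np.meshgrid(np.arange(H, dtype=np.float64), np.arange(W, dtype=np.float64), indexing="ij")
    labels = np.zeros((H, W), dtype=np.int32)

    # torso: large ellipse centred on the image
    body = ((rr - H / 2.0) / (0.46 * H)) ** 2 + ((cc_grid - W / 2.0) / (0.48 * W)) ** 2 <= 1.0
    labels[body] = LABELS["body"]

    # liver/stomach-like blob in the lower-left quadrant of the torso
    liver = (
        ((rr - 0.72 * H) / (0.16 * H)) ** 2 + ((cc_grid - 0.30 * W) / (0.22 * W)) ** 2 <= 1.0
    ) & body
    labels[liver] = LABELS["liver"]

    dist = np.sqrt((rr - cr) ** 2 + (cc_grid - cc) ** 2)
    labels[(dist >= r_inner) & (dist < r_outer)] = LABELS["myocardium"]
    labels[dist < r_inner] = LABELS["blood_pool"]

    return TissueMap(
        labels=labels,
        t1_by_label=dict(t1_by_label or DEFAULT_T1_MS),
        m0_by_label=dict(m0_by_label or DEFAULT_M0),
        pixel_spacing=pixel_spacing,
    )


def inversion_recovery_signal(m0, t1_ms, ti_ms) -> np.ndarray:
    """Noiseless magnitude IR signal ``|M0 - 2 M0 exp(-TI/T1)|`` (broadcasting)."""
    m0 = np.asarray(m0, dtype=np.float64)
    t1_ms = np.asarray(t1_ms, dtype=np.float64)
    return np.abs(m0 - 2.0 * m0 * np.exp(-np.asarray(ti_ms, dtype=np.float64) / t1_ms))


def simulate_irw(
    tissue_map: TissueMap,
    tis=None,
    noise_sigma: float = 0.0,
    seed=None,
    blur_sigma_px: float = 0.0,
) -> IRWStack:
    """Simulate the 7 IRW frames of a tissue map.

    Noise model: ``|S + N(0, sigma)|`` per pixel per frame, sigma in M0
    units; bit-reproducible for a fixed seed. ``blur_sigma_px`` applies a
    Gaussian point-spread surrogate to each noiseless frame (band-limited
    images warp cleanly; 0 keeps the piecewise-constant ideal whose fits
    are exact).
    """
    tis = default_ti_schedule() if tis is None else np.asarray(tis, dtype=np.float64)
    if tis.shape != (N_FRAMES,):
        raise ContractError(f"need exactly {N_FRAMES} inversion times, got {tis.shape}")
    if np.any(tis <= 0):
        raise ContractError("all inversion times must be positive")
    if noise_sigma < 0:
        raise ContractError(f"noise_sigma must be >= 0, got {noise_sigma}")
    tis = np.sort(tis)

    t1 = tissue_map.t1_image()
    m0 = tissue_map.m0_image()
    frames = np.stack([inversion_recovery_signal(m0, t1, ti) for ti in tis])
    if blur_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        frames = np.stack([gaussian_filter(f, blur_sigma_px) for f in frames])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = np.abs(frames + rng.normal(0.0, noise_sigma, size=frames.shape))

    return IRWStack(
        images=frames,
        tis=tis,
        pixel_spacing=tissue_map.pixel_spacing,
        meta={
            "source": "phantom",
            "seed": seed,
            "noise_sigma": float(noise_sigma),
            "blur_sigma_px": float(blur_sigma_px),
            "t1_gt": t1,
            "m0_gt": m0,
            "labels": tissue_map.labels.copy(),
        },
    )
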