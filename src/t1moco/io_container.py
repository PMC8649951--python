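"""Readers/writers: fixture container, NIfTI, DICOM series.

The canonical test/dev format is a single-file compressed array archive
(``.npz``) holding the frames, inversion times, pixel spacing and a JSON
metadata blob (ground-truth arrays, when present, are stored as separate
arrays). DICOM and NIfTI support is deliberately thin: a DICOM series
directory (requires the optional ``pydicom`` extra) or a NIfTI volume with
a JSON sidecar carrying the inversion times.

Coordinate convention (package-wide): row-major arrays, 0-based indexing,
displacement components ordered (row, col).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .dvf import DVFSet
from .errors import FormatError
from .phantom import IRWStack

__all__ = [
    "save_stack_fixture",
    "load_stack_fixture",
    "read_irw_stack",
    "write_nifti",
    "file_checksum",
]

_META_ARRAY_KEYS = ("t1_gt", "m0_gt", "labels", "applied_dvfs", "gt_inverse_dvfs")


def save_stack_fixture(path, stack: IRWStack, gt_inverse: DVFSet | None = None) -> Path:
    """Write a stack (plus any ground truth in its meta) to one ``.npz``."""
    path = Path(path)
    meta = dict(stack.meta)
    arrays = {}
    for key in _META_ARRAY_KEYS:
        if key in meta:
            arrays[key] = np.asarray(meta.pop(key))
    if gt_inverse is not None:
        arrays["gt_inverse_dvfs"] = gt_inverse.as_array()
    meta_json = json.dumps(meta, default=_json_fallback)
    np.savez_compressed(
        path,
        images=stack.images,
        tis=stack.tis,
        pixel_spacing=np.float64(stack.pixel_spacing),
        meta_json=np.frombuffer(meta_json.encode(), dtype=np.uint8),
        **arrays,
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def _json_fallback(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def load_stack_fixture(path) -> IRWStack:
    path = Path(path)
    with np.load(path) as data:
        if "images" not in data or "tis" not in data:
            raise FormatError(f"{path} is not a t1moco stack fixture")
        meta = json.loads(bytes(data["meta_json"]).decode()) if "meta_json" in data else {}
        for key in _META_ARRAY_KEYS:
            if key in data:
                meta[key] = data[key]
        return IRWStack(
            images=data["images"],
            tis=data["tis"],
            pixel_spacing=float(data["pixel_spacing"]) if "pixel_spacing" in data else 1.8,
            meta=meta,
        )


def _read_nifti_stack(path: Path) -> IRWStack:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume (H, W, 7), got shape {arr.shape}")
    if arr.shape[-1] != 7:
        raise FormatError(f"{path}: found {arr.shape[-1]} of 7 frames")
    sidecar = path.with_suffix("").with_suffix(".json") if path.name.endswith(".nii.gz") else path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing TI sidecar {sidecar.name}")
    side = json.loads(sidecar.read_text())
    if "tis_ms" not in side:
        raise FormatError(f"{sidecar}: no 'tis_ms' entry")
    spacing = float(img.header.get_zooms()[0])
    return IRWStack(
        images=np.transpose(arr, (2, 0, 1)).astype(np.float64),
        tis=np.asarray(side["tis_ms"], dtype=np.float64),
        pixel_spacing=spacing,
        meta={"source": str(path)},
    )


def _read_dicom_series(path: Path) -> IRWStack:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading DICOM series requires the optional 'pydicom' dependency "
            "(pip install t1moco[dicom])"
        ) from exc
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.is_file())
    frames, tis = [], []
    spacing = 1.8
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if not hasattr(ds, "pixel_array"):
            continue
        ti = getattr(ds, "InversionTime", None)
        if ti is None:
            raise FormatError(f"{f}: missing InversionTime tag")
        frames.append(ds.pixel_array.astype(np.float64))
        tis.append(float(ti))
        if getattr(ds, "PixelSpacing", None):
            spacing = float(ds.PixelSpacing[0])
    if len(frames) != 7:
        raise FormatError(f"{path}: found {len(frames)} of 7 frames")
    return IRWStack(images=np.stack(frames), tis=np.asarray(tis), pixel_spacing=spacing,
                    meta={"source": str(path)})


def read_irw_stack(path) -> IRWStack:
    """Read a stack from a fixture ``.npz``, NIfTI (+TI sidecar) or DICOM
    directory. Frames come back sorted by ascending inversion time."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such stack: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix == ".npz":
        return load_stack_fixture(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti_stack(path)
    raise FormatError(f"unrecognised stack format: {path}")


def write_nifti(path, array: np.ndarray, pixel_spacing: float = 1.8):
    """Export a 2-D map or (7, H, W) stack as float NIfTI (stack -> H, W, 7)."""
    import nibabel as nib

    arr = np.asarray(array, dtype=np.float32)
    if arr.ndim == 3:
        arr = np.transpose(arr, (1, 2, 0))
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
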