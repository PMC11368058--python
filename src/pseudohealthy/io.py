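"""File I/O: NIfTI volumes, 16-bit PNG slices/masks, checkpoint archives."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .image import GraySlice, LesionMask, ValidationError


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Load a NIfTI volume; returns (array, in-plane spacing in mm)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    return np.asarray(data, dtype=np.float64), float(zooms[0])


def load_mask_volume(path) -> np.ndarray:
    """Load a NIfTI label volume; any nonzero label collapses to 1."""
    data, _ = load_nifti(path)
    if np.isnan(data).all():
        raise ValidationError("annotation volume is all-NaN")
    return (np.nan_to_num(data) != 0).astype(np.uint8)


def save_slice_png(path, img: GraySlice) -> None:
    """Write a slice as 16-bit grayscale PNG ([-1,1] -> [0, 65535])."""
    from PIL import Image

    arr = np.round((img.pixels.astype(np.float64) + 1.0) / 2.0 * 65535.0).astype(np.uint16)
    Image.fromarray(arr).save(str(path))


def load_slice_png(path, spacing: float = 1.0) -> GraySlice:
    """Read a grayscale PNG, rescaling the full bit depth to [-1, 1]."""
    from PIL import Image

    im = Image.open(str(path))
    arr = np.asarray(im, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[..., 0]
    peak = 65535.0 if arr.max() > 255 or im.mode in ("I;16", "I") else 255.0
    return GraySlice((2.0 * arr / peak - 1.0).astype(np.float32), spacing)


def save_mask_png(path, mask: LesionMask) -> None:
    from PIL import Image

    Image.fromarray((mask.pixels * 255).astype(np.uint8), mode="L").save(str(path))


def load_mask_png(path, spacing: float = 1.0) -> LesionMask:
    from PIL import Image

    arr = np.asarray(Image.open(str(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return LesionMask((arr != 0).astype(np.uint8), spacing)


def save_checkpoint(path, kind: str, meta: dict, arrays: list[np.ndarray]) -> None:
    """Single-file archive: architecture metadata + parameter arrays."""
    payload = {f"param_{i:04d}": a for i, a in enumerate(arrays)}
    np.savez(str(path), kind=np.array(kind), meta=np.array(json.dumps(meta)), **payload)


def load_checkpoint(path) -> tuple[str, dict, list[np.ndarray]]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"checkpoint not found: {p}")
    with np.load(str(p)) as z:
        kind = str(z["kind"])
        meta = json.loads(str(z["meta"]))
        keys = sorted(k for k in z.files if k.startswith("param_"))
        arrays = [z[k] for k in keys]
    return kind, meta, arrays
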