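"""Core image/mask types and the pixel-level operations shared by every
stage: intensity normalization, left-right flipping, mask dilation,
compositing and patch bookkeeping.

Conventions
-----------
* Grayscale slices live in ``[-1, 1]``; the darkest value is background
  (skull-stripped scans have a zero background, which maps to -1).
* Lesion masks are binary; 1 marks missing/pathological pixels.
* Coordinates are 0-based row-major; flips are about the vertical
  midline (left-right), matching brain bilateral symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


class ValidationError(ValueError):
    """Raised when an input violates an operation's contract."""


@dataclass(frozen=True)
class GraySlice:
    """A 2-D grayscale slice with isotropic pixel spacing in mm."""

    pixels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("slice must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ValidationError("slice contains non-finite values")
        if px.min() < -1.0 - 1e-5 or px.max() > 1.0 + 1e-5:
            raise ValidationError("slice values must lie in [-1, 1]; normalize first")
        object.__setattr__(self, "pixels", np.clip(px, -1.0, 1.0))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def foreground(self) -> np.ndarray:
        """Boolean mask of non-background pixels (above the -1 floor)."""
        return self.pixels > -1.0 + 1e-3


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask paired with a slice: 1 = missing/pathological."""

    pixels: np.ndarray
    spacing: float = 1.0

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("mask must be 2-D")
        vals = np.unique(px)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("mask values must be 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self):
        return self.pixels.shape

    def fraction_of(self, foreground: np.ndarray) -> float:
        n = int(np.count_nonzero(foreground))
        if n == 0:
            raise ValidationError("empty foreground")
        return float(np.count_nonzero(self.pixels.astype(bool) & foreground)) / n


@dataclass
class PatchSet:
    """Non-overlapping raster-order tiling of a (C, H, W) feature map.

    A patch is labeled *inside* if at least one of its pixels is masked;
    only *outside* patches ever serve as attention context.
    """

    patch_size: int
    patches: np.ndarray          # (P, C, p, p) raster order
    inside: np.ndarray           # (P,) bool, True = inside mask
    grid: tuple[int, int]        # (rows, cols) of the patch grid
    channels: int = field(default=1)

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    @property
    def n_outside(self) -> int:
        return int(np.count_nonzero(~self.inside))

    def flat(self) -> np.ndarray:
        """(P, C*p*p) view used for affinity computation."""
        return self.patches.reshape(self.n_patches, -1)


def normalize_intensity(raw: np.ndarray, spacing: float = 1.0) -> GraySlice:
    """Linearly map an arbitrary-range image to [-1, 1].

    The minimum maps to -1 and the maximum to +1.  A zero-range image
    maps to all -1 (background), consistent with skull-stripped scans
    where the darkest value is background.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValidationError("expected a 2-D array")
    if not np.all(np.isfinite(raw)):
        raise ValidationError("input contains non-finite values")
    lo, hi = raw.min(), raw.max()
    if hi - lo <= 0:
        return GraySlice(np.full(raw.shape, -1.0, dtype=np.float32), spacing)
    return GraySlice((2.0 * (raw - lo) / (hi - lo) - 1.0).astype(np.float32), spacing)


def horizontal_flip(img: GraySlice) -> GraySlice:
    return GraySlice(img.pixels[:, ::-1].copy(), img.spacing)


def flip_mask(mask: LesionMask) -> LesionMask:
    return LesionMask(mask.pixels[:, ::-1].copy(), mask.spacing)


def disk_structure(radius_px: float) -> np.ndarray:
    """Euclidean disk footprint: lattice points with dx^2 + dy^2 <= r^2."""
    r = int(np.floor(radius_px))
    if r < 0:
        raise ValidationError("radius must be non-negative")
    yy, xx = np.ogrid[-r:r + 1, -r:r + 1]
    return (yy * yy + xx * xx) <= radius_px * radius_px + 1e-9


def dilate_mask(mask: LesionMask, radius_mm: float) -> LesionMask:
    """Morphological dilation with a Euclidean disk of ``radius_mm``."""
    if radius_mm < 0:
        raise ValidationError("dilation radius must be non-negative")
    r_px = radius_mm / mask.spacing
    if r_px < 1.0:
        return LesionMask(mask.pixels.copy(), mask.spacing)
    out = ndi.binary_dilation(mask.pixels.astype(bool), structure=disk_structure(r_px))
    return LesionMask(out.astype(np.uint8), mask.spacing)


def composite(original: GraySlice, generated: GraySlice, mask: LesionMask) -> GraySlice:
    """mask * generated + (1 - mask) * original, bit-exact outside the mask."""
    if original.pixels.shape != generated.pixels.shape or original.pixels.shape != mask.shape:
        raise ValidationError("composite inputs must share one shape")
    m = mask.pixels.astype(bool)
    out = original.pixels.copy()
    out[m] = generated.pixels[m]
    return GraySlice(out, original.spacing)


def extract_patches(feature: np.ndarray, patch_size: int, mask: LesionMask) -> PatchSet:
    """Tile a (H, W) or (C, H, W) feature map into raster-order patches.

    Spatial dims must be divisible by ``patch_size``; the mask must match
    the feature's spatial dims.
    """
    feat = np.asarray(feature, dtype=np.float32)
    if feat.ndim == 2:
        feat = feat[None]
    c, h, w = feat.shape
    if h % patch_size or w % patch_size:
        raise ValidationError(
            f"spatial dims {h}x{w} not divisible by patch size {patch_size}; resize or pad first")
    if mask.shape != (h, w):
        raise ValidationError("mask shape must match feature spatial dims")
    gh, gw = h // patch_size, w // patch_size
    tiles = feat.reshape(c, gh, patch_size, gw, patch_size).transpose(1, 3, 0, 2, 4)
    patches = tiles.reshape(gh * gw, c, patch_size, patch_size).copy()
    mt = mask.pixels.reshape(gh, patch_size, gw, patch_size).transpose(0, 2, 1, 3)
    inside = mt.reshape(gh * gw, -1).any(axis=1)
    return PatchSet(patch_size, patches, inside, (gh, gw), channels=c)


def scatter_patches(ps: PatchSet) -> np.ndarray:
    """Inverse of :func:`extract_patches` (returns a (C, H, W) array)."""
    gh, gw = ps.grid
    p, c = ps.patch_size, ps.channels
    tiles = ps.patches.reshape(gh, gw, c, p, p).transpose(2, 0, 3, 1, 4)
    return tiles.reshape(c, gh * p, gw * p).copy()


def downsample_mask(mask: LesionMask, factor: int) -> LesionMask:
    """Block-max downsampling: a coarse pixel is masked if any fine pixel is."""
    h, w = mask.shape
    if h % factor or w % factor:
        raise ValidationError("mask dims not divisible by downsampling factor")
    m = mask.pixels.reshape(h // factor, factor, w // factor, factor).max(axis=(1, 3))
    return LesionMask(m, mask.spacing * factor)


def resize_slice(img: GraySlice, shape: tuple[int, int]) -> GraySlice:
    """Bilinear resize preserving the [-1, 1] range."""
    from skimage.transform import resize

    out = resize(img.pixels.astype(np.float64), shape, order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    new_spacing = img.spacing * img.height / shape[0]
    return GraySlice(np.clip(out, -1, 1).astype(np.float32), new_spacing)
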