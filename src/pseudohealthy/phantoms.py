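"""Synthetic brain-like phantoms for desk-scale training and testing.

The phantoms emulate the features of skull-stripped axial MRI slices
that the synthesis pipeline depends on: a bilaterally symmetric
brain-shaped foreground on a -1 background, nested internal structures
(cortex band, tissue ellipses, ventricle-like dark shapes), lesions as
local intensity anomalies with an optional mass-effect deformation, and
free-form random training masks covering 30-60% of the brain area.
They do not model MR physics, partial-volume effects or scanner noise
statistics; see docs/methods.md for what that implies about test
conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .image import GraySlice, LesionMask, ValidationError, disk_structure


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise of one healthy phantom slice."""

    size: int = 64
    foreground_axes: tuple[float, float] = (0.40, 0.34)  # semi-axes as fraction of size
    n_structures: int = 3
    noise_sigma: float = 0.03
    seed: int = 0

    def axes_px(self) -> tuple[float, float]:
        a = self.foreground_axes[0] * self.size
        b = self.foreground_axes[1] * self.size
        return a, b


@dataclass(frozen=True)
class LesionSpec:
    """One circular lesion: intensity anomaly plus optional mass effect."""

    center: tuple[float, float]          # (row, col)
    radius: float
    intensity_shift: float = 0.7         # in [-2, 2]
    deformation_amplitude: float = 0.0   # px; support width of the radial push
    seed: int = 0

    def __post_init__(self):
        if not -2.0 <= self.intensity_shift <= 2.0:
            raise ValidationError("intensity_shift must lie in [-2, 2]")
        if self.deformation_amplitude < 0:
            raise ValidationError("deformation_amplitude must be >= 0")


def _sym_grid(size: int):
    """Row/col grids centred so that column reversal is an exact mirror."""
    c = (size - 1) / 2.0
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    return rr - c, cc - c


def make_healthy_phantom(spec: PhantomSpec) -> GraySlice:
    """Deterministic bilaterally symmetric phantom on a -1 background."""
    s = spec.size
    a, b = spec.axes_px()
    if a >= s / 2 or b >= s / 2:
        raise ValidationError("foreground ellipse does not fit inside the image")
    if spec.noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    rng = np.random.default_rng(spec.seed)
    dr, dc = _sym_grid(s)
    ell = (dc / a) ** 2 + (dr / b) ** 2  # horizontal semi-axis a (left-right)
    fg = ell <= 1.0

    img = np.full((s, s), -1.0)
    img[fg] = 0.15
    cortex = (ell <= 1.0) & (ell >= 0.78)
    img[cortex] = 0.45

    # mirrored internal tissue ellipses
    for _ in range(spec.n_structures):
        off_c = rng.uniform(0.12, 0.55) * a
        off_r = rng.uniform(-0.5, 0.5) * b
        ra = rng.uniform(0.10, 0.22) * a
        rb = rng.uniform(0.10, 0.22) * b
        level = rng.uniform(-0.35, 0.75)
        if abs(off_c) + ra >= a or abs(off_r) + rb >= b:
            raise ValidationError("internal structure does not fit inside the foreground")
        for sign in (-1.0, 1.0):
            m = ((dc - sign * off_c) / ra) ** 2 + ((dr - off_r) / rb) ** 2 <= 1.0
            img[m & fg] = level

    # ventricle-like dark crescents, mirrored about the midline
    for sign in (-1.0, 1.0):
        m = ((dc - sign * 0.16 * a) / (0.12 * a)) ** 2 + (dr / (0.42 * b)) ** 2 <= 1.0
        img[m & fg] = -0.65

    if spec.noise_sigma > 0:
        noise = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=(s, s)), 1.2)
        noise /= max(noise.std(), 1e-9)
        img[fg] += spec.noise_sigma * noise[fg]

    return GraySlice(np.clip(img, -1, 1).astype(np.float32), spacing=1.0)


def inject_lesion(img: GraySlice, spec: LesionSpec) -> tuple[GraySlice, LesionMask]:
    """Apply an intensity anomaly (and optional mass effect) to a phantom.

    The mass effect is a compact-support radial push: tissue at radius r
    from the lesion centre is displaced outward by
    ``A/2 * (1 - (r - R)/A)^2`` for ``R <= r <= R + A`` (constant A/2
    inside the lesion), so the image changes only within the lesion disk
    dilated by the deformation amplitude.
    """
    s = img.pixels.shape
    cy, cx = spec.center
    rr, cc = np.mgrid[0:s[0], 0:s[1]].astype(np.float64)
    dist = np.hypot(rr - cy, cc - cx)
    disk = dist <= spec.radius + 1e-9
    if not np.any(disk & img.foreground()):
        raise ValidationError("lesion disk does not intersect the foreground")

    out = img.pixels.astype(np.float64).copy()
    amp = spec.deformation_amplitude
    if amp >= 1.0:
        # support width just under the amplitude keeps every warped lattice
        # pixel inside the disk dilated by the amplitude
        t = np.clip((dist - spec.radius) / (amp - 0.999), 0.0, 1.0)
        mag = 0.5 * amp * (1.0 - t) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            ur = np.where(dist > 1e-9, (rr - cy) / dist, 0.0)
            uc = np.where(dist > 1e-9, (cc - cx) / dist, 0.0)
        # output at x samples input at x - u(x): an outward push of tissue
        coords = np.stack([rr - mag * ur, cc - mag * uc])
        out = ndi.map_coordinates(out, coords, order=1, mode="nearest")

    rng = np.random.default_rng(spec.seed)
    texture = ndi.gaussian_filter(rng.normal(0.0, 1.0, size=s), 1.0)
    # texture rides on the anomaly, so a zero shift leaves the image intact
    out[disk] += spec.intensity_shift * (1.0 + 0.12 * texture[disk])
    return (GraySlice(np.clip(out, -1, 1).astype(np.float32), img.spacing),
            LesionMask(disk.astype(np.uint8), img.spacing))


def sample_training_mask(shape: tuple[int, int], foreground: np.ndarray,
                         ratio_range: tuple[float, float] = (0.30, 0.60),
                         seed: int = 0) -> LesionMask:
    """Free-form training mask covering a 30-60% fraction of the brain.

    Strokes (thick random polylines) and disks seed the shape family;
    the union is then grown or shrunk monotonically -- by ranking
    foreground pixels on signed Euclidean distance to the union -- until
    the masked fraction of the foreground equals a target drawn
    uniformly from ``ratio_range``.
    """
    lo, hi = ratio_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValidationError("ratio_range must satisfy 0 < lo <= hi < 1")
    fg = np.asarray(foreground, dtype=bool)
    if fg.shape != tuple(shape):
        raise ValidationError("foreground shape mismatch")
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValidationError("foreground is empty")
    k_lo = int(np.ceil(lo * n_fg))
    k_hi = int(np.floor(hi * n_fg))
    if k_lo > k_hi or k_lo < 1:
        raise ValidationError("foreground too small to achieve the requested ratio")

    rng = np.random.default_rng(seed)
    h, w = shape
    canvas = np.zeros(shape, dtype=bool)
    fg_pts = np.argwhere(fg)
    for _ in range(rng.integers(2, 6)):
        p = fg_pts[rng.integers(len(fg_pts))].astype(np.float64)
        thick = rng.uniform(1.5, 4.0)
        for _ in range(rng.integers(3, 8)):
            ang = rng.uniform(0, 2 * np.pi)
            step = rng.uniform(0.08, 0.25) * min(h, w)
            q = p + step * np.array([np.sin(ang), np.cos(ang)])
            n = max(int(step), 2)
            for t in np.linspace(0, 1, n):
                y, x = p + t * (q - p)
                yy, xx = int(round(y)), int(round(x))
                if 0 <= yy < h and 0 <= xx < w:
                    canvas[yy, xx] = True
            p = np.clip(q, 0, [h - 1, w - 1])
        canvas = ndi.binary_dilation(canvas, structure=disk_structure(thick))
    for _ in range(rng.integers(1, 4)):
        cy, cx = fg_pts[rng.integers(len(fg_pts))]
        r = rng.uniform(2.0, 0.15 * min(h, w))
        yy, xx = np.ogrid[0:h, 0:w]
        canvas |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    if not canvas.any():
        canvas[tuple(fg_pts[rng.integers(len(fg_pts))])] = True

    # signed distance to the stroke union: negative inside, positive outside
    signed = np.where(canvas, -ndi.distance_transform_edt(canvas),
                      ndi.distance_transform_edt(~canvas))
    k = int(rng.integers(k_lo, k_hi + 1))
    vals = signed[fg]
    order = np.argsort(vals, kind="stable")
    chosen = np.zeros(n_fg, dtype=bool)
    chosen[order[:k]] = True
    mask = np.zeros(shape, dtype=np.uint8)
    mask[fg] = chosen
    return LesionMask(mask)


@dataclass
class PairedDataset:
    """Paired healthy/pathological phantoms with ground-truth masks."""

    healthy: list[GraySlice]
    pathological: list[GraySlice]
    masks: list[LesionMask]
    train_idx: np.ndarray
    val_idx: np.ndarray

    def __len__(self) -> int:
        return len(self.healthy)


def make_paired_dataset(n: int, template: PhantomSpec = PhantomSpec(), seed: int = 0,
                        radius_range: tuple[float, float] = (0.09, 0.19),
                        shift_range: tuple[float, float] = (0.5, 1.0),
                        deformation_range: tuple[float, float] = (0.0, 3.0),
                        val_fraction: float = 0.2) -> PairedDataset:
    """Generate ``n`` lesioned phantoms with a reproducible train/val split."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    s = template.size
    a, b = template.axes_px()
    c = (s - 1) / 2.0
    healthy, pathological, masks = [], [], []
    for i in range(n):
        spec = PhantomSpec(size=s, foreground_axes=template.foreground_axes,
                           n_structures=template.n_structures,
                           noise_sigma=template.noise_sigma,
                           seed=int(rng.integers(0, 2 ** 31 - 1)))
        h_img = make_healthy_phantom(spec)
        # lesion centre inside the ellipse with margin for its radius
        radius = rng.uniform(*radius_range) * s
        while True:
            oy = rng.uniform(-0.7, 0.7) * b
            ox = rng.uniform(-0.7, 0.7) * a
            if (ox / a) ** 2 + (oy / b) ** 2 <= 0.55:
                break
        sign = -1.0 if rng.random() < 0.5 else 1.0
        les = LesionSpec(center=(c + oy, c + ox), radius=radius,
                         intensity_shift=sign * rng.uniform(*shift_range),
                         deformation_amplitude=rng.uniform(*deformation_range),
                         seed=int(rng.integers(0, 2 ** 31 - 1)))
        p_img, m = inject_lesion(h_img, les)
        healthy.append(h_img)
        pathological.append(p_img)
        masks.append(m)
    perm = np.random.default_rng(seed + 1).permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return PairedDataset(healthy, pathological, masks,
                         train_idx=np.sort(perm[n_val:]), val_idx=np.sort(perm[:n_val]))
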