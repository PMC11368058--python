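"""Stage 1 -- lesion localization.

A standard encoder-decoder U-Net with skip connections, trained with
pixel-wise binary cross-entropy, localizes lesions in pathological
slices.  The same interface also backs the healthiness metric's
segmentation model, which is a separately trained instance.  Manual
pixel-level annotations can stand in for the model wherever a
:class:`~pseudohealthy.image.LesionMask` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import io as pio
from .image import GraySlice, LesionMask, ValidationError, dilate_mask
from .nn import Adam, Conv2d, Module, Tensor, concat, lr_at_epoch


class UNet(Module):
    def __init__(self, depth: int = 4, width: int = 32, in_ch: int = 1, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth, self.width, self.in_ch = depth, width, in_ch
        ch = [width * 2 ** i for i in range(depth + 1)]
        self.enc = [Conv2d(in_ch if i == 0 else ch[i - 1], ch[i], 3, act="relu", rng=rng)
                    for i in range(depth)]
        self.down = [Conv2d(ch[i], ch[i], 3, stride=2, act="relu", rng=rng) for i in range(depth)]
        self.mid = Conv2d(ch[depth - 1], ch[depth], 3, act="relu", rng=rng)
        self.up = [Conv2d(ch[i + 1], ch[i], 3, act="relu", rng=rng) for i in range(depth)]
        self.dec = [Conv2d(2 * ch[i], ch[i], 3, act="relu", rng=rng) for i in range(depth)]
        self.head = Conv2d(width, 1, 1, padding=0, rng=rng, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        skips = []
        for i in range(self.depth):
            x = self.enc[i](x)
            skips.append(x)
            x = self.down[i](x)
        x = self.mid(x)
        for i in reversed(range(self.depth)):
            x = self.up[i](x.upsample2())
            x = self.dec[i](concat([skips[i], x]))
        return self.head(x)  # logits


@dataclass
class SegmentorModel:
    """Trained segmentation model with its decision threshold."""

    net: UNet
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValidationError("threshold must lie in (0, 1)")

    def predict_proba(self, img: GraySlice) -> np.ndarray:
        x = _prepare_input(img, self.net.depth)
        logits = self.net(Tensor(x)).data[0, 0]
        return (1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60))))[: img.height, : img.width]


def _prepare_input(img: GraySlice, depth: int) -> np.ndarray:
    h, w = img.pixels.shape
    mult = 2 ** depth
    ph, pw = (-h) % mult, (-w) % mult
    px = img.pixels
    if ph or pw:
        px = np.pad(px, ((0, ph), (0, pw)), mode="edge")
    return px[None, None].astype(np.float32)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    p, t = pred.astype(bool), truth.astype(bool)
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, t).sum() / denom


def train_unet(images: list[GraySlice], masks: list[LesionMask],
               config: dict | None = None) -> SegmentorModel:
    """Train a U-Net on paired slices/masks; keeps the best-val-Dice weights."""
    config = dict(config or {})
    if len(images) != len(masks):
        raise ValidationError("images and masks must be paired lists of equal length")
    if len(images) == 0:
        raise ValidationError("training list is empty")
    if all(m.pixels.sum() == 0 for m in masks):
        raise ValidationError("every training mask is empty; nothing to learn")

    depth = int(config.get("depth", 4))
    width = int(config.get("width", 32))
    epochs = int(config.get("epochs", 20))
    batch = int(config.get("batch", 8))
    lr0 = float(config.get("lr", 1e-3))
    seed = int(config.get("seed", 0))
    halve = int(config.get("lr_halve_every", 5))
    threshold = float(config.get("threshold", 0.5))
    val_fraction = float(config.get("val_fraction", 0.15))

    rng = np.random.default_rng(seed)
    n = len(images)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx = perm
    if n_val == 0:
        val_idx = perm

    net = UNet(depth=depth, width=width, seed=seed)
    opt = Adam(net.parameters(), lr=lr0)
    best = (-1.0, [p.copy() for p in net.state_arrays()])

    xs = np.stack([_prepare_input(im, depth)[0] for im in images])
    ys = np.stack([_prepare_input(GraySlice(m.pixels.astype(np.float32) * 2 - 1, m.spacing), depth)[0]
                   for m in masks])
    ys = (ys > 0).astype(np.float32)

    for epoch in range(epochs):
        opt.lr = lr_at_epoch(lr0, epoch, halve)
        order = rng.permutation(tr_idx)
        for s in range(0, len(order), batch):
            idx = order[s:s + batch]
            loss = net(Tensor(xs[idx])).bce_with_logits(ys[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
        model = SegmentorModel(net, threshold)
        dices = []
        for i in val_idx:
            prob = model.predict_proba(images[i])
            dices.append(dice_coefficient(prob >= threshold, masks[i].pixels))
        vd = float(np.mean(dices))
        if vd > best[0]:
            best = (vd, [p.copy() for p in net.state_arrays()])

    net.load_arrays(best[1])
    return SegmentorModel(net, threshold, meta={"val_dice": best[0], "depth": depth, "width": width})


def predict_lesion_mask(model: SegmentorModel, img: GraySlice) -> LesionMask:
    """Threshold the sigmoid probability map into a binary lesion mask."""
    prob = model.predict_proba(img)
    return LesionMask((prob >= model.threshold).astype(np.uint8), img.spacing)


def prepare_inference_mask(mask: LesionMask, margin_mm: float = 5.0) -> LesionMask:
    """Dilate the predicted mask by the adjacent margin (default 5 mm).

    This dilated mask is the one used by the coarse-fill and refinement
    stages and by the final composite.
    """
    return dilate_mask(mask, margin_mm)


def load_manual_annotation(path, target_shape: tuple[int, int] | None = None,
                           allow_resize: bool = True) -> LesionMask:
    """Load a manual annotation (PNG or NIfTI slice); nonzero labels -> 1."""
    from pathlib import Path

    p = Path(path)
    if p.suffix == ".png":
        mask = pio.load_mask_png(p)
    else:
        vol = pio.load_mask_volume(p)
        mask = LesionMask(vol if vol.ndim == 2 else vol[:, :, vol.shape[2] // 2])
    if target_shape is not None and mask.shape != tuple(target_shape):
        if not allow_resize:
            raise ValidationError(f"annotation shape {mask.shape} != target {target_shape}")
        from scipy import ndimage as ndi

        zoom = (target_shape[0] / mask.shape[0], target_shape[1] / mask.shape[1])
        mask = LesionMask(ndi.zoom(mask.pixels, zoom, order=0), mask.spacing)
    return mask


def save_segmentor(path, model: SegmentorModel) -> None:
    meta = {"depth": model.net.depth, "width": model.net.width,
            "in_ch": model.net.in_ch, "threshold": model.threshold}
    pio.save_checkpoint(path, "segmentor", meta, model.net.state_arrays())


def load_segmentor(path) -> SegmentorModel:
    kind, meta, arrays = pio.load_checkpoint(path)
    if kind != "segmentor":
        raise ValidationError(f"checkpoint kind {kind!r} is not a segmentor")
    net = UNet(depth=meta["depth"], width=meta["width"], in_ch=meta["in_ch"])
    net.load_arrays(arrays)
    return SegmentorModel(net, meta["threshold"], meta=meta)
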