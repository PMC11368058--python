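"""Stage 2 -- coarse inpainting ("Vague-Filler").

A straight-line residual network of gated convolutions, with no skip
connections, fills the masked region of a slice with a blurry healthy
outline.  The input image is downsampled to H/2 x W/2, then to
H/4 x W/4, processed by a chain of dilated gated blocks at the H/4
scale, and upsampled back to full resolution with a tanh output.  The
only training objective is the mean absolute error (L1) to the intact
healthy slice, which favours contour structure over texture.
"""

from __future__ import annotations

import numpy as np

from . import io as pio
from .image import GraySlice, LesionMask, ValidationError, composite
from .nn import Adam, Conv2d, GatedConv2d, Module, Tensor, concat, conv2d, lr_at_epoch

_DILATIONS = (1, 2, 4, 8, 4, 2)


class VagueFillerModel(Module):
    """Gated-conv coarse filler; `width` scales the channel plan
    width -> 2*width -> 4*width at the H/4 resolution (default 32 -> 64
    -> 128)."""

    def __init__(self, width: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        w = width
        self.g_in = GatedConv2d(2, w, 5, stride=2, rng=rng)           # H/2
        self.g_down = GatedConv2d(w, 2 * w, 3, stride=2, rng=rng)     # H/4
        self.g_widen = GatedConv2d(2 * w, 4 * w, 3, rng=rng)
        self.blocks = [GatedConv2d(4 * w, 4 * w, 3, dilation=d, rng=rng) for d in _DILATIONS]
        self.g_up = GatedConv2d(4 * w, w, 3, rng=rng)                 # after x2 upsample -> H/2
        self.head = Conv2d(w, 1, 3, act="tanh", rng=rng, gain=0.5)    # predicts at H/2
        # fixed binomial smoothing after the final nearest x2 upsample:
        # the coarse fill is band-limited at the H/2 scale by construction,
        # leaving full-resolution sharpening to the refinement stage
        k = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float32) / 16.0
        self.smooth = Tensor(k[None, None])

    def __call__(self, masked_img: Tensor, mask: Tensor) -> Tensor:
        x = concat([masked_img, mask])
        x = self.g_widen(self.g_down(self.g_in(x)))
        for blk in self.blocks:
            x = x + blk(x)  # local residual chain, straight line
        x = self.g_up(x.upsample2())
        x = self.head(x).upsample2()
        return conv2d(x, self.smooth, None, padding=1)


def vague_fill(model: VagueFillerModel, img: GraySlice, mask: LesionMask) -> GraySlice:
    """Coarse-fill the masked region; pixels outside the mask are kept.

    The network never sees masked pixels: its image channel is
    pre-multiplied by (1 - mask).
    """
    if img.pixels.shape != mask.shape:
        raise ValidationError("image and mask shapes differ")
    h, w = img.pixels.shape
    if h % 4 or w % 4:
        raise ValidationError("image dims must be divisible by 4")
    m = mask.pixels.astype(np.float32)
    x = (img.pixels * (1.0 - m))[None, None]
    out = model(Tensor(x), Tensor(m[None, None])).data[0, 0]
    return composite(img, GraySlice(out, img.spacing), mask)


def l1_loss(pred, target) -> Tensor:
    """Mean absolute difference over all pixels and batch items."""
    pred_t = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred))
    target_t = target if isinstance(target, Tensor) else Tensor(np.asarray(target))
    if pred_t.shape != target_t.shape:
        raise ValidationError("l1_loss shapes differ")
    return (pred_t - target_t).abs().mean()


def train_vague_filler(model: VagueFillerModel, healthy: list[GraySlice],
                       mask_sampler, config: dict | None = None
                       ) -> tuple[VagueFillerModel, list[float]]:
    """L1-only training against intact healthy slices.

    Per step a fresh free-form mask covering 30-60% of the brain is
    sampled by ``mask_sampler(img, seed) -> LesionMask``; Adam minimizes
    the full-image L1 to the original slice; the learning rate halves
    every 5 epochs.
    """
    config = dict(config or {})
    if len(healthy) == 0:
        raise ValidationError("no healthy slices to train on")
    epochs = int(config.get("epochs", 1))
    batch = int(config.get("batch", 4))
    lr0 = float(config.get("lr", 1e-3))
    seed = int(config.get("seed", 0))
    halve = int(config.get("lr_halve_every", 5))
    max_steps = config.get("max_steps")

    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr0)
    history: list[float] = []
    step = 0
    for epoch in range(epochs):
        opt.lr = lr_at_epoch(lr0, epoch, halve)
        order = rng.permutation(len(healthy))
        for s in range(0, len(order), batch):
            idx = order[s:s + batch]
            imgs = np.stack([healthy[i].pixels for i in idx])[:, None]
            masks = np.stack([mask_sampler(healthy[i], int(rng.integers(0, 2 ** 31 - 1))).pixels
                              for i in idx]).astype(np.float32)[:, None]
            pred = model(Tensor(imgs * (1.0 - masks)), Tensor(masks))
            loss = l1_loss(pred, Tensor(imgs))
            opt.zero_grad()
            loss.backward()
            opt.step()
            history.append(float(loss.data))
            step += 1
            if max_steps is not None and step >= int(max_steps):
                return model, history
    return model, history


def save_filler(path, model: VagueFillerModel) -> None:
    pio.save_checkpoint(path, "filler", {"width": model.width}, model.state_arrays())


def load_filler(path) -> VagueFillerModel:
    kind, meta, arrays = pio.load_checkpoint(path)
    if kind != "filler":
        raise ValidationError(f"checkpoint kind {kind!r} is not a filler")
    model = VagueFillerModel(width=meta["width"])
    model.load_arrays(arrays)
    return model
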