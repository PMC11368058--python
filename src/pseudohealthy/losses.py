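"""Adversarial and perceptual training objectives.

Hinge adversarial losses (geometric-GAN form):

    L_D = E[max(0, 1 - D(real))] + E[max(0, 1 + D(fake))]
    L_G = -E[D(fake)]

Scores beyond the +/-1 margins contribute zero gradient, which
stabilizes discriminator training.  The perceptual (texture) loss is
the L1 distance between frozen feature-extractor activations of target
and output, weighted by lambda = 64; the generator's total objective is
L_G + L_perc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ValidationError
from .nn import Conv2d, Module, SNConv2d, Tensor


class DiscriminatorModel(Module):
    """Spectral-normalized strided-conv critic; score map mean-reduced
    to one real-valued score per sample."""

    def __init__(self, width: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        w = width
        self.c1 = SNConv2d(1, w, rng=rng)
        self.c2 = SNConv2d(w, 2 * w, rng=rng)
        self.c3 = SNConv2d(2 * w, 4 * w, rng=rng)
        self.c4 = SNConv2d(4 * w, 4 * w, rng=rng)
        self.c5 = SNConv2d(4 * w, 1, k=3, stride=1, padding=1, act=None, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """(N, 1, H, W) in [-1, 1] -> (N,) scores."""
        s = self.c5(self.c4(self.c3(self.c2(self.c1(x)))))
        return s.mean(axis=3).mean(axis=2).reshape(s.shape[0])


def _to_tensor(scores) -> Tensor:
    t = scores if isinstance(scores, Tensor) else Tensor(np.atleast_1d(np.asarray(scores, dtype=np.float32)))
    if t.data.size == 0:
        raise ValidationError("empty score set")
    return t


def hinge_d_loss(real_scores, fake_scores) -> Tensor:
    """Discriminator hinge loss; zero iff all real >= 1 and all fake <= -1."""
    r, f = _to_tensor(real_scores), _to_tensor(fake_scores)
    return (1.0 - r).maximum(0.0).mean() + (1.0 + f).maximum(0.0).mean()


def hinge_g_loss(fake_scores) -> Tensor:
    """Generator hinge loss: negative mean critic score of fakes."""
    return -_to_tensor(fake_scores).mean()


class FeatureExtractor(Module):
    """Frozen multi-tap convolutional feature extractor phi.

    ``backbone="random-fixed"`` (default) is a deterministic stack of
    seeded, never-trained convolutions with average-pool stages -- a
    self-contained stand-in exposing the same interface as a pretrained
    backbone.  ``backbone="vgg16"`` loads convolution weights from a
    local ``.npz`` archive (first three blocks, taps at each pooling
    stage); grayscale input is replicated to three channels.
    """

    def __init__(self, backbone: str = "random-fixed", seed: int = 0,
                 weights_path=None):
        self.backbone = backbone
        if backbone == "random-fixed":
            rng = np.random.default_rng(seed)
            self.stages = [
                [Conv2d(1, 8, 3, act="relu", rng=rng)],
                [Conv2d(8, 16, 3, act="relu", rng=rng)],
                [Conv2d(16, 32, 3, act="relu", rng=rng)],
            ]
            self.in_ch = 1
        elif backbone == "vgg16":
            if weights_path is None:
                raise ValidationError("vgg16 backbone requires a local weights_path (.npz); "
                                      "use the 'random-fixed' backbone for a self-contained run")
            self.stages, self.in_ch = self._load_vgg(weights_path)
        else:
            raise ValidationError(f"unknown backbone {backbone!r}")
        for stage in self.stages:
            for layer in stage:
                layer.w.requires_grad = False
                layer.b.requires_grad = False

    @staticmethod
    def _load_vgg(weights_path):
        # expects conv0_w, conv0_b, ... in VGG16 order; taps after layers 1, 3, 6
        with np.load(str(weights_path)) as z:
            n = len([k for k in z.files if k.endswith("_w")])
            convs = []
            for i in range(min(n, 7)):
                w, b = z[f"conv{i}_w"], z[f"conv{i}_b"]
                layer = Conv2d(w.shape[1], w.shape[0], w.shape[2], act="relu")
                layer.w.data = np.ascontiguousarray(w, dtype=np.float32)
                layer.b.data = np.ascontiguousarray(b, dtype=np.float32)
                convs.append(layer)
        cuts = [2, 4, 7]
        stages = [convs[a:b] for a, b in zip([0] + cuts[:-1], cuts) if convs[a:b]]
        return stages, convs[0].w.data.shape[1]

    def __call__(self, x: Tensor) -> list[Tensor]:
        if self.in_ch == 3 and x.shape[1] == 1:
            from .nn import concat

            x = concat([x, x, x])
        taps = []
        for i, stage in enumerate(self.stages):
            for layer in stage:
                x = layer(x)
            taps.append(x)
            if i < len(self.stages) - 1:
                x = x.avg_pool2()
        return taps


def perceptual_loss(extractor: FeatureExtractor, target, output, lam: float = 64.0) -> Tensor:
    """lambda * mean over tap layers of L1 feature distance."""
    tt = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float32))
    ot = output if isinstance(output, Tensor) else Tensor(np.asarray(output, dtype=np.float32))
    if tt.shape != ot.shape:
        raise ValidationError("perceptual_loss shapes differ")
    taps_t = extractor(tt.detach())
    taps_o = extractor(ot)
    total = None
    for a, b in zip(taps_t, taps_o):
        d = (a - b).abs().mean()
        total = d if total is None else total + d
    return total * (lam / len(taps_t))


def generator_total_loss(g_adv: Tensor | float, perceptual: Tensor | float) -> Tensor:
    """Total generator objective: adversarial plus perceptual term."""
    g = g_adv if isinstance(g_adv, Tensor) else Tensor(np.asarray(g_adv, dtype=np.float32))
    p = perceptual if isinstance(perceptual, Tensor) else Tensor(np.asarray(perceptual, dtype=np.float32))
    if not (np.all(np.isfinite(g.data)) and np.all(np.isfinite(p.data))):
        raise ValidationError("non-finite loss term")
    return g + p


@dataclass
class LossReport:
    """Per-step loss values for the metrics log."""

    step: int
    l1: float = float("nan")
    d_loss: float = float("nan")
    g_adv: float = float("nan")
    perceptual: float = float("nan")
    lam: float = 64.0

    @property
    def total(self) -> float:
        return self.g_adv + self.perceptual

    def line(self) -> str:
        return (f"{self.step}\t{self.l1:.6f}\t{self.d_loss:.6f}\t"
                f"{self.g_adv:.6f}\t{self.perceptual:.6f}\t{self.total:.6f}")


def save_discriminator(path, model: DiscriminatorModel) -> None:
    from . import io as pio

    pio.save_checkpoint(path, "discriminator", {"width": model.width}, model.state_arrays())


def load_discriminator(path) -> DiscriminatorModel:
    from . import io as pio

    kind, meta, arrays = pio.load_checkpoint(path)
    if kind != "discriminator":
        raise ValidationError(f"checkpoint kind {kind!r} is not a discriminator")
    model = DiscriminatorModel(width=meta["width"])
    model.load_arrays(arrays)
    return model
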