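"""Training and inference pipelines, plus dataset slicing rules.

Training runs on healthy slices only: each step masks 30-60% of the
brain at random to emulate segmentor output, the Vague-Filler learns to
coarse-fill with L1 loss (phase A), then -- with the filler frozen --
the refinement generator and critic train adversarially with hinge and
perceptual losses (phase B).  Inference localizes the lesion, dilates
the mask by 5 mm, coarse-fills, refines, and composites with the input
so everything outside the dilated mask is preserved bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .filler import VagueFillerModel, l1_loss, train_vague_filler, vague_fill
from .generator import GeneratorModel, refine
from .image import GraySlice, LesionMask, ValidationError, composite, normalize_intensity
from .losses import (DiscriminatorModel, FeatureExtractor, LossReport,
                     generator_total_loss, hinge_d_loss, hinge_g_loss, perceptual_loss)
from .nn import Adam, Tensor, lr_at_epoch
from .phantoms import sample_training_mask
from .segmentor import SegmentorModel, predict_lesion_mask, prepare_inference_mask


@dataclass
class TrainedModels:
    filler: VagueFillerModel
    generator: GeneratorModel
    discriminator: DiscriminatorModel
    log: list[LossReport]


def _healthy_only(data) -> list[GraySlice]:
    """Training loader guard: reject items carrying a nonempty lesion mask."""
    out = []
    for item in data:
        if isinstance(item, tuple):
            img, mask = item
            if mask is not None and np.any(np.asarray(mask.pixels)):
                raise ValidationError("training consumes healthy images only; an item "
                                      "with a nonempty ground-truth lesion mask was rejected")
            out.append(img)
        else:
            out.append(item)
    if not out:
        raise ValidationError("no healthy slices provided")
    return out


def default_mask_sampler(cfg: RunConfig):
    def sampler(img: GraySlice, seed: int) -> LesionMask:
        return sample_training_mask(img.pixels.shape, img.foreground(),
                                    cfg.mask_ratio, seed)
    return sampler


def train_models(healthy, cfg: RunConfig | None = None,
                 filler_steps: int | None = None,
                 gan_steps: int | None = None) -> TrainedModels:
    """Two-phase training: L1-only filler, then adversarial refinement.

    ``filler_steps`` / ``gan_steps`` cap the number of optimizer steps
    per phase (otherwise ``cfg.epochs`` sweeps of the data are run).
    """
    cfg = cfg or RunConfig()
    slices = _healthy_only(healthy)
    sampler = default_mask_sampler(cfg)
    rng = np.random.default_rng(cfg.seed)
    batch = min(cfg.resolve_batch(), len(slices))

    filler = VagueFillerModel(width=cfg.filler_width, seed=cfg.seed)
    fb = min(cfg.filler_batch or batch, len(slices))
    filler, history = train_vague_filler(
        filler, slices, sampler,
        {"epochs": cfg.epochs, "batch": fb, "lr": cfg.lr, "seed": cfg.seed,
         "lr_halve_every": cfg.lr_halve_every, "max_steps": filler_steps})
    log = [LossReport(step=i, l1=v, lam=cfg.lambda_perc) for i, v in enumerate(history)]

    gen = GeneratorModel(widths=cfg.generator_widths, patch_size=cfg.patch_size,
                         use_cra=cfg.use_cra, use_flip=cfg.use_flip, seed=cfg.seed + 1)
    disc = DiscriminatorModel(width=cfg.disc_width, seed=cfg.seed + 2)
    extractor = FeatureExtractor("random-fixed", seed=cfg.seed + 3)
    opt_g = Adam(gen.parameters(), lr=cfg.lr)
    opt_d = Adam(disc.parameters(), lr=cfg.lr)

    step = 0
    done = False
    for epoch in range(cfg.epochs if gan_steps is None else 10 ** 9):
        opt_g.lr = opt_d.lr = lr_at_epoch(cfg.lr, epoch, cfg.lr_halve_every)
        order = rng.permutation(len(slices))
        for s in range(0, len(order), batch):
            idx = order[s:s + batch]
            targets, fakes = [], []
            for i in idx:
                img = slices[i]
                mask = sampler(img, int(rng.integers(0, 2 ** 31 - 1)))
                vague = vague_fill(filler, img, mask)  # filler frozen in phase B
                fakes.append(gen.forward(vague.pixels, mask))
                targets.append(img.pixels[None, None])
            fake_batch = fakes[0] if len(fakes) == 1 else _stack(fakes)
            target_batch = np.concatenate(targets)

            # -- discriminator update
            d_real = disc(Tensor(target_batch))
            d_fake = disc(fake_batch.detach())
            d_loss = hinge_d_loss(d_real, d_fake)
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # -- generator update: hinge + perceptual (lambda = 64)
            g_adv = hinge_g_loss(disc(fake_batch))
            perc = perceptual_loss(extractor, target_batch, fake_batch, lam=cfg.lambda_perc)
            total = generator_total_loss(g_adv, perc)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            log.append(LossReport(step=len(log),
                                  l1=float(np.mean(np.abs(fake_batch.data - target_batch))),
                                  d_loss=float(d_loss.data), g_adv=float(g_adv.data),
                                  perceptual=float(perc.data), lam=cfg.lambda_perc))
            step += 1
            if gan_steps is not None and step >= gan_steps:
                done = True
                break
        if done or gan_steps is None and epoch == cfg.epochs - 1:
            break
    return TrainedModels(filler, gen, disc, log)


def _stack(tensors):
    from .nn import concat

    return concat(tensors, axis=0)


def synthesize_pseudo_healthy(p: GraySlice, segmentor_or_mask,
                              filler: VagueFillerModel, gen: GeneratorModel,
                              margin_mm: float = 5.0) -> tuple[GraySlice, LesionMask]:
    """Full inference: localize -> dilate 5 mm -> coarse-fill -> refine
    -> composite.  Returns the pseudo-healthy slice and the mask used."""
    if isinstance(segmentor_or_mask, LesionMask):
        raw = segmentor_or_mask
    elif isinstance(segmentor_or_mask, SegmentorModel):
        raw = predict_lesion_mask(segmentor_or_mask, p)
    else:
        raise ValidationError("expected a SegmentorModel or a LesionMask")
    mask = prepare_inference_mask(raw, margin_mm)
    if not mask.pixels.any():
        return GraySlice(p.pixels.copy(), p.spacing), mask
    vague = vague_fill(filler, p, mask)
    out = refine(gen, vague, mask)
    return composite(p, out, mask), mask


def extract_slices(volume: np.ndarray, every_k: int, keep_predicate=None,
                   spacing: float = 1.0) -> list[GraySlice]:
    """Take axial slices at indices 0, k, 2k, ... and normalize each.

    ``keep_predicate`` (GraySlice -> bool) filters slices, e.g. the
    foreground-fraction predicate used for lung CT; None keeps all.
    """
    if every_k < 1:
        raise ValidationError("every_k must be >= 1")
    vol = np.asarray(volume)
    if vol.ndim != 3 or vol.shape[2] == 0:
        raise ValidationError("expected a non-empty 3-D volume (H, W, slices)")
    out = []
    for k in range(0, vol.shape[2], every_k):
        sl = normalize_intensity(vol[:, :, k], spacing)
        if keep_predicate is None or keep_predicate(sl):
            out.append(sl)
    return out


def foreground_fraction_predicate(min_fraction: float = 0.01):
    """Keep slices whose non-background area exceeds ``min_fraction``."""
    def pred(sl: GraySlice) -> bool:
        return sl.foreground().mean() > min_fraction
    return pred


def large_lesion_filter(masks: list[LesionMask], foregrounds: list[np.ndarray],
                        threshold: float = 0.20) -> list[int]:
    """Indices whose lesion area strictly exceeds ``threshold`` of the
    brain area (the large-lesion selection rule)."""
    if len(masks) != len(foregrounds):
        raise ValidationError("masks and foregrounds must be paired")
    keep = []
    for i, (m, fg) in enumerate(zip(masks, foregrounds)):
        n_brain = int(np.count_nonzero(fg))
        if n_brain == 0:
            raise ValidationError(f"item {i}: zero brain area")
        if np.count_nonzero(m.pixels) / n_brain > threshold:
            keep.append(i)
    return keep


def masked_l1(a: GraySlice, b: GraySlice, mask: LesionMask) -> float:
    """Mean absolute difference restricted to the masked region."""
    m = mask.pixels.astype(bool)
    if not m.any():
        return 0.0
    return float(np.mean(np.abs(a.pixels[m] - b.pixels[m])))
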