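"""Stage 3 -- refinement generator with flip-symmetric contextual
residual attention.

The vague coarse fill and the mask are encoded twice with shared
weights: once as-is and once horizontally flipped (brains are
bilaterally symmetric, so the mirrored hemisphere is a strong prior for
a lesioned one).  The Attention Calculation Module scores each path's
deepest features (PIAS for the forward path, FIAS for the flipped one),
the Attention Transfer Module fills hole patches on both paths, the
flipped-path maps are re-flipped and all four streams are fused by
convolution and decoded, with the stride-1 encoder features skipped
into a full-resolution decode stage (the refiner can synthesize the
detail the deliberately band-limited coarse filler cannot).  Inside the
mask the output is the vague fill plus the decoder's tanh-bounded
correction plus a learned-gate multiple of the aggregated
high-frequency residual transplanted from context patches; outside the
mask the input is kept bit-exactly.

Decoder and fusion kernels are width-symmetrized (and at the fusion
layer additionally symmetrized under the swap of forward/flipped
channel groups), making the whole refiner exactly equivariant to
horizontal flips of its input; when the flip path is active the
residual aggregation therefore uses the symmetrized combination of
PIAS and the mirror-permuted FIAS.
"""

from __future__ import annotations

import numpy as np

from . import io as pio
from .attention import (AttentionMatrix, aggregate_residuals, attention_scores,
                        compute_residual, mirror_scores, transfer_matrix)
from .image import (GraySlice, LesionMask, ValidationError, composite,
                    downsample_mask, extract_patches, flip_mask)
from .nn import Conv2d, Module, Tensor, concat

_DOWN_FACTOR = 4  # encoder takes H -> H/4; 16x16 image patches are 4x4 feature patches


def _patchify(t: Tensor, pf: int) -> tuple[Tensor, tuple[int, int, int]]:
    """(1, C, H, W) tensor -> (1, P, C*pf*pf) patch rows (raster order)."""
    _, c, h, w = t.shape
    gh, gw = h // pf, w // pf
    rows = (t.reshape(c, gh, pf, gw, pf)
             .transpose((1, 3, 0, 2, 4))
             .reshape(1, gh * gw, c * pf * pf))
    return rows, (c, gh, gw)


def _unpatchify(rows: Tensor, shape: tuple[int, int, int], pf: int) -> Tensor:
    c, gh, gw = shape
    return (rows.reshape(gh, gw, c, pf, pf)
                .transpose((2, 0, 3, 1, 4))
                .reshape(1, c, gh * pf, gw * pf))


class GeneratorModel(Module):
    """Refinement generator; ablation switches select plain encoder-
    decoder (`use_cra=False`), contextual residual attention
    (`use_cra=True`), and the flip-symmetric dual path (`use_flip=True`,
    which requires `use_cra`)."""

    def __init__(self, widths: tuple[int, int, int] = (16, 32, 48), patch_size: int = 16,
                 use_cra: bool = True, use_flip: bool = True, seed: int = 0):
        if use_flip and not use_cra:
            raise ValidationError("use_flip requires use_cra: the flip path exists "
                                  "only to feed the attention fusion")
        if patch_size % _DOWN_FACTOR:
            raise ValidationError("patch_size must be divisible by 4")
        rng = np.random.default_rng(seed)
        w0, w1, w2 = widths
        self.widths = tuple(widths)
        self.patch_size = patch_size
        self.use_cra, self.use_flip = use_cra, use_flip

        self.enc1 = Conv2d(2, w0, 5, act="elu", rng=rng)
        self.enc2 = Conv2d(w0, w1, 3, stride=2, act="elu", rng=rng)
        self.enc3 = Conv2d(w1, w2, 3, stride=2, act="elu", rng=rng)

        n_streams = 1 + (1 if use_cra else 0) + (2 if use_flip else 0)
        if use_flip:
            # stream order: [fA, flip(fB), tA, flip(tB)]; a horizontal flip of
            # the input swaps groups (0,1) and (2,3)
            groups = np.arange(n_streams * w2).reshape(n_streams, w2)
            perm = np.concatenate([groups[1], groups[0], groups[3], groups[2]])
            self.fuse = Conv2d(n_streams * w2, w2, 3, act="elu", rng=rng, sym_perm=perm)
            self.fuse.w.data[:, 2 * w2:] = 0.0
        else:
            self.fuse = Conv2d(n_streams * w2, w2, 3, act="elu", rng=rng, sym="width")
            if use_cra:
                self.fuse.w.data[:, w2:] = 0.0
        # attention-transfer streams enter through zero-initialized fusion
        # columns: switching CRA on never degrades the baseline function at
        # init, the streams are recruited only where they reduce the loss
        self.dec1 = Conv2d(w2, w1, 3, act="elu", rng=rng, sym="width")
        self.dec2 = Conv2d(w1, w0, 3, act="elu", rng=rng, sym="width")
        # full-resolution decode conv fed by the stride-1 encoder features
        # (both orientations when the flip path is on): the refiner can
        # synthesize detail the band-limited coarse filler cannot
        if use_flip:
            g = np.arange(3 * w0).reshape(3, w0)
            self.dec3 = Conv2d(3 * w0, w0, 3, act="elu", rng=rng,
                               sym_perm=np.concatenate([g[0], g[2], g[1]]))
        else:
            self.dec3 = Conv2d(2 * w0, w0, 3, act="elu", rng=rng, sym="width")
        # near-zero init so the merge starts from the vague fill itself
        self.head = Conv2d(w0, 1, 3, act="tanh", rng=rng, gain=0.03, sym="width")
        # learned strength of the residual transplant inside the hole
        self.res_gate = Tensor(np.float32(0.0), requires_grad=True)

    # -- internals ------------------------------------------------------
    def _encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (full-resolution features, deepest H/4 features)."""
        e1 = self.enc1(x)
        return e1, self.enc3(self.enc2(e1))

    def forward(self, vague: np.ndarray, mask: LesionMask) -> Tensor:
        """Refine one slice; returns the composited (1,1,H,W) tensor."""
        h, w = vague.shape
        if mask.shape != (h, w):
            raise ValidationError("vague image and mask shapes differ")
        if h % self.patch_size or w % self.patch_size:
            raise ValidationError("dims must be divisible by the patch size; resize first")
        m = mask.pixels.astype(np.float32)
        x = np.stack([vague.astype(np.float32), m])[None]
        e1a, fa = self._encode(Tensor(x))
        pf = self.patch_size // _DOWN_FACTOR
        mask_f = downsample_mask(mask, _DOWN_FACTOR)
        ps_a = extract_patches(fa.data[0], pf, mask_f)
        grid = ps_a.grid
        # attention needs at least one hole patch and one context patch
        attend = self.use_cra and bool(ps_a.inside.any()) and ps_a.n_outside > 0

        am_a = am_res = None
        if attend:
            am_a = attention_scores(ps_a, "PIAS")
            am_res = am_a

        streams = [fa]
        e1b = None
        if self.use_flip:
            e1b, fb = self._encode(Tensor(x[..., ::-1].copy()))
            streams.append(fb.flip_w())
        if self.use_cra:
            streams.append(self._transfer(fa, am_a, pf) if attend else fa)
            if self.use_flip:
                if attend:
                    ps_b = extract_patches(fb.data[0], pf, flip_mask(mask_f))
                    am_b = attention_scores(ps_b, "FIAS")
                    streams.append(self._transfer(fb, am_b, pf).flip_w())
                    mirrored = mirror_scores(am_b, grid, "PIAS")
                    am_res = AttentionMatrix(0.5 * (am_a.affinity + mirrored.affinity),
                                             0.5 * (am_a.scores + mirrored.scores),
                                             am_a.inside, "PIAS")
                else:
                    streams.append(fb.flip_w())

        y = self.fuse(concat(streams))
        y = self.dec1(y).upsample2()
        y = self.dec2(y).upsample2()
        if self.use_flip:
            y = self.dec3(concat([y, e1a, e1b.flip_w()]))
        else:
            y = self.dec3(concat([y, e1a]))
        y = self.head(y)

        # merge: the vague fill is the base inside the hole (long skip),
        # the aggregated residual transplants high-frequency context
        # texture weighted by a learned gate, and the decoder contributes
        # a tanh-bounded correction
        base = vague.astype(np.float64).copy()
        if attend:
            res = compute_residual(GraySlice(vague), _DOWN_FACTOR)
            r_agg = aggregate_residuals(res, am_res, mask, self.patch_size)
            y = y + self.res_gate * Tensor(((r_agg - res) * m)[None, None])
        y = y + Tensor((base * m)[None, None])
        # composite: input kept bit-exactly outside the mask
        return Tensor((vague * (1.0 - m))[None, None]) + y * Tensor(m[None, None])

    def _transfer(self, feat: Tensor, am: AttentionMatrix, pf: int) -> Tensor:
        rows, shape = _patchify(feat, pf)
        return _unpatchify(rows.apply_patch_matrix(transfer_matrix(am)), shape, pf)


def refine(model: GeneratorModel, vague: GraySlice, mask: LesionMask) -> GraySlice:
    """Refine a vague coarse fill into a sharper pseudo-healthy slice."""
    out = model.forward(vague.pixels, mask).data[0, 0]
    refined = GraySlice(np.clip(out, -1, 1), vague.spacing)
    return composite(vague, refined, mask)


def save_generator(path, model: GeneratorModel) -> None:
    meta = {"widths": list(model.widths), "patch_size": model.patch_size,
            "use_cra": model.use_cra, "use_flip": model.use_flip}
    pio.save_checkpoint(path, "generator", meta, model.state_arrays())


def load_generator(path) -> GeneratorModel:
    kind, meta, arrays = pio.load_checkpoint(path)
    if kind != "generator":
        raise ValidationError(f"checkpoint kind {kind!r} is not a generator")
    model = GeneratorModel(widths=tuple(meta["widths"]), patch_size=meta["patch_size"],
                           use_cra=meta["use_cra"], use_flip=meta["use_flip"])
    model.load_arrays(arrays)
    return model
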