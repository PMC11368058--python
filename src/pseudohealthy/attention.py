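"""Contextual attention: patch affinity scores, attention transfer and
contextual residual aggregation.

The Attention Calculation Module (ACM) measures cosine similarity
between every context patch b_i (outside the mask) and every hole patch
b_j (inside the mask),

    c_{i,j} = < b_i/||b_i||, b_j/||b_j|| >,

squares and normalizes the affinities into attention scores

    s_{i,j} = c_{i,j}^2 / sum_{i'} c_{i',j}^2,

so each hole column is a convex weighting over context patches.  The
Attention Transfer Module (ATM) fills hole patches with the weighted
sum of context patches; contextual residual aggregation applies the
same scores to full-resolution high-frequency residual patches so fine
texture is transplanted into the hole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GraySlice, LesionMask, PatchSet, ValidationError, extract_patches, scatter_patches

_EPS = 1e-8


@dataclass
class AttentionMatrix:
    """All-pairs patch affinities (c) and normalized scores (s).

    ``s[i, j]`` is nonzero only for context row i and hole column j; for
    every hole column the scores over context rows sum to 1.
    """

    affinity: np.ndarray   # (P, P) cosine similarities
    scores: np.ndarray     # (P, P) squared-normalized, column-stochastic over outside rows
    inside: np.ndarray     # (P,) bool labels
    orientation: str = "PIAS"

    @property
    def n_patches(self) -> int:
        return self.scores.shape[0]


def attention_scores(ps: PatchSet, orientation: str = "PIAS") -> AttentionMatrix:
    """ACM: cosine affinities squared and normalized per hole column."""
    if ps.n_outside < 1:
        raise ValidationError("attention undefined: no patches outside the mask")
    flat = ps.flat().astype(np.float64)
    norms = np.maximum(np.linalg.norm(flat, axis=1), _EPS)
    unit = flat / norms[:, None]
    aff = unit @ unit.T
    p = ps.n_patches
    outside = ~ps.inside
    scores = np.zeros((p, p))
    if ps.inside.any():
        sq = aff[outside][:, ps.inside] ** 2
        denom = sq.sum(axis=0)
        n_out = int(outside.sum())
        cols = np.where(denom > _EPS, 1.0, 0.0)
        safe = np.where(denom > _EPS, denom, 1.0)
        w = sq / safe
        # all-zero affinity column: fall back to uniform weights over context
        w = w * cols + (1.0 - cols) / n_out
        tmp = np.zeros((n_out, p))
        tmp[:, ps.inside] = w
        scores[outside] = tmp
    return AttentionMatrix(aff, scores, ps.inside.copy(), orientation)


def attention_transfer(ps: PatchSet, am: AttentionMatrix) -> PatchSet:
    """ATM: replace each hole patch by its score-weighted context sum."""
    if am.n_patches != ps.n_patches:
        raise ValidationError("score matrix does not match the patch count")
    patches = ps.patches.copy()
    if ps.inside.any():
        flat = ps.flat()
        filled = am.scores[:, ps.inside].T.astype(np.float32) @ flat  # (n_in, D)
        patches[ps.inside] = filled.reshape(-1, ps.channels, ps.patch_size, ps.patch_size)
    return PatchSet(ps.patch_size, patches, ps.inside.copy(), ps.grid, ps.channels)


def transfer_matrix(am: AttentionMatrix) -> np.ndarray:
    """(P, P) linear operator: identity on context rows, scores on hole rows."""
    p = am.n_patches
    t = np.zeros((p, p), dtype=np.float32)
    t[~am.inside, ~am.inside] = 1.0
    t[am.inside] = am.scores[:, am.inside].T
    return t


def compute_residual(img: GraySlice, factor: int = 4) -> np.ndarray:
    """High-frequency residual: image minus up(down(image)).

    Down/up use block-average and nearest-repeat at integer factors, so
    the operation is exactly equivariant to horizontal flips.
    """
    h, w = img.pixels.shape
    if h % factor or w % factor:
        raise ValidationError("image dims must be divisible by the residual factor")
    px = img.pixels.astype(np.float64)
    low = px.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))
    blur = low.repeat(factor, axis=0).repeat(factor, axis=1)
    return (px - blur).astype(np.float32)


def aggregate_residuals(residual: np.ndarray, am: AttentionMatrix,
                        mask: LesionMask, patch_size: int) -> np.ndarray:
    """Fill hole residual patches with score-weighted context residuals."""
    ps = extract_patches(residual, patch_size, mask)
    if ps.n_patches != am.n_patches:
        raise ValidationError("residual patch grid does not match the score matrix")
    if not np.array_equal(ps.inside, am.inside):
        raise ValidationError("mask labels disagree with the score matrix labels")
    return scatter_patches(attention_transfer(ps, am))[0]


def mirror_permutation(grid: tuple[int, int]) -> np.ndarray:
    """Patch-index permutation induced by a horizontal image flip."""
    gh, gw = grid
    idx = np.arange(gh * gw).reshape(gh, gw)[:, ::-1]
    return idx.reshape(-1)


def mirror_scores(am: AttentionMatrix, grid: tuple[int, int], orientation: str) -> AttentionMatrix:
    """Re-express a flipped-frame score matrix in the unflipped frame."""
    perm = mirror_permutation(grid)
    return AttentionMatrix(am.affinity[np.ix_(perm, perm)],
                           am.scores[np.ix_(perm, perm)],
                           am.inside[perm], orientation)
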