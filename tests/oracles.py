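"""Shared brute-force references and stubs used across test modules."""

import numpy as np

from pseudohealthy import GraySlice

EPS = 1e-8


def brute_force_scores(ps):
    """Nested-loop reference for affinity and squared-normalized scores."""
    flat = ps.flat().astype(np.float64)
    p = ps.n_patches
    c = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            ni = max(np.linalg.norm(flat[i]), EPS)
            nj = max(np.linalg.norm(flat[j]), EPS)
            c[i, j] = float(flat[i] @ flat[j]) / (ni * nj)
    s = np.zeros((p, p))
    outside = [i for i in range(p) if not ps.inside[i]]
    for j in range(p):
        if not ps.inside[j]:
            continue
        denom = sum(c[i, j] ** 2 for i in outside)
        for i in outside:
            s[i, j] = (c[i, j] ** 2 / denom) if denom > EPS else 1.0 / len(outside)
    return c, s


def brute_force_transfer(ps, s):
    """Nested-loop reference for attention transfer."""
    patches = ps.patches.astype(np.float64).copy()
    for j in range(ps.n_patches):
        if not ps.inside[j]:
            continue
        acc = np.zeros_like(patches[j])
        for i in range(ps.n_patches):
            if not ps.inside[i]:
                acc += s[i, j] * patches[i]
        patches[j] = acc
    return patches


class StubSegmentor:
    """Returns probability maps with a prescribed count of hot pixels."""

    threshold = 0.5

    def __init__(self, counts):
        self.counts = list(counts)

    def predict_proba(self, img):
        n = self.counts.pop(0)
        out = np.zeros(img.pixels.shape)
        out.flat[:n] = 1.0
        return out


class StubClassifier:
    def __init__(self, probs):
        self.probs = list(probs)

    def predict_proba(self, edge_map):
        return self.probs.pop(0)


def flat_slice(value=0.0, shape=(32, 32)):
    return GraySlice(np.full(shape, value, dtype=np.float32))
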