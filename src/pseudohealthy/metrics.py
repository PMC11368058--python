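"""Evaluation suite: Healthiness, masked PSNR/SSIM, Structure Healthiness.

* Healthiness ``H = 1 - E[N(f_p(output))] / E[N(f_p(input))]`` compares
  mean pathological-pixel counts found by a segmentation model in the
  synthesized outputs against those found in the pathological inputs
  (the model's own prediction of the input is used, not the ground-truth
  mask, to cancel segmentor bias).  H = 1 means no residual pathology.
* Identity preservation: PSNR and SSIM between output and input with the
  pathological region zeroed on both sides -- masked PSNR is computed
  over the mask complement on the [0, 1] scale with a 99 dB cap.
* Structure Healthiness: the mean probability, from a binary classifier
  on Canny edge maps, that outputs generated from large-lesion inputs
  are free of structural deformation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.metrics import structural_similarity

from . import io as pio
from .image import GraySlice, LesionMask, ValidationError
from .nn import Adam, Conv2d, Module, Tensor
from .segmentor import SegmentorModel, predict_lesion_mask


def healthiness(outputs: list[GraySlice], inputs: list[GraySlice],
                f_p: SegmentorModel) -> float:
    """1 minus the ratio of mean pathological-pixel counts (ratio of means)."""
    if len(outputs) != len(inputs) or not outputs:
        raise ValidationError("outputs and inputs must be nonempty paired lists")
    n_out = [int(predict_lesion_mask(f_p, o).pixels.sum()) for o in outputs]
    n_in = [int(predict_lesion_mask(f_p, x).pixels.sum()) for x in inputs]
    denom = float(np.mean(n_in))
    if denom <= 0:
        raise ValidationError("segmentor finds no pathology in the inputs; H undefined")
    return 1.0 - float(np.mean(n_out)) / denom


def _to01(img: GraySlice) -> np.ndarray:
    return (img.pixels.astype(np.float64) + 1.0) / 2.0


def masked_psnr(output: GraySlice, input_: GraySlice, mask: LesionMask,
                cap: float = 99.0) -> float:
    """PSNR over the mask complement on the [0, 1] scale (peak = 1)."""
    if output.pixels.shape != input_.pixels.shape or output.pixels.shape != mask.shape:
        raise ValidationError("shape mismatch")
    keep = ~mask.pixels.astype(bool)
    if not keep.any():
        raise ValidationError("mask covers the whole image; nothing to compare")
    diff = _to01(output)[keep] - _to01(input_)[keep]
    mse = float(np.mean(diff * diff))
    if mse <= 0:
        return cap
    return min(cap, 10.0 * np.log10(1.0 / mse))


def masked_ssim(output: GraySlice, input_: GraySlice, mask: LesionMask) -> float:
    """SSIM between the two images with the masked region zeroed on both
    sides (Gaussian 11x11 window, sigma 1.5, standard stabilizers)."""
    if output.pixels.shape != input_.pixels.shape or output.pixels.shape != mask.shape:
        raise ValidationError("shape mismatch")
    if min(output.pixels.shape) < 11:
        raise ValidationError("image smaller than the 11x11 SSIM window")
    keep = (~mask.pixels.astype(bool)).astype(np.float64)
    return float(structural_similarity(
        _to01(output) * keep, _to01(input_) * keep, win_size=11,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        data_range=1.0))


def canny_edges(img: GraySlice) -> np.ndarray:
    """Binary Canny edge map (sigma 1, hysteresis at the 10th/30th
    gradient-magnitude percentiles); constant images yield no edges."""
    px = img.pixels.astype(np.float64)
    if np.ptp(px) <= 0:
        return np.zeros(px.shape, dtype=bool)
    return canny(px, sigma=1.0, low_threshold=0.10, high_threshold=0.30,
                 use_quantiles=True)


class _EdgeNet(Module):
    """VGG-style stack of small strided convolutions with a scalar
    deformation-free logit."""

    def __init__(self, width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        w = width
        self.c1 = Conv2d(1, w, 3, stride=2, act="relu", rng=rng)
        self.c2 = Conv2d(w, 2 * w, 3, stride=2, act="relu", rng=rng)
        self.c3 = Conv2d(2 * w, 4 * w, 3, stride=2, act="relu", rng=rng)
        self.head = Conv2d(4 * w, 1, 1, padding=0, rng=rng, gain=0.5)

    def __call__(self, x: Tensor) -> Tensor:
        s = self.head(self.c3(self.c2(self.c1(x))))
        return s.mean(axis=3).mean(axis=2).reshape(s.shape[0])


@dataclass
class EdgeClassifier:
    """Binary classifier on Canny edge maps; outputs the probability
    that an edge map is free of deformation."""

    net: _EdgeNet
    meta: dict

    def predict_proba(self, edge_map: np.ndarray) -> float:
        x = np.asarray(edge_map, dtype=np.float32)[None, None]
        logit = float(self.net(Tensor(x)).data[0])
        return float(1.0 / (1.0 + np.exp(-np.clip(logit, -60, 60))))


def train_deformation_classifier(healthy_edges: list[np.ndarray],
                                 deformed_edges: list[np.ndarray],
                                 config: dict | None = None) -> EdgeClassifier:
    """Train the edge-map classifier with binary cross-entropy.

    Label 1 = deformation-free (healthy), 0 = deformed.  Held-out
    accuracy on a seeded split is reported in ``meta['accuracy']``.
    """
    config = dict(config or {})
    if not healthy_edges or not deformed_edges:
        raise ValidationError("both classes must be nonempty")
    width = int(config.get("width", 8))
    epochs = int(config.get("epochs", 10))
    batch = int(config.get("batch", 16))
    lr = float(config.get("lr", 1e-3))
    seed = int(config.get("seed", 0))
    val_fraction = float(config.get("val_fraction", 0.2))

    xs = np.stack([np.asarray(e, dtype=np.float32) for e in healthy_edges + deformed_edges])[:, None]
    ys = np.concatenate([np.ones(len(healthy_edges)), np.zeros(len(deformed_edges))]).astype(np.float32)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ys))
    n_val = max(1, int(round(val_fraction * len(ys))))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    net = _EdgeNet(width=width, seed=seed)
    opt = Adam(net.parameters(), lr=lr)
    for _ in range(epochs):
        order = rng.permutation(tr_idx)
        for s in range(0, len(order), batch):
            idx = order[s:s + batch]
            loss = net(Tensor(xs[idx])).bce_with_logits(ys[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()

    logits = np.concatenate([net(Tensor(xs[val_idx[s:s + 64]])).data
                             for s in range(0, len(val_idx), 64)])
    acc = float(np.mean((logits > 0) == (ys[val_idx] > 0.5)))
    return EdgeClassifier(net, meta={"accuracy": acc, "width": width})


def structure_healthiness(outputs: list[GraySlice], classifier: EdgeClassifier) -> float:
    """Mean deformation-free probability over outputs synthesized from
    large-lesion inputs."""
    if not outputs:
        raise ValidationError("empty large-lesion output set")
    probs = [classifier.predict_proba(canny_edges(o)) for o in outputs]
    return float(np.mean(probs))


@dataclass
class MetricReport:
    healthiness: float
    mpsnr: float
    mssim: float
    sh: float
    n_images: int
    n_large_lesion: int

    def __post_init__(self):
        if not (0.0 <= self.sh <= 1.0) and not np.isnan(self.sh):
            raise ValidationError("SH must lie in [0, 1]")
        if self.mssim > 1.0 + 1e-9:
            raise ValidationError("SSIM cannot exceed 1")

    def to_dict(self) -> dict:
        return {"healthiness": self.healthiness, "mpsnr": self.mpsnr,
                "mssim": self.mssim, "sh": self.sh,
                "n_images": self.n_images, "n_large_lesion": self.n_large_lesion}


def evaluate(outputs: list[GraySlice], inputs: list[GraySlice],
             masks: list[LesionMask], f_p: SegmentorModel,
             classifier: EdgeClassifier | None = None,
             large_lesion_threshold: float = 0.20) -> MetricReport:
    """Full metric suite over paired outputs/inputs/masks."""
    from .pipelines import large_lesion_filter

    h = healthiness(outputs, inputs, f_p)
    mp = float(np.mean([masked_psnr(o, x, m) for o, x, m in zip(outputs, inputs, masks)]))
    ms = float(np.mean([masked_ssim(o, x, m) for o, x, m in zip(outputs, inputs, masks)]))
    fgs = [x.foreground() for x in inputs]
    big = large_lesion_filter(masks, fgs, large_lesion_threshold)
    if classifier is not None and big:
        sh = structure_healthiness([outputs[i] for i in big], classifier)
    else:
        sh = float("nan")
    return MetricReport(h, mp, ms, sh, len(outputs), len(big))


def save_edge_classifier(path, clf: EdgeClassifier) -> None:
    pio.save_checkpoint(path, "edge-classifier", clf.meta, clf.net.state_arrays())


def load_edge_classifier(path) -> EdgeClassifier:
    kind, meta, arrays = pio.load_checkpoint(path)
    if kind != "edge-classifier":
        raise ValidationError(f"checkpoint kind {kind!r} is not an edge classifier")
    net = _EdgeNet(width=meta["width"])
    net.load_arrays(arrays)
    return EdgeClassifier(net, meta)
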