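"""Run configuration and the flat key:value config-file format."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path


@dataclass
class RunConfig:
    """Defaults mirror the published training recipe: masks covering
    30-60% of the brain, a 5 mm inference margin, 16x16 attention
    patches, perceptual weight 64, Adam at 0.001 halved every 5 epochs,
    batch 16 for 240/256-px slices and 4 for 512-px slices."""

    seed: int = 0
    image_size: int = 256
    mask_ratio: tuple[float, float] = (0.30, 0.60)
    margin_mm: float = 5.0
    patch_size: int = 16
    lambda_perc: float = 64.0
    lr: float = 1e-3
    lr_halve_every: int = 5
    batch: int | None = None
    filler_batch: int | None = None  # phase-A batch; defaults to `batch`
    epochs: int = 10
    use_cra: bool = True
    use_flip: bool = True
    filler_width: int = 32
    generator_widths: tuple[int, int, int] = (16, 32, 48)
    disc_width: int = 32
    extra: dict = field(default_factory=dict)

    def resolve_batch(self) -> int:
        if self.batch is not None:
            return self.batch
        return 4 if self.image_size >= 512 else 16


def _convert(value: str):
    v = value.strip()
    low = v.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    if "," in v:
        return tuple(_convert(p) for p in v.split(","))
    return v


def parse_config_file(path) -> dict:
    """Flat ``key: value`` text, nesting by dots, '#' comments."""
    out: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, value = line.split(":", 1)
        out[key.strip()] = _convert(value)
    return out


def make_run_config(file_values: dict | None = None, **overrides) -> RunConfig:
    """Merge precedence: defaults < config file < explicit flags."""
    known = {f.name for f in fields(RunConfig)}
    merged: dict = {}
    extra: dict = {}
    for src in (file_values or {}), {k: v for k, v in overrides.items() if v is not None}:
        for k, v in src.items():
            (merged if k in known else extra)[k] = v
    cfg = RunConfig(**merged)
    cfg.extra.update(extra)
    return cfg
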