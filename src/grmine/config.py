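"""Flat key=value pipeline configuration.

One namespace collects every stage's tunables with their reference
defaults (promoter window 400 nt, scan p-value 1e-4, core-target
prevalence 0.5 over >= 2 genera with a top-5 fallback, putative-GR rule
>= 10 targets over >= 2 genomes, lr 1e-6 with 1,000-batch warm-up,
gradient clip 100, weight decay 0.1, dropout 0.4, 5x TF weight). The file
format is deliberately parser-free: one ``key = value`` per line, ``#``
comments; unknown keys are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    # motif scanning
    window: int = 400
    p_threshold: float = 1e-4
    pseudocount: float = 0.1
    short_motif_width: int = 6
    symmetry_threshold: float = 0.6
    # regulon / network
    min_frac: float = 0.5
    min_genera: int = 2
    fallback_k: int = 5
    putative_min_targets: int = 10
    putative_min_genomes: int = 2
    # training
    lr: float = 1e-6
    warmup_batches: int = 1000
    clip_norm: float = 100.0
    weight_decay: float = 0.1
    dropout: float = 0.4
    tf_weight: float = 5.0
    neg_per_pos: float = 1.0
    batch_size: int = 32
    epochs: int = 10
    threshold: float = 0.5
    # backend + head
    backend: str = "stub"
    backend_k: int = 3
    backend_dim: int = 32
    model_dim: int = 512
    n_layers: int = 12
    n_heads: int = 8
    head_dim: int = 64
    ffn_dim: int = 512
    max_len: int = 1024
    seed: int = 0


_FIELD_TYPES = {f.name: f.type for f in fields(PipelineConfig)}


def _coerce(name: str, raw: str):
    current = getattr(PipelineConfig(), name)
    if isinstance(current, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw


def load_config(
    path: str | Path | None = None,
    defaults: dict | None = None,
    **overrides,
) -> PipelineConfig:
    """Read a flat key=value file (optional) and apply keyword overrides.

    ``defaults`` are soft values applied before the file (the file and
    explicit overrides win). Unknown keys raise ``ValueError``; overrides
    with value ``None`` are ignored so CLI flags can pass through unset
    options.
    """
    values: dict = {}
    for key, value in (defaults or {}).items():
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = value
    if path is not None:
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected key = value")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}:{line_no}: unknown config key {key!r}")
            values[key] = _coerce(key, raw)
    for key, value in overrides.items():
        if value is None:
            continue
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = value
    return replace(PipelineConfig(), **values)
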