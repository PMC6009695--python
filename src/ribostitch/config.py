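"""Pipeline configuration: defaults, config-file parsing, flag overrides."""

from __future__ import annotations

import dataclasses
from pathlib import Path


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable knob of the pipeline, with its default value.

    Config files are flat ``key = value`` text; keys mirror CLI flags
    (dashes or underscores both accepted). Flags override file values.
    """

    # clustering / region extraction
    flank: int = 1000
    # seeding
    iterations: int = 3
    spacer: int = 1000
    min_length: int = 6000       # pseudocontig QC: shorter => too_short
    max_factor: float = 3.0      # pseudocontig QC: > max_factor * expected => too_long
    trust_identity: float = 0.8  # partition mean identity below this => untrusted
    # mapping
    min_identity: float = 0.8
    map_k: int = 21
    max_seed_hits: int = 50
    # alignment scoring (mapper and flank matcher)
    match: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -1
    band: int = 15
    # assembly
    k: int = 0                   # 0 => auto from read length
    min_kmer_count: int = 2
    bubble_identity: float = 0.9
    # scoring
    score_min_identity: float = 0.95
    score_min_coverage: float = 0.5
    min_extension: float = 0.9
    span_tolerance: float = 0.2
    # annotate detector
    detect_k: int = 31
    detect_density: float = 0.5
    detect_min_fraction: float = 0.8
    # diagnostics
    entropy_window: int = 351
    stack_samples: int = 10
    stack_flag_ratio: float = 1.5
    # general
    seed: int = 0

    def validate(self) -> None:
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.flank < 0:
            raise ConfigError("flank must be >= 0")
        if not 0.0 <= self.trust_identity <= 1.0:
            raise ConfigError("trust_identity must be in [0, 1]")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ConfigError("min_identity must be in [0, 1]")
        if self.k and (self.k % 2 == 0 or self.k < 11):
            raise ConfigError("k must be odd and >= 11 (or 0 for auto)")


class ConfigError(ValueError):
    """Invalid configuration key or value."""


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def _coerce(name: str, raw: str):
    field = _FIELDS[name]
    if field.type in ("int", int):
        return int(raw)
    if field.type in ("float", float):
        return float(raw)
    return raw


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig`.

    ``path`` points at a flat key/value file (``key = value`` per line,
    ``#`` comments). Keyword ``overrides`` (from CLI flags) win over file
    values; ``None`` overrides are ignored. Unknown keys raise
    :class:`ConfigError` listing the valid keys.
    """
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (part.strip() for part in line.split("=", 1))
            key = key.replace("-", "_")
            if key not in _FIELDS:
                raise ConfigError(
                    f"unknown config key {key!r}; valid keys: "
                    + ", ".join(sorted(_FIELDS))
                )
            values[key] = _coerce(key, raw)
    for key, val in overrides.items():
        if val is None:
            continue
        key = key.replace("-", "_")
        if key not in _FIELDS:
            raise ConfigError(
                f"unknown config key {key!r}; valid keys: "
                + ", ".join(sorted(_FIELDS))
            )
        values[key] = val
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg


def auto_k(read_length: int) -> int:
    """Assembly k-mer size for a given read length: min(127, ~0.55*L), odd."""
    k = min(127, int(0.55 * read_length))
    if k % 2 == 0:
        k -= 1
    return max(k, 21)
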