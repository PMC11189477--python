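"""Plain-text ``key = value`` configuration for the pipeline and simulator.

Unknown keys are rejected so typos cannot silently fall back to defaults;
values are coerced to the types declared on the target dataclass.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, get_args, get_origin

from .phasing import (
    DEFAULT_CONSENSUS_FRACTION,
    DEFAULT_INTERVAL_BP,
    DEFAULT_MIN_EVENT_SPACING_BP,
    DEFAULT_MIN_MARKER_CONFIDENCE,
    DEFAULT_MIN_POPULATION,
    DEFAULT_MIN_SUPPORT,
    DEFAULT_TOLERANCE_BP,
    DEFAULT_WINDOW,
)
from .simdata import SimConfig


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable of the filter->matrix->phase->map pipeline plus paths."""

    sites_vcf: str = ""
    calls_dir: str = ""
    outdir: str = "gametophase_out"
    reads: str = ""  # optional long reads for haplotype partitioning
    reference_fasta: str = ""  # reference for marker probes
    phenotypes: str = ""  # optional phenotype TSV for the QTL scan
    min_quality: float = 30.0
    min_minor_depth: int = 5
    quality_from: str = "qual"  # "qual" | "gq"
    window: int = DEFAULT_WINDOW
    min_support: int = DEFAULT_MIN_SUPPORT
    consensus_fraction: float = DEFAULT_CONSENSUS_FRACTION
    tolerance_bp: float = DEFAULT_TOLERANCE_BP
    min_population: int = DEFAULT_MIN_POPULATION
    interval_bp: int = DEFAULT_INTERVAL_BP
    min_event_spacing_bp: float = DEFAULT_MIN_EVENT_SPACING_BP
    min_marker_confidence: float = DEFAULT_MIN_MARKER_CONFIDENCE
    flank_bp: int = 10
    min_margin: int = 1
    min_ratio: float = 0.3
    kmer_k: int = 31
    min_shared: int = 10
    walk_cm: float = 1.0
    window_cm: float = 10.0
    lod_threshold: float = 2.5
    max_cofactors: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 <= self.consensus_fraction <= 1.0:
            raise ConfigError("consensus_fraction must lie in [0, 1]")
        if not 0.0 <= self.min_marker_confidence <= 1.0:
            raise ConfigError("min_marker_confidence must lie in [0, 1]")
        if self.quality_from not in ("qual", "gq"):
            raise ConfigError("quality_from must be 'qual' or 'gq'")
        for name in ("window", "min_support", "interval_bp", "flank_bp", "kmer_k"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")


def parse_keyvalue(path) -> dict[str, str]:
    """Parse ``key = value`` lines; '#' starts a comment; blanks ignored."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in out:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        out[key] = value
    return out


def _coerce(value: str, typ: Any) -> Any:
    origin = get_origin(typ)
    if origin is not None and type(None) in get_args(typ):  # Optional[...]
        if value.lower() in ("", "none"):
            return None
        inner = [t for t in get_args(typ) if t is not type(None)][0]
        return _coerce(value, inner)
    if origin is tuple or typ is tuple:
        parts = [p.strip() for p in value.replace(":", ",").split(",")]
        args = get_args(typ) or (str, str)
        return tuple(_coerce(p, t) for p, t in zip(parts, args))
    if typ is bool:
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"cannot parse boolean from {value!r}")
    if typ is int:
        return int(float(value)) if "e" in value.lower() or "." in value else int(value)
    if typ is float:
        return float(value)
    return value


def _from_mapping(cls, mapping: dict[str, str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    import typing

    hints = typing.get_type_hints(cls)
    kwargs = {k: _coerce(v, hints[k]) for k, v in mapping.items()}
    return cls(**kwargs)


def load_pipeline_config(path) -> PipelineConfig:
    return _from_mapping(PipelineConfig, parse_keyvalue(path))


def load_sim_config(path) -> SimConfig:
    return _from_mapping(SimConfig, parse_keyvalue(path))
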