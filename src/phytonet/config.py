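"""YAML run configuration with fail-closed parsing.

Unknown keys are rejected (with a did-you-mean suggestion) so that a
misspelled parameter can never be silently ignored; every default matches
the platform's analysis contract (FDR < 0.05 for ORA, |NES| > 1.0 with
FDR < 0.25 for GSEA, 1000 permutations, 1000 null networks, hub degree 5).
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    relationships: str = ""
    gene_sets: list[str] = field(default_factory=list)
    expression: Optional[str] = None
    preranked: Optional[str] = None
    run_ora: bool = True
    run_gsea: bool = True
    run_gsva: bool = True           # skipped (with reason) if no expression
    n_perm: int = 1000
    n_random: int = 1000
    ora_min_size: int = 3
    gsea_min_size: int = 3
    gsva_min_size: int = 15
    gsva_max_size: int = 500
    fdr_threshold: float = 0.05
    nes_threshold: float = 1.0
    gsea_fdr_threshold: float = 0.25
    hub_degree: int = 5
    resolution: float = 1.0
    gsea_weight: float = 1.0
    weight_by_frequency: bool = False
    seed: Optional[int] = None
    output_root: str = "phytonet_results"
    skip_figures: bool = False
    overwrite: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)


_TYPES = {
    str: "string", int: "integer", float: "number", bool: "boolean",
}


def _check_type(key: str, value, ftype) -> object:
    origin = getattr(ftype, "__origin__", None)
    if ftype is Optional[str] or ftype == Optional[str]:
        if value is None or isinstance(value, str):
            return value
        raise ConfigError(f"key {key!r}: expected string or null, "
                          f"got {type(value).__name__}")
    if ftype is Optional[int] or ftype == Optional[int]:
        if value is None or (isinstance(value, int)
                             and not isinstance(value, bool)):
            return value
        raise ConfigError(f"key {key!r}: expected integer or null")
    if origin is list or ftype == list[str]:
        if isinstance(value, str):
            return [value]
        if isinstance(value, list) and all(isinstance(v, str) for v in value):
            return value
        raise ConfigError(f"key {key!r}: expected a list of strings")
    if ftype is bool:
        if isinstance(value, bool):
            return value
        raise ConfigError(f"key {key!r}: expected boolean, "
                          f"got {type(value).__name__}")
    if ftype is int:
        if isinstance(value, int) and not isinstance(value, bool):
            return value
        raise ConfigError(f"key {key!r}: expected integer, "
                          f"got {type(value).__name__}")
    if ftype is float:
        if isinstance(value, (int, float)) and not isinstance(value, bool):
            return float(value)
        raise ConfigError(f"key {key!r}: expected number, "
                          f"got {type(value).__name__}")
    if ftype is str:
        if isinstance(value, str):
            return value
        raise ConfigError(f"key {key!r}: expected string, "
                          f"got {type(value).__name__}")
    return value


def config_from_mapping(data: dict) -> RunConfig:
    known = {f.name: f.type for f in fields(RunConfig)}
    # dataclass field types may be strings under from __future__ annotations
    import typing
    hints = typing.get_type_hints(RunConfig)
    cfg = RunConfig()
    for key, value in data.items():
        if key not in known:
            hint = difflib.get_close_matches(key, known, n=1)
            extra = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown configuration key {key!r}{extra}")
        setattr(cfg, key, _check_type(key, value, hints[key]))
    if not cfg.relationships:
        raise ConfigError("'relationships' (input CSV path) is required")
    return cfg


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML configuration file, filling defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a YAML mapping")
    return config_from_mapping(raw)
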