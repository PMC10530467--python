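"""Typed run configuration with YAML loading and path validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import yaml

from .errors import ConfigError

__all__ = ["RunConfig"]

_PATH_KEYS = (
    "vcf",
    "ped",
    "panel",
    "variants_table",
    "scores_table",
    "regulatory_table",
    "edge_db",
    "term_db",
    "background",
)


@dataclass
class RunConfig:
    vcf: Path
    ped: Path
    panel: Path
    variants_table: Optional[Path] = None
    scores_table: Optional[Path] = None
    regulatory_table: Optional[Path] = None
    edge_db: Optional[Path] = None
    term_db: Optional[Path] = None
    background: Optional[Path] = None

    maf_max: float = 0.04
    qual_min: float = 30.0
    votes_min: int = 4
    affected_min: int = 2
    protected_rank_max: Optional[int] = 8
    prior: float = 0.041
    tier_bounds: tuple = (0.15, 0.4, 0.7, 0.9)

    manual_includes: List[str] = field(default_factory=list)
    network_eligible: List[str] = field(default_factory=list)
    extra_includes: Dict[str, List[str]] = field(default_factory=dict)
    invert_tools: List[str] = field(default_factory=list)

    out_dir: Path = Path("results")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_max <= 1.0):
            raise ConfigError(f"maf_max={self.maf_max} outside (0, 1]")
        if not (0.0 <= self.prior < 1.0):
            raise ConfigError(f"prior={self.prior} outside [0, 1)")
        if list(self.tier_bounds) != sorted(self.tier_bounds):
            raise ConfigError("tier_bounds must be increasing")

    def validate_paths(self) -> None:
        """Every referenced input path must exist at run start."""
        for key in _PATH_KEYS:
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"configured path {key}={path} does not exist")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        """Load a config file; relative paths resolve against its directory."""
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        kwargs: dict = {}
        for key, value in (data.get("paths") or {}).items():
            if key not in _PATH_KEYS:
                raise ConfigError(f"unknown path key {key!r} in {path}")
            kwargs[key] = (base / value).resolve() if value else None
        for key, value in (data.get("thresholds") or {}).items():
            if key == "tier_bounds":
                value = tuple(value)
            kwargs[key] = value
        for key in ("manual_includes", "network_eligible", "invert_tools"):
            if key in data:
                kwargs[key] = list(data[key])
        if "extra_includes" in data:
            kwargs["extra_includes"] = {
                patient: list(genes) for patient, genes in data["extra_includes"].items()
            }
        if "out_dir" in data:
            kwargs["out_dir"] = (base / data["out_dir"]).resolve()
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        missing = [k for k in ("vcf", "ped", "panel") if k not in kwargs]
        if missing:
            raise ConfigError(f"{path}: missing required paths: {', '.join(missing)}")
        return cls(**kwargs)
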