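"""Run configuration: analyst-tunable weights, thresholds and key mappings."""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ..errors import ConfigError
from .vcf import DEFAULT_KEY_MAP

#: default per-source weights: the known-gene source counts as strong
#: evidence, every candidate-gene source and the user list as limited
DEFAULT_WEIGHTS = {
    "king": 3.0,
    "exphenosion": 1.0,
    "mouse": 1.0,
    "zebrafish": 1.0,
    "homology": 1.0,
    "ppi": 1.0,
    "expression": 1.0,
    "user": 1.0,
}


@dataclass
class RunConfig:
    module_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS)
    )
    known_gene_rule: str = "king"  # gene is "known" iff it appears in the king list
    candidate_threshold: float = 1.0
    pm2_maf_cutoff: float = 1e-5
    ba1_maf_cutoff: float = 0.05
    bs1_maf_cutoff: float = 0.01
    pli_cutoff: float = 0.9
    expression_cutoff: float = 1.0  # TPM
    ppi_levels: int = 1
    exphenosion_levels: int = 1
    ps2_from_de_novo: bool = True
    info_key_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_KEY_MAP))
    seed: int | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("pm2_maf_cutoff", "ba1_maf_cutoff", "bs1_maf_cutoff", "pli_cutoff"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {value}")
        if self.expression_cutoff < 0:
            raise ConfigError("expression_cutoff must be >= 0")
        if self.ppi_levels < 0 or self.exphenosion_levels < 0:
            raise ConfigError("neighborhood/expansion levels must be >= 0")
        if self.candidate_threshold < 0:
            raise ConfigError("candidate_threshold must be >= 0")
        for source, weight in self.module_weights.items():
            if weight < 0:
                raise ConfigError(f"weight for {source!r} must be >= 0, got {weight}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        merged = dict(data)
        # mappings merge over the defaults rather than replacing them
        if "module_weights" in merged:
            weights = dict(DEFAULT_WEIGHTS)
            weights.update(merged["module_weights"])
            merged["module_weights"] = weights
        if "info_key_map" in merged:
            keys = dict(DEFAULT_KEY_MAP)
            keys.update(merged["info_key_map"])
            merged["info_key_map"] = keys
        return cls(**{**asdict(base), **merged})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "wt") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path


def parse_weights(spec: str) -> dict[str, float]:
    """Parse a ``king=3,ppi=1`` style weight override string."""
    weights: dict[str, float] = {}
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ConfigError(f"bad weight spec {part!r}; expected source=value")
        source, value = part.split("=", 1)
        try:
            weights[source.strip()] = float(value)
        except ValueError as exc:
            raise ConfigError(f"bad weight value in {part!r}") from exc
    return weights
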