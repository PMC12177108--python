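"""Pipeline configuration: every tunable with its default, serializable to
YAML (JSON-compatible) so each run can write its fully resolved settings
next to its outputs and be replayed bit-identically."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError


@dataclass
class PipelineConfig:
    cutoff_hz: float = 0.7
    filter_order: int = 5
    n_phase_bins: int = 15
    vdp_factor: float = 0.4
    vdp_percentile: float = 90.0
    fvl_band: tuple[float, float] = (75.0, 95.0)
    fvl_cutoff: float = 90.0
    fvl_shift_search: bool = False
    trim_percentile: float = 99.0
    percentile_convention: str = "linear"
    registration: str = "none"
    remove_vessels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.fvl_band = tuple(self.fvl_band)  # type: ignore[assignment]
        if self.registration not in ("none", "rigid"):
            raise InvalidParameterError(f"unknown registration mode {self.registration!r}")
        if not (0 < self.vdp_percentile <= 100):
            raise InvalidParameterError("vdp_percentile must be in (0, 100]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fvl_band"] = list(d["fvl_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        return cls.from_dict(data or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
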