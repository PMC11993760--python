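"""Run configuration: validation, YAML round-trip, deterministic naming."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .geometry import PRESETS, SKIN_INDEX, SurfaceParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run.

    Either ``preset`` (a named parameter set) or ``params`` (explicit five
    surface parameters plus index) or ``height_map`` (a path) identifies the
    surface.  Serialization is canonical: ``to_yaml`` output is byte-stable
    under a read/write round trip.
    """

    preset: str | None = None
    params: dict | None = None
    height_map: str | None = None
    mode: str = "reflection"
    theta_i_deg: list[float] = field(default_factory=lambda: [45.0])
    n_outside: float = 1.0
    n_inside: float | None = None
    ray_count: int = 100_000
    seed: int = 0
    bin_width_deg: float = 1.0
    max_depth: int = 20
    power_cutoff: float = 1e-4
    output_dir: str = "."

    def validate(self) -> None:
        sources = [s for s in (self.preset, self.params, self.height_map) if s]
        if len(sources) != 1:
            raise ValueError(
                "config error at 'preset|params|height_map': exactly one "
                "surface source must be given")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(
                f"config error at 'preset': unknown preset {self.preset!r}; "
                f"choose from {sorted(PRESETS)}")
        if self.params is not None:
            try:
                SurfaceParams(**self.params)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config error at 'params': {exc}") from exc
        if self.mode not in ("reflection", "transmission"):
            raise ValueError("config error at 'mode': must be reflection|transmission")
        for th in self.theta_i_deg:
            if not 0.0 <= th < 90.0:
                raise ValueError(
                    f"config error at 'theta_i_deg': {th} outside [0, 90)")
        if self.ray_count < 1:
            raise ValueError("config error at 'ray_count': must be >= 1")
        if self.bin_width_deg <= 0 or abs(round(180.0 / self.bin_width_deg)
                                          * self.bin_width_deg - 180.0) > 1e-9:
            raise ValueError("config error at 'bin_width_deg': must divide 180")
        if not 0.0 < self.power_cutoff < 1.0:
            raise ValueError("config error at 'power_cutoff': must lie in (0, 1)")
        if self.max_depth < 1:
            raise ValueError("config error at 'max_depth': must be >= 1")

    def surface_params(self) -> SurfaceParams | None:
        if self.preset is not None:
            return PRESETS[self.preset]
        if self.params is not None:
            return SurfaceParams(**self.params)
        return None

    def resolved_n_inside(self) -> float:
        if self.n_inside is not None:
            return self.n_inside
        sp = self.surface_params()
        return sp.n if sp is not None else SKIN_INDEX

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError("config error: top level must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"config error at {sorted(unknown)}: unknown fields")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def config_hash(self) -> str:
        """Short stable hash of the canonical serialization, for file names."""
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:8]
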