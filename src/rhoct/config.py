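"""Run configuration: one serialisable object that reproduces a whole run."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .physics import PhysicsConstants, WaterReference

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Validated settings shared by the CLI commands.

    A run is reproducible from its config plus seed; ``config_hash`` is
    logged into output sidecars for provenance.
    """

    energies: tuple[float, float] = (50.0, 200.0)
    m: float = 3.8
    n: float = 3.2
    C_p: float = 9.8e-24
    water_mode: str = "self_consistent"
    water_table: dict | None = None
    z_bounds: tuple[float, float] = (1.0, 30.0)
    clamp_policy: str = "flag"
    calibration_exclude: tuple[str, ...] = ()
    sigma_ref: float = 10.0
    dose_ref: float = 30.0
    energy_ratio: float = 0.5
    dose: float = 30.0
    n_inplane: int = 512
    roi_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        e1, e2 = self.energies
        if not 0 < e1 < e2 < 511:
            raise ValueError(f"invalid energy pair {self.energies}")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if not 0 < self.roi_fraction <= 1:
            raise ValueError("roi_fraction must be in (0, 1]")
        # constructing these validates the remaining physics settings
        self.constants()
        self.water()

    def constants(self) -> PhysicsConstants:
        return PhysicsConstants(C_p=self.C_p, m=self.m, n=self.n)

    def water(self) -> WaterReference:
        kwargs = {"mode": self.water_mode, "consts": self.constants()}
        if self.water_table:
            kwargs["table"] = {float(k): float(v) for k, v in self.water_table.items()}
        return WaterReference(**kwargs)

    @property
    def config_hash(self) -> str:
        doc = asdict(self)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("energies", "z_bounds", "calibration_exclude"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
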