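"""Run configuration: the scenario grids, noise level, head variant and seed."""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import yaml

from .fields import SyntheticHeadConfig
from .flutter import NOISE_LEVELS_DB

__all__ = ["RunConfig"]

#: Default seed recorded in run manifests.
DEFAULT_SEED = 20110617

HEAD_VARIANTS = ("focused", "isotropic_pair")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs, serializable to/from YAML."""

    frequencies_khz: tuple[float, ...] = tuple(float(f) for f in range(20, 111, 10))
    snr_grid_db: tuple[float, ...] = tuple(float(a) for a in range(0, 51, 5))
    noise_level: str = "medium"
    variant: str = "focused"
    n_cells: int = 256
    n_realizations: int = 20
    n_prey: int = 1000
    radii_m: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    seed: int = DEFAULT_SEED
    output_dir: str = "pinnasonar_run"
    head: SyntheticHeadConfig = dc_field(default_factory=SyntheticHeadConfig)

    def validate(self) -> None:
        bad = []
        if not self.frequencies_khz or any(f <= 0 for f in self.frequencies_khz):
            bad.append("frequencies_khz")
        if len(self.snr_grid_db) == 0:
            bad.append("snr_grid_db")
        if self.noise_level not in NOISE_LEVELS_DB:
            bad.append("noise_level")
        if self.variant not in HEAD_VARIANTS:
            bad.append("variant")
        if self.n_cells < 1:
            bad.append("n_cells")
        if self.n_realizations < 1:
            bad.append("n_realizations")
        if not self.radii_m or any(r <= 0 for r in self.radii_m):
            bad.append("radii_m")
        if bad:
            raise ValueError(f"invalid configuration keys: {', '.join(bad)}")

    @property
    def sigma_db(self) -> float:
        return NOISE_LEVELS_DB[self.noise_level]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["head"] = asdict(self.head)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "head" in d and isinstance(d["head"], dict):
            d["head"] = SyntheticHeadConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["head"].items()
            })
        for key in ("frequencies_khz", "snr_grid_db", "radii_m"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)
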