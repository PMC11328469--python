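"""Run configuration: one JSON-serializable object covering every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .errors import InvalidInputError
from .inversion import DEFAULT_A_RANGE, DEFAULT_C_RANGE, DEFAULT_GRID
from .masks import HISTO_PIXEL_SIZE
from .simulate import (
    DEFAULT_AMPLITUDE,
    DEFAULT_ENCODING_GAIN,
    DEFAULT_FREQUENCIES,
)
from .springpot import TISSUE_DENSITY


@dataclass(frozen=True)
class AcquisitionConfig:
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES
    n_offsets: int = 4
    matrix: int = 64
    pixel_size_m: float = 150.0e-6
    tube_inner_diameter_m: float = 7.0e-3
    density_kg_m3: float = TISSUE_DENSITY
    amplitude_m: float = DEFAULT_AMPLITUDE
    encoding_gain_rad_per_m: float = DEFAULT_ENCODING_GAIN
    noise_sd_rad: float = 0.05


@dataclass(frozen=True)
class InversionConfig:
    c_range_mps: tuple[float, float] = DEFAULT_C_RANGE
    a_range_mps: tuple[float, float] = DEFAULT_A_RANGE
    n_grid: int = DEFAULT_GRID
    bin_width_m: float | None = None     # None: one pixel
    weight_by_npx: bool = False


@dataclass(frozen=True)
class RheologyConfig:
    mu_bounds_pa: tuple[float, float] = (1.0, 1e7)
    alpha_bounds: tuple[float, float] = (0.0, 1.0)


@dataclass(frozen=True)
class HistologyConfig:
    gamma: float = 1.5
    pixel_size_um: float = HISTO_PIXEL_SIZE
    tile_px: int = 1000
    saturation_threshold: float = 0.04
    n_tiles_per_group: int = 2


@dataclass(frozen=True)
class StatsConfig:
    fdr: bool = False


@dataclass(frozen=True)
class RunConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    rheology: RheologyConfig = field(default_factory=RheologyConfig)
    histology: HistologyConfig = field(default_factory=HistologyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    n_wave_samples: int | None = 8   # samples to push through wave simulation
                                     # + inversion; None = all

    def validate(self) -> None:
        if len(self.acquisition.frequencies) == 0:
            raise InvalidInputError("frequency list must not be empty")
        if self.acquisition.n_offsets < 3:
            raise InvalidInputError("need >= 3 time offsets")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        return cls(
            acquisition=_load(AcquisitionConfig, d.get("acquisition", {})),
            inversion=_load(InversionConfig, d.get("inversion", {})),
            rheology=_load(RheologyConfig, d.get("rheology", {})),
            histology=_load(HistologyConfig, d.get("histology", {})),
            stats=_load(StatsConfig, d.get("stats", {})),
            seed=int(d.get("seed", 0)),
            n_wave_samples=d.get("n_wave_samples"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _load(cls, d: dict):
    kwargs = {}
    for fname, ftype in cls.__dataclass_fields__.items():
        if fname in d:
            v = d[fname]
            kwargs[fname] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)
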