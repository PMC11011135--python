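"""Run configuration: a fully serializable description of one study.

A :class:`RunConfig` pins everything a pipeline run needs — geometry,
phantom, pulse, preprocessing, APR and beamforming settings, and the
seed of every stochastic step — and round-trips losslessly through
YAML, so two runs from the same file are bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .apr import APRConfig
from .errors import ValidationError
from .geometry import ArrayGeometry, make_geometry
from .preprocess import GateWindow
from .simulate import Pulse

__all__ = ["RunConfig", "GeometrySpec", "PhantomSpec"]


@dataclass
class GeometrySpec:
    shape: str = "flat"
    n_elements: int = 128
    pitch_mm: float = 1.0
    radius_mm: float | None = None

    def build(self) -> ArrayGeometry:
        return make_geometry(self.shape, self.n_elements, self.pitch_mm, self.radius_mm)


@dataclass
class PhantomSpec:
    kind: str = "center_point"
    params: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    #: pulse parameters (Hz); fs is the RF sampling rate
    center_frequency_hz: float = 5e6
    fractional_bandwidth: float = 0.6
    fs_hz: float = 40e6
    sound_speed_mps: float = 1540.0
    noise_level: float = 0.0
    seed: int = 0
    #: preprocessing: gate in mm or null for the full record
    gate_mm: list | None = None
    rf_smoothing_window: int = 9
    sg_window: int = 21
    sg_order: int = 2
    resmooth_round1: bool = True
    #: APR settings
    reference_scanline: int | str = "strongest"
    threshold: int | None = 5
    round2: bool = True
    #: beamforming
    dynamic_range_db: float = 60.0
    focus_mode: str = "dynamic"

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValidationError("noise_level must be >= 0")
        if self.dynamic_range_db <= 0:
            raise ValidationError("dynamic_range_db must be > 0")
        if self.gate_mm is not None and len(self.gate_mm) != 2:
            raise ValidationError("gate_mm must be [z_min, z_max] or null")

    # -- derived objects ----------------------------------------------

    def pulse(self) -> Pulse:
        return Pulse(self.center_frequency_hz, self.fractional_bandwidth, self.fs_hz)

    def gate(self) -> GateWindow | None:
        return GateWindow(*self.gate_mm) if self.gate_mm is not None else None

    def apr_config(self) -> APRConfig:
        return APRConfig(
            gate=self.gate(),
            reference_scanline=self.reference_scanline,
            threshold=self.threshold,
            envelope_smoothing_window=self.rf_smoothing_window,
            resmooth_round1=self.resmooth_round1,
            sg_window=self.sg_window,
            sg_order=self.sg_order,
            round2=self.round2,
        )

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        geom = doc.pop("geometry", {})
        phan = doc.pop("phantom", {})
        known = {f for f in cls.__dataclass_fields__ if f not in ("geometry", "phantom")}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(geometry=GeometrySpec(**geom), phantom=PhantomSpec(**phan), **doc)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
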