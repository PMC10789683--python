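"""Core domain containers shared across the pipeline.

Pressures are in cmH2O throughout (1 mmHg = 1.36 cmH2O at the config
layer), flow in L/s, volume in mL above the end-expiratory level,
compliances in mL/cmH2O.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CMH2O_PER_MMHG = 1.36

#: channel names every waveform record carries, in canonical order
CHANNELS = ("paw", "flow", "volume", "pes", "dppl", "cvp")

#: annotation labels understood by the pipeline
LABELS = ("exp_hold", "insp_hold", "ot_baseline", "ot_squeeze", "breath_start")


class SchemaError(ValueError):
    """A record or file does not conform to the waveform schema."""


class CalibrationError(ValueError):
    """Occlusion-test calibration is unstable (|ΔCVP| below threshold)."""


@dataclass(frozen=True)
class VentilatorSettings:
    """Volume-controlled ventilation settings.

    tidal_volume : mL delivered per breath
    peep         : cmH2O positive end-expiratory pressure
    resp_rate    : breaths/min
    insp_frac    : fraction of the cycle spent in inspiration
    sample_rate  : Hz of the recorded waveforms
    """

    tidal_volume: float = 350.0
    peep: float = 6.0
    resp_rate: float = 20.0
    insp_frac: float = 1.0 / 3.0
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.tidal_volume <= 0:
            raise ValueError("tidal_volume must be > 0")
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if not 0 < self.insp_frac < 1:
            raise ValueError("insp_frac must lie in (0, 1)")
        if self.sample_rate < 50:
            raise ValueError("sample_rate must be >= 50 Hz")
        if self.resp_rate <= 0:
            raise ValueError("resp_rate must be > 0")

    @property
    def cycle_s(self) -> float:
        return 60.0 / self.resp_rate

    @property
    def insp_s(self) -> float:
        return self.cycle_s * self.insp_frac

    @property
    def exp_s(self) -> float:
        return self.cycle_s * (1.0 - self.insp_frac)


@dataclass(frozen=True)
class SubjectParams:
    """Subject-level physiology that persists across conditions.

    lung_compliance   : CL, mL/cmH2O
    airway_resistance : cmH2O·s/L
    pes_transmission  : ΔPes/ΔPpl ratio of the esophageal balloon
    cardiac_rate      : beats/min, drives the CVP oscillation
    cardiac_amplitude : cmH2O, amplitude of the CVP cardiac oscillation
    noise_sd          : per-channel white-noise SD, cmH2O (flow/volume in
                        their own units); missing channels default to 0
    """

    weight: float = 43.0
    lung_compliance: float = 30.0
    airway_resistance: float = 10.0
    pes_transmission: float = 0.9
    cardiac_rate: float = 80.0
    cardiac_amplitude: float = 2.0
    noise_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lung_compliance <= 0:
            raise ValueError("lung_compliance must be > 0")
        if not 0.7 <= self.pes_transmission <= 1.1:
            raise ValueError("pes_transmission must lie in [0.7, 1.1]")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd values must be >= 0")

    def sigma(self, channel: str) -> float:
        return float(self.noise_sd.get(channel, 0.0))


VOLUME_STATUSES = ("low", "normal", "high")
CCW_LEVELS = ("N", "L")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition: intravascular volume level x chest-wall state.

    ccw               : chest-wall compliance, mL/cmH2O
    cvp_baseline      : end-expiratory CVP, cmH2O
    transmission      : T = ΔCVP per unit ΔPpl (true κ = 1/T)
    abdominal_pressure: cmH2O (descriptive covariate)
    end_expiratory_ppl: absolute pleural pressure at end-expiration, cmH2O
    """

    volume_status: str = "normal"
    ccw_level: str = "N"
    ccw: float = 89.0
    cvp_baseline: float = 16.6
    transmission: float = 0.45
    abdominal_pressure: float = 10.0
    end_expiratory_ppl: float = 3.0

    def __post_init__(self) -> None:
        if self.volume_status not in VOLUME_STATUSES:
            raise ValueError(f"volume_status must be one of {VOLUME_STATUSES}")
        if self.ccw_level not in CCW_LEVELS:
            raise ValueError(f"ccw_level must be one of {CCW_LEVELS}")
        if self.ccw <= 0:
            raise ValueError("ccw must be > 0")
        if not 0 < self.transmission <= 1.5:
            raise ValueError("transmission must lie in (0, 1.5]")


@dataclass(frozen=True)
class Annotation:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown annotation label {self.label!r}")
        if self.t_end < self.t_start:
            raise ValueError("annotation must have t_end >= t_start")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class WaveformRecord:
    """Uniformly sampled multichannel recording with event annotations."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    annotations: list[Annotation] = field(default_factory=list)
    truth: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        n = self.time.size
        if n < 2:
            raise SchemaError("record needs at least 2 samples")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=0, atol=1e-9):
            raise SchemaError("time grid must be uniform")
        for name in CHANNELS:
            if name not in self.channels:
                raise SchemaError(f"missing channel {name!r}")
            arr = np.asarray(self.channels[name], dtype=float)
            if arr.shape != self.time.shape:
                raise SchemaError(f"channel {name!r} length mismatch")
            self.channels[name] = arr
        t0, t1 = self.time[0], self.time[-1]
        for ann in self.annotations:
            if ann.t_start < t0 - 1e-9 or ann.t_end > t1 + 1e-9:
                raise SchemaError(
                    f"annotation {ann.label} [{ann.t_start}, {ann.t_end}] "
                    "lies outside the record"
                )

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])

    def windows(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def slice(self, t_start: float, t_end: float) -> dict[str, np.ndarray]:
        mask = (self.time >= t_start - 1e-12) & (self.time <= t_end + 1e-12)
        return {name: arr[mask] for name, arr in self.channels.items()}


@dataclass(frozen=True)
class HoldWindow:
    """A zero-flow window used to read plateau pressures."""

    label: str
    t_start: float
    t_end: float
    source: str = "annotation"  # or "detected"

    def __post_init__(self) -> None:
        if self.label not in ("exp_hold", "insp_hold", "ot_baseline", "ot_squeeze"):
            raise ValueError(f"invalid hold label {self.label!r}")
        if self.source not in ("annotation", "detected"):
            raise ValueError("source must be 'annotation' or 'detected'")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class PlateauReading:
    """A windowed pressure reading; CVP readings are cardiac-cycle averaged."""

    channel: str
    value: float
    window: HoldWindow
    n_cardiac_cycles: Optional[int] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("plateau value must be finite")


@dataclass(frozen=True)
class OTCalibration:
    """Deltas and the κ calibration extracted from one occlusion test."""

    d_paw: float
    d_cvp: float
    kappa: float
    d_pes: Optional[float] = None
    d_dppl: Optional[float] = None
    ratio_pes: Optional[float] = None
    ratio_dppl: Optional[float] = None
    valid_pes: Optional[bool] = None
    valid_dppl: Optional[bool] = None


@dataclass
class DeltaSet:
    """Tidal pressure swings for one condition plus derived quantities.

    All deltas are inspiratory-hold minus expiratory-hold readings;
    est_dppl = κ·ΔCVP is the CVP-derived pleural-swing estimate.
    """

    d_paw: float
    d_cvp: Optional[float] = None
    d_pes: Optional[float] = None
    d_dppl: Optional[float] = None
    est_dppl: Optional[float] = None
    tidal_volume: Optional[float] = None
    kappa: Optional[float] = None
    ratio_pes: Optional[float] = None
    ratio_dppl: Optional[float] = None
    crs: Optional[float] = None
    ccw: Optional[float] = None
    cl: Optional[float] = None
    valid_pes: bool = False
    valid_dppl: bool = False
    ot_ok: bool = False
    subject: Optional[str] = None
    volume_status: Optional[str] = None
    ccw_level: Optional[str] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman bias / precision / limits of agreement for one stratum."""

    n: int
    bias: float
    precision: float
    loa_low: float
    loa_high: float
    stratum: str = "overall"


@dataclass(frozen=True)
class RmcorrResult:
    """Repeated-measures (within-subject) correlation."""

    r: float
    df: int
    p: float
    n_subjects: int
    n_pairs: int
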