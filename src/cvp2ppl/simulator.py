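"""Synthetic cardio-respiratory waveform generator.

Emulates a paralyzed, volume-control-ventilated pig instrumented with
airway pressure (paw), esophageal pressure (pes), directly measured
pleural pressure (dppl) and central venous pressure (cvp) catheters.
The mechanics are a single-compartment linear model:

    1/Crs = 1/CL + 1/Ccw                (series elastances)
    paw  = PEEP + V/Crs + R·flow        (flow in L/s, V in mL)
    dppl = Ppl_ee + V/Ccw               (+ chest squeeze during occlusion)
    pes  = Pes_ee + k_es·(dppl − Ppl_ee)
    cvp  = CVP_ee + T·(dppl − Ppl_ee) + cardiac oscillation + noise

where k_es is the esophageal transmission ratio and T the pleural-to-CVP
transmission (the occlusion-test calibration recovers κ = 1/T).

The breath engine is closed-form per phase: constant inspiratory flow,
passive expiration following an exponential with time constant R·Crs,
with the small non-emptying tail subtracted so every breath returns to
exactly the end-expiratory volume.  Each study condition record contains
annotated occlusion-test, expiratory-hold and inspiratory-hold windows,
mirroring the experimental protocol (occlusion test first, then holds on
unchanged ventilator settings).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .types import (
    CMH2O_PER_MMHG,
    CCW_LEVELS,
    VOLUME_STATUSES,
    Annotation,
    ConditionSpec,
    SubjectParams,
    VentilatorSettings,
    WaveformRecord,
)

__all__ = [
    "Prior",
    "StudyPriors",
    "simulate_condition",
    "simulate_occlusion_test",
    "draw_study",
    "respiratory_system_compliance",
]

#: default chest-squeeze size during the occlusion test, cmH2O
DEFAULT_SQUEEZE = 10.0
#: default hold duration, s (spans >=2 cardiac cycles at 80 bpm)
HOLD_DUR = 3.0
#: occlusion-test window durations, s
OT_BASELINE_DUR = 3.0
OT_RAMP_DUR = 1.0
OT_PLATEAU_DUR = 2.0
OT_RELEASE_DUR = 0.5

PRESSURE_CHANNELS = ("paw", "pes", "dppl", "cvp")


def respiratory_system_compliance(cl: float, ccw: float) -> float:
    """Crs from series elastance additivity: 1/Crs = 1/CL + 1/Ccw."""
    if cl <= 0 or ccw <= 0:
        raise ValueError("compliances must be positive")
    return 1.0 / (1.0 / cl + 1.0 / ccw)


class _Builder:
    """Accumulates per-segment volume/flow/squeeze traces on a uniform grid."""

    def __init__(self, sample_rate: float) -> None:
        self.fs = sample_rate
        self.dt = 1.0 / sample_rate
        self._vol: list[np.ndarray] = []
        self._flow: list[np.ndarray] = []
        self._squeeze: list[np.ndarray] = []
        self.annotations: list[Annotation] = []
        self._n = 0

    @property
    def t_now(self) -> float:
        return self._n * self.dt

    def _push(self, vol: np.ndarray, flow: np.ndarray, squeeze: np.ndarray) -> None:
        self._vol.append(vol)
        self._flow.append(flow)
        self._squeeze.append(squeeze)
        self._n += vol.size

    def _local_t(self, duration: float) -> np.ndarray:
        n = max(1, round(duration * self.fs))
        return np.arange(n) * self.dt

    def annotate(self, label: str, t_start: float, t_end: float) -> None:
        self.annotations.append(Annotation(label, t_start, t_end))

    def breath(self, vent: VentilatorSettings, crs: float, resistance: float) -> None:
        """One ventilated breath starting and ending at end-expiratory volume."""
        self.annotate("breath_start", self.t_now, self.t_now)
        tv, ti, te = vent.tidal_volume, vent.insp_s, vent.exp_s
        # inspiration: constant flow
        t = self._local_t(ti)
        insp_flow = tv / ti / 1000.0  # L/s
        self._push(tv * t / ti, np.full(t.size, insp_flow), np.zeros(t.size))
        # passive expiration, tail-corrected so V(te) = 0 exactly
        tau = resistance * crs / 1000.0  # s
        t = self._local_t(te)
        decay = np.exp(-t / tau)
        norm = 1.0 - np.exp(-te / tau)
        vol = tv * (decay - np.exp(-te / tau)) / norm
        flow = -tv / tau * decay / norm / 1000.0
        self._push(vol, flow, np.zeros(t.size))

    def hold(self, volume: float, duration: float, label: str) -> None:
        """Zero-flow occlusion at a fixed lung volume."""
        t = self._local_t(duration)
        self.annotate(label, self.t_now, self.t_now + duration - self.dt)
        self._push(np.full(t.size, volume), np.zeros(t.size), np.zeros(t.size))

    def inspiration(self, vent: VentilatorSettings) -> None:
        t = self._local_t(vent.insp_s)
        tv = vent.tidal_volume
        self._push(tv * t / vent.insp_s,
                   np.full(t.size, tv / vent.insp_s / 1000.0),
                   np.zeros(t.size))

    def expiration(self, vent: VentilatorSettings, crs: float, resistance: float) -> None:
        tau = resistance * crs / 1000.0
        te = vent.exp_s
        t = self._local_t(te)
        decay = np.exp(-t / tau)
        norm = 1.0 - np.exp(-te / tau)
        tv = vent.tidal_volume
        self._push(tv * (decay - np.exp(-te / tau)) / norm,
                   -tv / tau * decay / norm / 1000.0,
                   np.zeros(t.size))

    def occlusion_test(self, magnitude: float) -> None:
        """Airway closed at end-expiration; smooth chest squeeze of `magnitude`."""
        dt = self.dt
        # flat baseline
        t = self._local_t(OT_BASELINE_DUR)
        self.annotate("ot_baseline", self.t_now, self.t_now + OT_BASELINE_DUR - dt)
        self._push(np.zeros(t.size), np.zeros(t.size), np.zeros(t.size))
        # cosine ramp up — the estimator must not depend on the ramp shape
        t = self._local_t(OT_RAMP_DUR)
        ramp = magnitude * 0.5 * (1.0 - np.cos(np.pi * t / OT_RAMP_DUR))
        self._push(np.zeros(t.size), np.zeros(t.size), ramp)
        # squeeze plateau
        t = self._local_t(OT_PLATEAU_DUR)
        self.annotate("ot_squeeze", self.t_now, self.t_now + OT_PLATEAU_DUR - dt)
        self._push(np.zeros(t.size), np.zeros(t.size), np.full(t.size, magnitude))
        # release
        t = self._local_t(OT_RELEASE_DUR)
        rel = magnitude * 0.5 * (1.0 + np.cos(np.pi * t / OT_RELEASE_DUR))
        self._push(np.zeros(t.size), np.zeros(t.size), rel)

    def assemble(
        self,
        subject: SubjectParams,
        cond: ConditionSpec,
        vent: VentilatorSettings,
        crs: float,
        rng: np.random.Generator,
        noise_free: bool,
        seed: int,
    ) -> WaveformRecord:
        volume = np.concatenate(self._vol)
        flow = np.concatenate(self._flow)
        squeeze = np.concatenate(self._squeeze)
        time = np.arange(volume.size) * self.dt

        paw = vent.peep + volume / crs + subject.airway_resistance * flow + squeeze
        dppl_swing = volume / cond.ccw + squeeze
        dppl = cond.end_expiratory_ppl + dppl_swing
        pes = cond.end_expiratory_ppl + subject.pes_transmission * dppl_swing
        cvp = cond.cvp_baseline + cond.transmission * dppl_swing

        amp = 0.0 if noise_free else subject.cardiac_amplitude
        if amp > 0:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            cvp = cvp + amp * np.sin(2.0 * np.pi * subject.cardiac_rate / 60.0 * time + phase)

        channels = {"paw": paw, "flow": flow, "volume": volume,
                    "pes": pes, "dppl": dppl, "cvp": cvp}
        if not noise_free:
            for name in PRESSURE_CHANNELS:
                sd = subject.sigma(name)
                if sd > 0:
                    channels[name] = channels[name] + rng.normal(0.0, sd, time.size)
            for name in ("flow", "volume"):
                sd = subject.sigma(name)
                if sd > 0:
                    channels[name] = channels[name] + rng.normal(0.0, sd, time.size)

        truth = {
            "subject": _params_dict(subject),
            "condition": _params_dict(cond),
            "ventilator": _params_dict(vent),
            "crs": crs,
            "seed": seed,
            "noise_free": noise_free,
        }
        return WaveformRecord(time=time, channels=channels,
                              annotations=self.annotations, truth=truth,
                              meta={"seed": seed})


def _params_dict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def simulate_condition(
    subject: SubjectParams,
    cond: ConditionSpec,
    vent: VentilatorSettings | None = None,
    n_breaths: int = 3,
    seed: int = 0,
    squeeze_magnitude: float = DEFAULT_SQUEEZE,
    noise_free: bool = False,
    include_ot: bool = True,
) -> WaveformRecord:
    """Simulate one condition: breaths, occlusion test, then both holds.

    The record is a deterministic function of its arguments (same seed,
    same inputs — bit-identical output).  It carries annotations for at
    least one expiratory hold, one inspiratory hold and (unless
    ``include_ot=False``) one occlusion-test baseline/squeeze pair.
    """
    if vent is None:
        vent = VentilatorSettings()
    if n_breaths < 3:
        raise ValueError("n_breaths must be >= 3")
    if squeeze_magnitude <= 0:
        raise ValueError("squeeze_magnitude must be > 0")
    crs = respiratory_system_compliance(subject.lung_compliance, cond.ccw)

    rng = np.random.default_rng(seed)
    b = _Builder(vent.sample_rate)
    for _ in range(n_breaths):
        b.breath(vent, crs, subject.airway_resistance)
    if include_ot:
        b.occlusion_test(squeeze_magnitude)
        for _ in range(2):  # stabilization on unchanged settings
            b.breath(vent, crs, subject.airway_resistance)
    b.hold(0.0, HOLD_DUR, "exp_hold")
    b.inspiration(vent)
    b.hold(vent.tidal_volume, HOLD_DUR, "insp_hold")
    b.expiration(vent, crs, subject.airway_resistance)
    return b.assemble(subject, cond, vent, crs, rng, noise_free, seed)


def simulate_occlusion_test(
    subject: SubjectParams,
    cond: ConditionSpec,
    vent: VentilatorSettings | None = None,
    squeeze_magnitude: float = DEFAULT_SQUEEZE,
    seed: int = 0,
    noise_free: bool = False,
) -> WaveformRecord:
    """Simulate a standalone occlusion test (airway closed at end-expiration).

    With no gas flow the chest squeeze transmits fully to the airway:
    Δpaw = Δdppl exactly, while Δcvp = T·Δdppl (plus cardiac oscillation
    and noise) and Δpes = k_es·Δdppl.
    """
    if vent is None:
        vent = VentilatorSettings()
    if squeeze_magnitude <= 0:
        raise ValueError("squeeze_magnitude must be > 0")
    crs = respiratory_system_compliance(subject.lung_compliance, cond.ccw)
    rng = np.random.default_rng(seed)
    b = _Builder(vent.sample_rate)
    b.occlusion_test(squeeze_magnitude)
    return b.assemble(subject, cond, vent, crs, rng, noise_free, seed)


# --------------------------------------------------------------------------
# study-level sampling


@dataclass(frozen=True)
class Prior:
    """Truncated normal prior; sd = 0 degenerates to the mean."""

    mean: float
    sd: float
    low: float = -np.inf
    high: float = np.inf

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        out = stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                  size=size, random_state=rng)
        return float(out) if size is None else out


def _mmHg(mean: float, sd: float, low: float = 0.5, high: float = 45.0) -> Prior:
    """Prior stated in mmHg, converted to cmH2O (1 mmHg = 1.36 cmH2O)."""
    return Prior(mean * CMH2O_PER_MMHG, sd * CMH2O_PER_MMHG,
                 low * CMH2O_PER_MMHG, high * CMH2O_PER_MMHG)


@dataclass(frozen=True)
class StudyPriors:
    """Parameter priors for the six-condition pig study.

    Defaults reproduce the study conditions: adult-sized pigs around
    43 kg ventilated at ~8 mL/kg with PEEP 6; chest-wall compliance about
    89 mL/cmH2O normally and about 37 mL/cmH2O under an abdominal band;
    end-expiratory CVP rising from ~7.5 mmHg (hypovolemia, normal chest
    wall) to ~19.7 mmHg (hypervolemia, banded); pleural-to-CVP
    transmission T centred on 0.45 so the calibration ratio κ = 1/T is
    centred near 2.2.  CVP and abdominal pressures are specified in mmHg
    and converted to cmH2O here.
    """

    weight: Prior = Prior(43.2, 1.8, 35.0, 55.0)
    tv_per_kg: Prior = Prior(8.0, 0.5, 7.0, 10.5)          # mL/kg
    lung_compliance: Prior = Prior(30.0, 7.0, 12.0, 60.0)  # mL/cmH2O
    airway_resistance: Prior = Prior(10.0, 2.0, 5.0, 20.0)  # cmH2O·s/L
    pes_transmission: Prior = Prior(0.9, 0.1, 0.7, 1.1)
    cardiac_rate: Prior = Prior(88.0, 17.0, 55.0, 140.0)   # bpm
    cardiac_amplitude: Prior = Prior(2.0, 0.5, 0.5, 4.0)   # cmH2O
    ccw_N: Prior = Prior(89.0, 22.0, 45.0, 160.0)          # mL/cmH2O
    ccw_L: Prior = Prior(37.0, 15.0, 15.0, 80.0)
    transmission: Prior = Prior(0.45, 0.15, 0.2, 1.0)      # ΔCVP/ΔPpl
    #: per-condition jitter of T around the subject value; 0 = the null
    #: model in which transmission is independent of volume status
    transmission_condition_sd: float = 0.0
    cvp_baseline: dict[tuple[str, str], Prior] = field(default_factory=lambda: {
        ("low", "N"): _mmHg(7.5, 1.0),
        ("low", "L"): _mmHg(11.7, 1.5),
        ("normal", "N"): _mmHg(12.2, 1.2),
        ("normal", "L"): _mmHg(15.7, 2.6),
        ("high", "N"): _mmHg(14.9, 2.6),
        ("high", "L"): _mmHg(19.7, 3.3),
    })
    abdominal_pressure: dict[str, Prior] = field(default_factory=lambda: {
        "N": _mmHg(7.6, 3.5, 0.5, 30.0),
        "L": _mmHg(20.0, 3.2, 5.0, 35.0),
    })
    end_expiratory_ppl: dict[str, Prior] = field(default_factory=lambda: {
        "N": Prior(3.0, 1.0, 0.0, 8.0),
        "L": Prior(6.0, 1.5, 2.0, 12.0),
    })
    noise_sd: float = 0.3  # cmH2O white noise on every pressure channel

    def zero_variance(self) -> "StudyPriors":
        """All priors collapsed to their means (identical subjects)."""

        def flat(p: Prior) -> Prior:
            return replace(p, sd=0.0)

        return StudyPriors(
            weight=flat(self.weight), tv_per_kg=flat(self.tv_per_kg),
            lung_compliance=flat(self.lung_compliance),
            airway_resistance=flat(self.airway_resistance),
            pes_transmission=flat(self.pes_transmission),
            cardiac_rate=flat(self.cardiac_rate),
            cardiac_amplitude=flat(self.cardiac_amplitude),
            ccw_N=flat(self.ccw_N), ccw_L=flat(self.ccw_L),
            transmission=flat(self.transmission),
            transmission_condition_sd=0.0,
            cvp_baseline={k: flat(p) for k, p in self.cvp_baseline.items()},
            abdominal_pressure={k: flat(p) for k, p in self.abdominal_pressure.items()},
            end_expiratory_ppl={k: flat(p) for k, p in self.end_expiratory_ppl.items()},
            noise_sd=self.noise_sd,
        )


#: protocol ordering: volume low → normal → high; within each, Ccw N then L
PROTOCOL = tuple((v, c) for v in VOLUME_STATUSES for c in CCW_LEVELS)


def draw_subject(priors: StudyPriors, rng: np.random.Generator) -> SubjectParams:
    noise = {ch: priors.noise_sd for ch in PRESSURE_CHANNELS}
    return SubjectParams(
        weight=priors.weight.sample(rng),
        lung_compliance=priors.lung_compliance.sample(rng),
        airway_resistance=priors.airway_resistance.sample(rng),
        pes_transmission=priors.pes_transmission.sample(rng),
        cardiac_rate=priors.cardiac_rate.sample(rng),
        cardiac_amplitude=priors.cardiac_amplitude.sample(rng),
        noise_sd=noise,
    )


def draw_conditions(
    priors: StudyPriors, rng: np.random.Generator
) -> list[ConditionSpec]:
    """Draw the subject's six conditions in protocol order.

    Ccw and transmission persist within the subject (one chest wall, one
    venous tree); baseline CVP is drawn per condition with the three
    volume levels sorted so baseline CVP is monotone in volume status for
    each chest-wall state, as in the experiment.
    """
    ccw = {"N": priors.ccw_N.sample(rng), "L": priors.ccw_L.sample(rng)}
    t_subject = priors.transmission.sample(rng)
    baselines: dict[tuple[str, str], float] = {}
    for lvl in CCW_LEVELS:
        draws = np.sort([priors.cvp_baseline[(v, lvl)].sample(rng)
                         for v in VOLUME_STATUSES])
        for v, val in zip(VOLUME_STATUSES, draws):
            baselines[(v, lvl)] = float(val)
    conds = []
    for v, lvl in PROTOCOL:
        t = t_subject
        if priors.transmission_condition_sd > 0:
            t = float(np.clip(
                t + rng.normal(0.0, priors.transmission_condition_sd), 0.05, 1.5))
        conds.append(ConditionSpec(
            volume_status=v, ccw_level=lvl, ccw=ccw[lvl],
            cvp_baseline=baselines[(v, lvl)], transmission=t,
            abdominal_pressure=priors.abdominal_pressure[lvl].sample(rng),
            end_expiratory_ppl=priors.end_expiratory_ppl[lvl].sample(rng),
        ))
    return conds


def draw_study(
    n_subjects: int,
    priors: StudyPriors | None = None,
    master_seed: int = 0,
    n_breaths: int = 3,
    noise_free: bool = False,
    peep: float = 6.0,
    resp_rate: float = 20.0,
    sample_rate: float = 100.0,
    protocol: tuple[tuple[str, str], ...] = PROTOCOL,
) -> list[WaveformRecord]:
    """Simulate ``n_subjects`` pigs × the protocol's conditions.

    Per-record seeds derive deterministically from ``master_seed``; the
    same master seed reproduces the identical study.  ``protocol`` may
    restrict the (volume_status, ccw_level) pairs, e.g. for scenario
    sweeps; subject-level draws are unaffected by the restriction.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 (within-subject statistics)")
    if priors is None:
        priors = StudyPriors()
    wanted = set(protocol)
    master = np.random.default_rng(master_seed)
    records: list[WaveformRecord] = []
    for i in range(n_subjects):
        rng = np.random.default_rng(master.integers(0, 2**31))
        subject = draw_subject(priors, rng)
        vent = VentilatorSettings(
            tidal_volume=subject.weight * priors.tv_per_kg.sample(rng),
            peep=peep, resp_rate=resp_rate, sample_rate=sample_rate)
        for cond in draw_conditions(priors, rng):
            rec_seed = int(rng.integers(0, 2**31))
            if (cond.volume_status, cond.ccw_level) not in wanted:
                continue
            rec = simulate_condition(subject, cond, vent, n_breaths=n_breaths,
                                     seed=rec_seed, noise_free=noise_free)
            rec.truth["subject_id"] = f"pig{i + 1:02d}"
            rec.meta["subject_id"] = f"pig{i + 1:02d}"
            records.append(rec)
    return records
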