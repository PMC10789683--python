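"""Occlusion-test calibration, tidal deltas, validity filters, compliances.

The method in one line: during an airway occlusion the chest squeeze
transmits fully to the airway, so κ = ΔPaw/ΔCVP measured there equals
ΔPpl/ΔCVP; during subsequent ventilation the tidal pleural swing is then
estimated as κ·ΔCVP (the corrected-CVP estimate of ΔPpl).

A measurement is deemed valid when its occlusion-test transmission ratio
(ΔPes/ΔPaw or Δd-Ppl/ΔPaw) lies in [0.8, 1.2], both bounds inclusive;
an occlusion test with |ΔCVP| below ``eps_cvp`` is an OT failure (κ
would be unstable) and the condition is excluded from CVP comparisons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .holds import detect_holds, plateau
from .types import (
    CalibrationError,
    DeltaSet,
    HoldWindow,
    OTCalibration,
    PlateauReading,
    WaveformRecord,
)

__all__ = [
    "VALIDITY_BAND",
    "EPS_CVP",
    "calibrate_ot",
    "tidal_deltas",
    "compute_compliances",
    "apply_exclusions",
    "extract_condition",
    "ExclusionReport",
]

#: inclusive validity band for ΔPes/ΔPaw and Δd-Ppl/ΔPaw during the OT
VALIDITY_BAND = (0.8, 1.2)
#: minimum |ΔCVP| (cmH2O) during the OT for a stable κ
EPS_CVP = 0.5

Readings = Mapping[str, "PlateauReading | float"]


def _value(readings: Readings, channel: str) -> Optional[float]:
    r = readings.get(channel)
    if r is None:
        return None
    return float(r.value) if isinstance(r, PlateauReading) else float(r)


def _in_band(ratio: float) -> bool:
    return VALIDITY_BAND[0] <= ratio <= VALIDITY_BAND[1]


def calibrate_ot(
    baseline: Readings,
    squeeze: Readings,
    eps_cvp: float = EPS_CVP,
) -> OTCalibration:
    """κ and validity ratios from one occlusion test.

    ``baseline`` and ``squeeze`` map channel names to plateau readings
    (paw and cvp required; pes and dppl optional).  Deltas are squeeze
    minus baseline; κ = ΔPaw/ΔCVP.  Raises :class:`CalibrationError`
    when |ΔCVP| < ``eps_cvp`` (the condition is then an OT failure).
    """
    for ch in ("paw", "cvp"):
        if _value(baseline, ch) is None or _value(squeeze, ch) is None:
            raise ValueError(f"occlusion test needs channel {ch!r} in both windows")
    d_paw = _value(squeeze, "paw") - _value(baseline, "paw")
    d_cvp = _value(squeeze, "cvp") - _value(baseline, "cvp")
    if abs(d_cvp) < eps_cvp:
        raise CalibrationError(
            f"|ΔCVP| = {abs(d_cvp):.3g} cmH2O < {eps_cvp} during occlusion "
            "test: κ unstable, condition marked OT-failed")
    kappa = d_paw / d_cvp

    d_pes = d_dppl = ratio_pes = ratio_dppl = None
    valid_pes = valid_dppl = None
    if _value(baseline, "pes") is not None and _value(squeeze, "pes") is not None:
        d_pes = _value(squeeze, "pes") - _value(baseline, "pes")
        ratio_pes = d_pes / d_paw
        valid_pes = _in_band(ratio_pes)
    if _value(baseline, "dppl") is not None and _value(squeeze, "dppl") is not None:
        d_dppl = _value(squeeze, "dppl") - _value(baseline, "dppl")
        ratio_dppl = d_dppl / d_paw
        valid_dppl = _in_band(ratio_dppl)
    return OTCalibration(d_paw=d_paw, d_cvp=d_cvp, kappa=kappa, d_pes=d_pes,
                         d_dppl=d_dppl, ratio_pes=ratio_pes,
                         ratio_dppl=ratio_dppl, valid_pes=valid_pes,
                         valid_dppl=valid_dppl)


def tidal_deltas(
    insp: Readings,
    exp: Readings,
    cal: Optional[OTCalibration],
    tv: Optional[float] = None,
) -> DeltaSet:
    """Tidal pressure swings (inspiratory − expiratory hold) and κ·ΔCVP.

    ΔPaw is plateau minus total PEEP, both read at zero flow.  Channels
    missing from either hold leave the corresponding comparison excluded
    while the rest proceed.  ``cal=None`` marks an OT-failed condition:
    the CVP-derived estimate is then unavailable.
    """
    d_paw = _value(insp, "paw") - _value(exp, "paw")
    ds = DeltaSet(d_paw=d_paw, tidal_volume=tv)
    if _value(insp, "pes") is not None and _value(exp, "pes") is not None:
        ds.d_pes = _value(insp, "pes") - _value(exp, "pes")
    if _value(insp, "dppl") is not None and _value(exp, "dppl") is not None:
        ds.d_dppl = _value(insp, "dppl") - _value(exp, "dppl")
    if _value(insp, "cvp") is not None and _value(exp, "cvp") is not None:
        ds.d_cvp = _value(insp, "cvp") - _value(exp, "cvp")

    if cal is not None:
        ds.kappa = cal.kappa
        ds.ratio_pes = cal.ratio_pes
        ds.ratio_dppl = cal.ratio_dppl
        ds.valid_pes = bool(cal.valid_pes)
        ds.valid_dppl = bool(cal.valid_dppl)
        if ds.d_cvp is not None:
            ds.est_dppl = cal.kappa * ds.d_cvp
            ds.ot_ok = True

    if tv is not None and ds.d_dppl is not None and d_paw > 0 and ds.d_dppl > 0:
        ds.crs, ds.ccw, ds.cl = compute_compliances(
            tv, plateau=_value(insp, "paw"), total_peep=_value(exp, "paw"),
            d_dppl=ds.d_dppl)
    elif tv is not None and d_paw > 0:
        ds.crs = tv / d_paw
    return ds


def compute_compliances(
    tv: float,
    plateau: float,
    total_peep: float,
    d_dppl: float,
) -> tuple[float, Optional[float], Optional[float]]:
    """Partition respiratory-system compliance using the pleural swing.

    crs = TV/(plateau − total PEEP); ccw = TV/Δd-Ppl;
    cl = TV/((plateau − total PEEP) − Δd-Ppl).  Elastances are additive:
    1/crs = 1/cl + 1/ccw by construction.  When the pleural swing
    consumes the whole driving pressure, cl is undefined and returned as
    None.
    """
    driving = plateau - total_peep
    if driving <= 0:
        raise ValueError("plateau must exceed total PEEP for a ventilated breath")
    if d_dppl <= 0:
        raise ValueError("d_dppl must be > 0")
    crs = tv / driving
    ccw = tv / d_dppl
    cl = tv / (driving - d_dppl) if driving > d_dppl else None
    return crs, ccw, cl


@dataclass
class ExclusionReport:
    """Validity-filter accounting and the three comparison index sets.

    Causes are counted in cascade order: direct-Ppl/Paw measurement
    failures first, then esophageal-ratio failures among the remainder,
    then CVP/occlusion-test failures among what is left.
    """

    n_total: int
    dppl_failures: int
    pes_invalid: int
    cvp_failures: int
    pes_vs_dppl: list[int] = field(default_factory=list)
    ccvp_vs_dppl: list[int] = field(default_factory=list)
    pes_vs_ccvp: list[int] = field(default_factory=list)

    @property
    def sizes(self) -> dict[str, int]:
        return {"pes_vs_dppl": len(self.pes_vs_dppl),
                "ccvp_vs_dppl": len(self.ccvp_vs_dppl),
                "pes_vs_ccvp": len(self.pes_vs_ccvp)}

    def to_dict(self) -> dict:
        return {"n_total": self.n_total,
                "dppl_failures": self.dppl_failures,
                "pes_invalid": self.pes_invalid,
                "cvp_failures": self.cvp_failures,
                "comparison_sizes": self.sizes}


def apply_exclusions(deltasets: Sequence[DeltaSet]) -> ExclusionReport:
    """Build the three method-comparison sets with independent filters.

    * Pes vs d-Ppl     : valid d-Ppl and valid Pes, both swings present
    * κ·ΔCVP vs d-Ppl  : valid d-Ppl and a successful occlusion test
    * Pes vs κ·ΔCVP    : valid Pes and a successful occlusion test
    """
    report = ExclusionReport(n_total=len(deltasets), dppl_failures=0,
                             pes_invalid=0, cvp_failures=0)
    for i, ds in enumerate(deltasets):
        ok_dppl = ds.valid_dppl and ds.d_dppl is not None
        ok_pes = ds.valid_pes and ds.d_pes is not None
        ok_cvp = ds.ot_ok and ds.est_dppl is not None
        if not ok_dppl:
            report.dppl_failures += 1
        elif not ok_pes:
            report.pes_invalid += 1
        elif not ok_cvp:
            report.cvp_failures += 1
        if ok_dppl and ok_pes:
            report.pes_vs_dppl.append(i)
        if ok_dppl and ok_cvp:
            report.ccvp_vs_dppl.append(i)
        if ok_pes and ok_cvp:
            report.pes_vs_ccvp.append(i)
    return report


def extract_condition(
    record: WaveformRecord,
    eps_cvp: float = EPS_CVP,
    avg_frac: float = 0.5,
) -> DeltaSet:
    """Run the full single-condition measurement chain on one record.

    Locates the occlusion-test and hold windows (annotation-first),
    reads cardiac-averaged plateaus, calibrates κ, and returns the
    condition's :class:`DeltaSet` with validity flags and compliances.
    An occlusion-test failure (unstable ΔCVP or missing OT windows)
    yields ``ot_ok=False`` rather than an exception.
    """
    windows = {w.label: w for w in detect_holds(record)}
    for needed in ("exp_hold", "insp_hold"):
        if needed not in windows:
            raise ValueError(f"record lacks a {needed} window")

    def read(win: HoldWindow, channels=("paw", "pes", "dppl", "cvp")) -> dict:
        return {ch: plateau(record, win, ch, avg_frac=avg_frac) for ch in channels}

    cal = None
    if "ot_baseline" in windows and "ot_squeeze" in windows:
        try:
            cal = calibrate_ot(read(windows["ot_baseline"]),
                               read(windows["ot_squeeze"]), eps_cvp=eps_cvp)
        except CalibrationError:
            cal = None

    insp = read(windows["insp_hold"])
    exp = read(windows["exp_hold"])
    tv = (plateau(record, windows["insp_hold"], "volume", avg_frac).value
          - plateau(record, windows["exp_hold"], "volume", avg_frac).value)
    ds = tidal_deltas(insp, exp, cal, tv=tv)

    if record.truth:
        ds.subject = record.truth.get("subject_id") or record.meta.get("subject_id")
        cond = record.truth.get("condition") or {}
        ds.volume_status = cond.get("volume_status")
        ds.ccw_level = cond.get("ccw_level")
    return ds
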