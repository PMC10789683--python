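"""Hold-window location and plateau-pressure extraction.

Plateau pressures (paw, pes, dppl) are read as the mean over the last
half of a zero-flow window, skipping post-occlusion equilibration.  CVP
is read over a whole number of cardiac cycles so the cardiac oscillation
averages out; the cycle length is estimated from the autocorrelation
peak of the windowed CVP trace (lag band 0.4–2 s, parabolic refinement)
and the averaging span end-aligned with fractional-sample interpolation,
so the cancellation does not depend on the sample grid.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as _signal

from .types import HoldWindow, PlateauReading, WaveformRecord

__all__ = ["detect_holds", "plateau", "estimate_cardiac_period"]

HOLD_LABELS = ("exp_hold", "insp_hold", "ot_baseline", "ot_squeeze")


def detect_holds(
    record: WaveformRecord,
    flow_eps: float = 1e-4,
    min_dur: float = 1.0,
    use_annotations: bool = True,
) -> list[HoldWindow]:
    """Return hold windows, preferring the record's annotations.

    Annotated windows reflect operator-triggered maneuvers and take
    precedence; detection from the flow channel (maximal runs with
    |flow| < ``flow_eps`` lasting at least ``min_dur`` seconds) is a
    fallback for unannotated recordings.  Detected windows are labelled
    inspiratory or expiratory by the lung-volume level inside them.
    """
    if use_annotations:
        annotated = [
            HoldWindow(a.label, a.t_start, a.t_end, source="annotation")
            for a in record.annotations
            if a.label in HOLD_LABELS
        ]
        if annotated:
            return annotated

    flow = record.channels["flow"]
    vol = record.channels["volume"]
    t = record.time
    mask = np.abs(flow) < flow_eps
    if not mask.any():
        return []
    # maximal runs of zero flow
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    run_starts, run_ends = idx[0::2], idx[1::2] - 1  # inclusive sample indices
    v_mid = 0.5 * (np.nanmin(vol) + np.nanmax(vol))
    windows: list[HoldWindow] = []
    for s, e in zip(run_starts, run_ends):
        if t[e] - t[s] < min_dur:
            continue
        label = "insp_hold" if vol[s:e + 1].mean() > v_mid else "exp_hold"
        windows.append(HoldWindow(label, float(t[s]), float(t[e]), source="detected"))
    return windows


def estimate_cardiac_period(
    x: np.ndarray,
    sample_rate: float,
    lag_band: tuple[float, float] = (0.4, 2.0),
    min_corr: float = 0.25,
) -> float | None:
    """Cardiac cycle length (s) from the autocorrelation peak, or None.

    Returns None when no periodicity stands out (normalized
    autocorrelation below ``min_corr`` everywhere in the lag band), e.g.
    on a cardiac-free or pure-noise trace.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    lo = max(1, int(np.floor(lag_band[0] * sample_rate)))
    # cap lags at 80% of the window so the unbiased estimate stays stable
    hi = min(int(0.8 * n), int(np.ceil(lag_band[1] * sample_rate)))
    if hi <= lo + 1:
        return None
    x = _signal.detrend(x, type="linear")
    denom = float(np.dot(x, x))
    if denom <= 0:
        return None
    c = _signal.correlate(x, x, mode="full")[n - 1:]
    # unbiased normalization: the biased (triangular-tapered) estimator
    # would drag the peak toward shorter lags
    lags = np.arange(n)
    r = (c / (n - lags)) / (denom / n)
    band = r[lo:hi + 1]
    rmax = float(band.max())
    if rmax < min_corr:
        return None
    # take the FIRST strong local maximum: higher-order peaks of a periodic
    # signal can edge above the fundamental through end effects
    thresh = max(min_corr, 0.8 * rmax)
    k = None
    for j in range(lo, hi + 1):
        if r[j] >= thresh and r[j] >= r[j - 1] and r[j] >= r[j + 1]:
            k = j
            break
    if k is None:
        k = int(np.argmax(band)) + lo

    def _refine(idx: int) -> float:
        if 0 < idx < n - 1:
            y0, y1, y2 = r[idx - 1], r[idx], r[idx + 1]
            d2 = y0 - 2 * y1 + y2
            delta = 0.0 if d2 == 0 else 0.5 * (y0 - y2) / d2
            return idx + float(np.clip(delta, -0.5, 0.5))
        return float(idx)

    lag = _refine(k)
    # harmonic refinement: the m-th autocorrelation peak divides the
    # interpolation error by m
    m = int(hi // k)
    if m >= 2:
        lo2 = int(m * lag - k // 2)
        hi2 = min(hi, int(m * lag + k // 2))
        if hi2 > lo2:
            k2 = lo2 + int(np.argmax(r[lo2:hi2 + 1]))
            if r[k2] >= min_corr:
                lag = _refine(k2) / m
    period = lag / sample_rate
    return _ls_frequency_refine(x, sample_rate, period)


def _ls_frequency_refine(x: np.ndarray, sample_rate: float, period: float) -> float:
    """Polish the cycle length by least squares around the autocorr estimate.

    Minimizes the residual of fitting {constant, trend, cos ωt, sin ωt}
    over ω within ±10% of the initial guess; exact for a clean sinusoid,
    maximum-likelihood under white noise.
    """
    from scipy.optimize import minimize_scalar

    t = np.arange(x.size) / sample_rate
    base = np.column_stack([np.ones_like(t), t])

    def rss(omega: float) -> float:
        d = np.column_stack([base, np.cos(omega * t), np.sin(omega * t)])
        _, res, *_ = np.linalg.lstsq(d, x, rcond=None)
        if res.size:
            return float(res[0])
        r = x - d @ np.linalg.lstsq(d, x, rcond=None)[0]
        return float(np.dot(r, r))

    w0 = 2.0 * np.pi / period
    opt = minimize_scalar(rss, bounds=(0.9 * w0, 1.1 * w0), method="bounded",
                          options={"xatol": 1e-10})
    return float(2.0 * np.pi / opt.x)


def _fractional_mean(t: np.ndarray, x: np.ndarray, a: float, b: float) -> float:
    """Mean of the piecewise-linear signal over [a, b] (fractional endpoints)."""
    inside = (t > a) & (t < b)
    ts = np.concatenate(([a], t[inside], [b]))
    xs = np.concatenate(([np.interp(a, t, x)], x[inside], [np.interp(b, t, x)]))
    return float(np.trapezoid(xs, ts) / (b - a))


def plateau(
    record: WaveformRecord,
    window: HoldWindow,
    channel: str,
    avg_frac: float = 0.5,
    cardiac_period: float | None = None,
) -> PlateauReading:
    """Windowed pressure reading for one channel.

    For paw/pes/dppl (and flow/volume) the value is the plain mean over
    the last ``avg_frac`` of the window.  For cvp it is the mean over the
    largest whole number of cardiac cycles fitting in that sub-window,
    which removes the cardiac-oscillation bias; if no whole cycle fits or
    no periodicity is detectable, the reading degrades to the plain mean
    (with a warning when the window is shorter than the cycle).  A known
    cycle length can be supplied via ``cardiac_period`` to skip the
    autocorrelation estimate.
    """
    if channel not in record.channels:
        raise KeyError(f"record has no channel {channel!r}")
    t0 = window.t_end - avg_frac * window.duration
    sub = (record.time >= t0 - 1e-12) & (record.time <= window.t_end + 1e-12)
    t = record.time[sub]
    x = record.channels[channel][sub]
    if t.size < 2:
        raise ValueError("window too short for the record's sample rate")

    if channel != "cvp":
        return PlateauReading(channel, float(x.mean()), window)

    full = (record.time >= window.t_start - 1e-12) & (record.time <= window.t_end + 1e-12)
    tf = record.time[full]
    xf = record.channels["cvp"][full]
    period = cardiac_period
    if period is None:
        period = estimate_cardiac_period(xf, record.sample_rate)
    span = t[-1] - t[0]
    if period is not None and period > span:
        # sub-window too short for a whole cycle: widen to the full hold
        t, x, span = tf, xf, tf[-1] - tf[0]
    if period is None or period > span:
        if period is not None:
            warnings.warn(
                "CVP window shorter than one cardiac cycle; falling back to "
                "the plain mean (degraded precision)", stacklevel=2)
        return PlateauReading(channel, float(x.mean()), window, n_cardiac_cycles=None)
    k = int(span // period)
    value = _fractional_mean(t, x, t[-1] - k * period, t[-1])
    return PlateauReading(channel, value, window, n_cardiac_cycles=k)
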