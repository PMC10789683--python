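"""Method-agreement statistics: Bland–Altman and repeated-measures correlation.

Both are implemented from definition.  Bland–Altman uses the simple
independent-pairs formula pooled over repeated measures per subject
(bias = mean difference, precision = sample SD of differences, limits of
agreement = bias ± 1.96·SD); a repeated-measures-adjusted variant of the
LoA is available behind a flag but is not the default.  The
repeated-measures correlation is the analysis-of-covariance common
within-subject correlation: center x and y within subject, fit a common
slope with per-subject intercepts, and take
r = sign(slope)·sqrt(SS_model/(SS_model+SS_error)) with
df = N − n_subjects − 1 and the p-value from the t transform
t = r·sqrt(df/(1−r²)).
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AgreementResult, RmcorrResult

__all__ = ["bland_altman", "bland_altman_strata", "rmcorr", "summarize_study"]

LOA_Z = 1.96  # limits-of-agreement multiplier


def bland_altman(
    estimates: Sequence[float],
    references: Sequence[float],
    stratum: str = "overall",
    subject_ids: Optional[Sequence] = None,
    repeated_measures_loa: bool = False,
) -> AgreementResult:
    """Bland–Altman agreement of ``estimates`` against ``references``.

    With ``repeated_measures_loa=True`` the SD entering the limits of
    agreement is inflated by the between/within variance decomposition
    of the differences across ``subject_ids`` (one-way ANOVA components),
    accounting for repeated measures per subject; the default is the
    simple pooled formula.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must be paired")
    if est.size < 2:
        raise ValueError("Bland–Altman needs at least 2 pairs")
    diff = est - ref
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if repeated_measures_loa:
        if subject_ids is None:
            raise ValueError("repeated_measures_loa requires subject_ids")
        sd = _rm_sd(diff, np.asarray(subject_ids))
    return AgreementResult(n=int(est.size), bias=bias, precision=sd,
                           loa_low=bias - LOA_Z * sd, loa_high=bias + LOA_Z * sd,
                           stratum=stratum)


def _rm_sd(diff: np.ndarray, subjects: np.ndarray) -> float:
    """SD of differences corrected for repeated measures per subject."""
    groups = [diff[subjects == s] for s in np.unique(subjects)]
    n = diff.size
    k = len(groups)
    if k < 2 or n <= k:
        return float(diff.std(ddof=1))
    grand = diff.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n - k)
    m_h = (n - sum(g.size ** 2 for g in groups) / n) / (k - 1)
    var = ms_within + max(ms_between - ms_within, 0.0) / max(m_h, 1.0)
    return float(np.sqrt(var))


def bland_altman_strata(
    estimates: Sequence[float],
    references: Sequence[float],
    stratum_labels: Sequence,
    include_overall: bool = True,
) -> dict[str, AgreementResult]:
    """Per-stratum Bland–Altman plus the pooled 'overall' result.

    Strata with fewer than 2 pairs are omitted with a warning.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    labels = np.asarray(stratum_labels)
    out: dict[str, AgreementResult] = {}
    if include_overall:
        out["overall"] = bland_altman(est, ref, "overall")
    for lab in pd.unique(labels):
        mask = labels == lab
        if mask.sum() < 2:
            warnings.warn(f"stratum {lab!r} has < 2 pairs; omitted", stacklevel=2)
            continue
        out[str(lab)] = bland_altman(est[mask], ref[mask], str(lab))
    return out


def rmcorr(
    subject_ids: Sequence,
    x: Sequence[float],
    y: Sequence[float],
) -> RmcorrResult:
    """Repeated-measures correlation (common within-subject correlation).

    Subjects with fewer than 2 complete pairs are dropped with a
    warning.  Requires at least 2 remaining subjects and some
    within-subject variance in x.
    """
    subj = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subj.size == x.size == y.size):
        raise ValueError("subject_ids, x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    subj, x, y = subj[keep], x[keep], y[keep]

    counts = pd.Series(subj).value_counts()
    small = counts[counts < 2].index
    if len(small):
        warnings.warn(f"dropping {len(small)} subject(s) with < 2 pairs",
                      stacklevel=2)
        keep = ~np.isin(subj, np.asarray(small))
        subj, x, y = subj[keep], x[keep], y[keep]
    uniq = np.unique(subj)
    if uniq.size < 2:
        raise ValueError("rmcorr needs >= 2 subjects with >= 2 pairs each")

    xc = x.copy()
    yc = y.copy()
    for s in uniq:
        m = subj == s
        xc[m] -= xc[m].mean()
        yc[m] -= yc[m].mean()
    sxx = float(np.dot(xc, xc))
    if sxx <= 0:
        raise ValueError("zero within-subject variance in x: rmcorr undefined")
    syy = float(np.dot(yc, yc))
    sxy = float(np.dot(xc, yc))
    slope = sxy / sxx
    ss_model = slope * slope * sxx
    ss_error = syy - ss_model
    if syy <= 0:
        raise ValueError("zero within-subject variance in y: rmcorr undefined")
    r = float(np.sign(slope) * np.sqrt(ss_model / (ss_model + ss_error)))
    r = float(np.clip(r, -1.0, 1.0))
    n = int(x.size)
    df = n - uniq.size - 1
    if df < 1:
        raise ValueError("rmcorr needs df >= 1")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return RmcorrResult(r=r, df=df, p=p, n_subjects=int(uniq.size), n_pairs=n)


SUMMARY_MEASURES = (
    ("crs", "Crs (mL/cmH2O)"),
    ("ccw", "Ccw (mL/cmH2O)"),
    ("cl", "CL (mL/cmH2O)"),
    ("ratio_pes", "dPes/dPaw during OT"),
    ("kappa", "dPaw/dCVP during OT (kappa)"),
    ("d_dppl", "d-Ppl swing (cmH2O)"),
    ("d_pes", "Pes swing (cmH2O)"),
    ("est_dppl", "CVP-derived Ppl swing (cmH2O)"),
)


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Condition-level summary: mean, SD and n per measure and cell.

    ``results`` is the tidy per-condition table (one row per pig ×
    condition, as produced by the pipeline).  Cells are the six volume ×
    chest-wall-state combinations plus 'all'; empty cells yield NaN.
    """
    cells = [(v, c) for v in ("low", "normal", "high") for c in ("N", "L")]
    rows = []
    for key, label in SUMMARY_MEASURES:
        if key not in results.columns:
            continue
        row: dict[str, object] = {"measure": label}
        for v, c in cells:
            sel = results[(results["volume_status"] == v)
                          & (results["ccw_level"] == c)][key].dropna()
            row[f"{v}/Ccw({c}) mean"] = sel.mean() if len(sel) else np.nan
            row[f"{v}/Ccw({c}) sd"] = sel.std(ddof=1) if len(sel) > 1 else np.nan
            row[f"{v}/Ccw({c}) n"] = len(sel)
        allv = results[key].dropna()
        row["all mean"] = allv.mean() if len(allv) else np.nan
        row["all sd"] = allv.std(ddof=1) if len(allv) > 1 else np.nan
        row["all n"] = len(allv)
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
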