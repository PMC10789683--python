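"""Study orchestration: simulate → extract → calibrate → filter → agree.

A run is a pure function of its :class:`StudyConfig`; with a fixed
master seed the report JSON is byte-identical across runs.  The report
mirrors the study's result structure: a condition-level summary table,
Bland–Altman agreement overall and stratified by volume status and
chest-wall state, repeated-measures correlations, and the exclusion
accounting.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__ as _version
from .agreement import bland_altman_strata, rmcorr, summarize_study
from .estimation import EPS_CVP, ExclusionReport, apply_exclusions, extract_condition
from .io import write_record
from .simulator import PROTOCOL, StudyPriors, draw_study
from .types import DeltaSet, RmcorrResult

__all__ = ["StudyConfig", "StudyReport", "run_study", "scenario_sweep"]

log = logging.getLogger("cvp2ppl")

#: the three method comparisons: (name, estimate column, reference column)
COMPARISONS = (
    ("pes_vs_dppl", "d_pes", "d_dppl"),
    ("ccvp_vs_dppl", "est_dppl", "d_dppl"),
    ("pes_vs_ccvp", "d_pes", "est_dppl"),
)


@dataclass(frozen=True)
class StudyConfig:
    """Everything a reproducible study run depends on."""

    n_subjects: int = 10
    master_seed: int = 0
    noise_free: bool = False
    priors: StudyPriors = field(default_factory=StudyPriors)
    n_breaths: int = 3
    peep: float = 6.0
    resp_rate: float = 20.0
    sample_rate: float = 100.0
    eps_cvp: float = EPS_CVP
    protocol: tuple = PROTOCOL
    write_waveforms: bool = False
    make_plots: bool = False

    def to_dict(self) -> dict:
        def fix_keys(obj):
            if isinstance(obj, dict):
                return {"/".join(k) if isinstance(k, tuple) else str(k):
                        fix_keys(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [fix_keys(v) for v in obj]
            return obj

        return fix_keys(dataclasses.asdict(self))

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): v for k, v in obj.items()}
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class StudyReport:
    """All study-level outputs plus provenance."""

    config: StudyConfig
    results: pd.DataFrame          # tidy per-condition table
    exclusions: ExclusionReport
    agreement: dict                # comparison -> stratum -> AgreementResult
    correlations: dict[str, Optional[RmcorrResult]]
    summary: pd.DataFrame

    @property
    def provenance(self) -> dict:
        return {"config_digest": self.config.digest(),
                "master_seed": self.config.master_seed,
                "version": _version}

    def to_dict(self) -> dict:
        agree = {
            comp: {stratum: dataclasses.asdict(res)
                   for stratum, res in strata.items()}
            for comp, strata in self.agreement.items()
        }
        corr = {comp: (dataclasses.asdict(r) if r is not None else None)
                for comp, r in self.correlations.items()}
        return {
            "provenance": self.provenance,
            "exclusions": self.exclusions.to_dict(),
            "agreement": agree,
            "correlations": corr,
            "summary": json.loads(self.summary.to_json(orient="index")),
            "conditions": json.loads(
                self.results.to_json(orient="records", double_precision=15)),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1,
                          default=_jsonable, **kwargs)


def _results_frame(deltasets: list[DeltaSet]) -> pd.DataFrame:
    df = pd.DataFrame([ds.to_dict() for ds in deltasets])
    return df.astype({c: float for c in
                      ("d_paw", "d_cvp", "d_pes", "d_dppl", "est_dppl",
                       "kappa", "crs", "ccw", "cl")
                      if c in df.columns})


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Execute one full study and (optionally) write the report tree.

    Writes ``report.json``, ``summary.tsv`` and ``conditions.tsv`` under
    ``out_dir`` (plus waveform CSVs and figures when enabled in the
    config).
    """
    records = draw_study(
        config.n_subjects, priors=config.priors, master_seed=config.master_seed,
        n_breaths=config.n_breaths, noise_free=config.noise_free,
        peep=config.peep, resp_rate=config.resp_rate,
        sample_rate=config.sample_rate, protocol=tuple(config.protocol))

    deltasets = []
    for rec in records:
        sid = rec.meta.get("subject_id", "?")
        cond = (rec.truth or {}).get("condition", {})
        tag = f"{sid}/{cond.get('volume_status')}-{cond.get('ccw_level')}"
        try:
            ds = extract_condition(rec, eps_cvp=config.eps_cvp)
        except Exception as exc:  # noqa: BLE001 - stage failure is fatal
            raise RuntimeError(f"extraction failed for condition {tag}") from exc
        if not ds.ot_ok:
            log.info("condition %s: occlusion-test failure (no κ)", tag)
        if not ds.valid_dppl:
            log.info("condition %s: d-Ppl/Paw ratio %.3f outside [0.8, 1.2]",
                     tag, -1 if ds.ratio_dppl is None else ds.ratio_dppl)
        if not ds.valid_pes:
            log.info("condition %s: Pes/Paw ratio %.3f outside [0.8, 1.2]",
                     tag, -1 if ds.ratio_pes is None else ds.ratio_pes)
        deltasets.append(ds)

    df = _results_frame(deltasets)
    excl = apply_exclusions(deltasets)

    agreement: dict[str, dict] = {}
    correlations: dict[str, Optional[RmcorrResult]] = {}
    for name, est_col, ref_col in COMPARISONS:
        idx = getattr(excl, name)
        sub = df.iloc[idx]
        strata: dict = {}
        if len(sub) >= 2:
            strata.update(bland_altman_strata(
                sub[est_col], sub[ref_col], sub["volume_status"]))
            ccw_strata = bland_altman_strata(
                sub[est_col], sub[ref_col],
                "Ccw(" + sub["ccw_level"].astype(str) + ")",
                include_overall=False)
            strata.update(ccw_strata)
        agreement[name] = strata
        try:
            correlations[name] = rmcorr(sub["subject"], sub[est_col], sub[ref_col])
        except ValueError as exc:
            log.info("rmcorr unavailable for %s: %s", name, exc)
            correlations[name] = None

    report = StudyReport(config=config, results=df, exclusions=excl,
                         agreement=agreement, correlations=correlations,
                         summary=summarize_study(df))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        report.summary.to_csv(out / "summary.tsv", sep="\t")
        df.to_csv(out / "conditions.tsv", sep="\t", index=False)
        if config.write_waveforms:
            wdir = out / "waveforms"
            for rec in records:
                cond = (rec.truth or {}).get("condition", {})
                name = (f"{rec.meta.get('subject_id')}_"
                        f"{cond.get('volume_status')}_{cond.get('ccw_level')}.csv")
                write_record(rec, wdir / name)
        if config.make_plots:
            _write_plots(report, out / "figures")
    return report


def _write_plots(report: StudyReport, fig_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    df = report.results
    for name, est_col, ref_col in COMPARISONS:
        idx = getattr(report.exclusions, name)
        sub = df.iloc[idx]
        if len(sub) < 2:
            continue
        est, ref = sub[est_col].to_numpy(), sub[ref_col].to_numpy()
        overall = report.agreement[name].get("overall")
        # Bland–Altman
        fig, ax = plt.subplots(figsize=(5, 4))
        mean, diff = (est + ref) / 2, est - ref
        for sid, grp in sub.assign(_m=mean, _d=diff).groupby("subject"):
            ax.plot(grp["_m"], grp["_d"], "o", ms=4, label=str(sid))
        if overall:
            ax.axhline(overall.bias, color="k")
            ax.axhline(overall.loa_low, color="k", ls="--")
            ax.axhline(overall.loa_high, color="k", ls="--")
        ax.set_xlabel("mean of methods (cmH2O)")
        ax.set_ylabel(f"{est_col} − {ref_col} (cmH2O)")
        ax.set_title(f"Bland–Altman: {name}")
        fig.savefig(fig_dir / f"ba_{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        # within-subject scatter
        fig, ax = plt.subplots(figsize=(5, 4))
        for sid, grp in sub.groupby("subject"):
            ax.plot(grp[ref_col], grp[est_col], "o", ms=4)
        lo = float(np.nanmin([ref.min(), est.min()]))
        hi = float(np.nanmax([ref.max(), est.max()]))
        ax.plot([lo, hi], [lo, hi], "k:", lw=1)
        r = report.correlations.get(name)
        ax.set_title(f"{name}" + (f"  rmcorr r={r.r:.3f}" if r else ""))
        ax.set_xlabel(f"{ref_col} (cmH2O)")
        ax.set_ylabel(f"{est_col} (cmH2O)")
        fig.savefig(fig_dir / f"scatter_{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


SWEEP_AXES = ("volume", "ccw", "noise", "T")


def scenario_sweep(
    config: StudyConfig,
    axis: str,
    levels: Optional[list] = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Re-run the study across levels of one axis and compare accuracy.

    Axes: ``volume`` (restrict to one volume status), ``ccw`` (restrict
    to one chest-wall state), ``noise`` (pressure-channel noise SD), and
    ``T`` (mean pleural-to-CVP transmission — sweeping it checks how a
    condition-dependent transmission would bias the estimate).  Returns
    the per-level reports and a tidy bias/precision comparison table for
    the CVP-derived estimate against the measured pleural swing.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    if levels is None:
        levels = {"volume": ["low", "normal", "high"], "ccw": ["N", "L"],
                  "noise": [0.0, 0.15, 0.3, 0.6], "T": [0.3, 0.45, 0.6, 0.9]}[axis]

    reports: dict = {}
    rows = []
    for level in levels:
        cfg = config
        if axis == "volume":
            cfg = replace(config, protocol=tuple(
                p for p in config.protocol if p[0] == level))
        elif axis == "ccw":
            cfg = replace(config, protocol=tuple(
                p for p in config.protocol if p[1] == level))
        elif axis == "noise":
            cfg = replace(config, priors=replace(config.priors, noise_sd=level))
        elif axis == "T":
            pri = config.priors
            cfg = replace(config, priors=replace(
                pri, transmission=replace(pri.transmission, mean=level)))
        rep = run_study(cfg, out_dir=None if out_dir is None
                        else Path(out_dir) / f"{axis}_{level}")
        reports[level] = rep
        overall = rep.agreement["ccvp_vs_dppl"].get("overall")
        rows.append({
            "axis": axis, "level": level,
            "n": overall.n if overall else 0,
            "bias": overall.bias if overall else np.nan,
            "precision": overall.precision if overall else np.nan,
        })
    table = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(out_dir) / f"sweep_{axis}.tsv", sep="\t", index=False)
    return reports, table
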