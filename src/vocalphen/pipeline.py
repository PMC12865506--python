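"""Pipeline orchestration: calibrate -> filter -> activity -> gate -> fit ->
predict -> extract -> summarize, with a per-species status table and a
structured run log so retention accounting stays auditable."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import calibration, detections, phenometrics
from .hgam import HGAMSpec, build_design, deviance_explained, fit_hgam, predict_curve


@dataclass
class PipelineConfig:
    detections_path: str
    sites_path: str
    effort_path: str
    validation_path: str
    traits_path: str
    outdir: str
    target_precision: float = 0.95
    min_sites: int = 5
    rel_height: float = 0.30
    hgam: HGAMSpec = field(default_factory=HGAMSpec)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        hgam = HGAMSpec(**raw.pop("hgam", {}))
        return cls(hgam=hgam, **raw)


@dataclass
class PipelineResult:
    thresholds: pd.DataFrame
    shifts: pd.DataFrame
    activity: pd.DataFrame
    gate: pd.DataFrame
    curves: pd.DataFrame
    phenometrics: pd.DataFrame
    summary: pd.DataFrame
    lags: pd.DataFrame
    status: pd.DataFrame
    fits: dict
    log: list[dict]


def _round_half_up(x, nd=2):
    factor = 10.0**nd
    return np.floor(np.asarray(x, dtype=float) * factor + 0.5) / factor


def run_frames(
    dets: pd.DataFrame,
    sites: pd.DataFrame,
    effort: pd.DataFrame,
    validation: pd.DataFrame,
    traits: pd.DataFrame,
    target_precision: float = 0.95,
    min_sites: int = 5,
    rel_height: float = 0.30,
    hgam_spec: HGAMSpec | None = None,
) -> PipelineResult:
    """Run every stage on in-memory tables.

    Per-species failures (unattainable threshold, gate failure, smooth
    non-convergence, undefined phenoperiod) are recorded in the status table
    — one row per species x stratum with monotone indicator columns
    ``detected <= fit <= attempted`` — and the run continues.
    """
    hgam_spec = hgam_spec or HGAMSpec()
    detections.validate_sites(sites)
    detections.validate_effort(effort)
    log: list[dict] = []

    species = sorted(set(validation.species_code) | set(dets.species_code))
    thr_rows, shift_rows, retained_parts = [], [], []
    for sp in species:
        samples = validation[validation.species_code == sp]
        records = dets[dets.species_code == sp]
        if not len(samples):
            log.append({"stage": "calibrate", "species": sp, "event": "no validation data"})
            continue
        fit = calibration.fit_truepositive_model(samples)
        if fit.separated:
            thr = calibration.solve_threshold_empirical(samples, target_precision)
        else:
            thr = calibration.solve_threshold(fit, target_precision)
        retained, thr = calibration.filter_detections(records, thr)
        retained_parts.append(retained)
        thr_rows.append(
            {
                "species_code": sp,
                "cs_threshold": thr.cs_threshold,
                "status": thr.status,
                "n_total": thr.n_total,
                "n_retained": thr.n_retained,
                "fraction_retained": thr.fraction_retained,
            }
        )
        if {"day", "stratum"} <= set(samples.columns):
            shift = calibration.assess_distribution_shift(samples)
            shift_rows.append(
                {
                    "species_code": sp,
                    "aic_base": shift.aic_base,
                    "aic_day": shift.aic_day,
                    "aic_stratum": shift.aic_stratum,
                    "best_model": shift.best_model,
                }
            )
        log.append({"stage": "calibrate", "species": sp, "threshold": thr.cs_threshold,
                    "status": thr.status, "n_retained": thr.n_retained})

    thresholds = pd.DataFrame(thr_rows)
    shifts = pd.DataFrame(shift_rows)
    retained_all = (
        pd.concat(retained_parts, ignore_index=True) if retained_parts else dets.iloc[0:0]
    )

    modeled_species = list(thresholds.species_code) if len(thresholds) else []
    act = activity_mod.daily_success_rates(retained_all, effort, sites, species=modeled_species)
    gate = activity_mod.modeling_gate(act, min_sites=min_sites)
    gate_map = {(r.species_code, r.stratum): r.eligible for r in gate.itertuples()}
    log.append({"stage": "activity", "rows": len(act)})

    att_cols = {st: f"attempted_{st}" for st in detections.STRATA}
    attempted_map = {}
    for st, col in att_cols.items():
        if col in traits.columns:
            attempted_map[st] = dict(zip(traits.species_code, traits[col].astype(bool)))
        else:
            attempted_map[st] = {}

    status_rows, curve_frames, pm_rows, fits = [], [], [], {}
    for sp in modeled_species:
        for st in detections.STRATA:
            attempted = bool(attempted_map[st].get(sp, True))
            fitted = detected = False
            if attempted and gate_map.get((sp, st), False):
                cell = act[(act.species_code == sp) & (act.stratum == st)]
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        design = build_design(cell, hgam_spec)
                        fit = fit_hgam(design, hgam_spec)
                    fitted = fit.converged
                except Exception as exc:  # keep the run going; record the cell
                    log.append({"stage": "fit", "species": sp, "stratum": st,
                                "event": f"error: {exc}"})
                if fitted:
                    fits[(sp, st)] = fit
                    curve = predict_curve(fit)
                    curve_frames.append(curve.to_frame())
                    pm = phenometrics.extract_phenometrics(curve, rel_height)
                    row = pm.to_row()
                    row["deviance_explained"] = deviance_explained(fit)
                    pm_rows.append(row)
                    detected = pm.phenoperiod_detected
                    log.append({"stage": "fit", "species": sp, "stratum": st,
                                "lambda": fit.lambda_smooth, "sigma": fit.sigma_site,
                                "dev_expl": deviance_explained(fit), "detected": detected})
            status_rows.append(
                {
                    "species_code": sp,
                    "stratum": st,
                    "attempted": int(attempted),
                    "fit": int(fitted),
                    "phenoperiod_detected": int(detected),
                }
            )

    curves = (
        pd.concat(curve_frames, ignore_index=True)
        if curve_frames
        else pd.DataFrame(columns=["species_code", "stratum", "day", "p_hat"])
    )
    pm_df = pd.DataFrame(pm_rows)
    if len(pm_df):
        summary, lags = phenometrics.summarize_groups(pm_df, traits)
    else:
        summary = pd.DataFrame()
        lags = pd.DataFrame(columns=["species_code", "peak_lag_days"])
    status = pd.DataFrame(status_rows)

    return PipelineResult(thresholds, shifts, act, gate, curves, pm_df,
                          summary, lags, status, fits, log)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-based entry point: load inputs, run all stages, write artifacts."""
    for p in (config.detections_path, config.sites_path, config.effort_path,
              config.validation_path, config.traits_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    dets = pd.read_csv(config.detections_path)
    sites = pd.read_csv(config.sites_path)
    effort = pd.read_csv(config.effort_path)
    validation = pd.read_csv(config.validation_path)
    traits = pd.read_csv(config.traits_path)

    result = run_frames(
        dets, sites, effort, validation, traits,
        target_precision=config.target_precision,
        min_sites=config.min_sites,
        rel_height=config.rel_height,
        hgam_spec=config.hgam,
    )

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.thresholds.to_csv(out / "thresholds.csv", index=False)
    result.shifts.to_csv(out / "shift_assessment.csv", index=False)
    result.activity.to_csv(out / "activity.csv", index=False)
    result.curves.to_csv(out / "curves.csv", index=False)
    result.phenometrics.to_csv(out / "phenometrics.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    result.lags.to_csv(out / "peak_lags.csv", index=False)
    result.status.to_csv(out / "status.csv", index=False)
    ind = result.status.pivot(index="species_code", columns="stratum",
                              values=["attempted", "fit", "phenoperiod_detected"])
    ind.columns = [f"{a}_{b}" for a, b in ind.columns]
    retention = report_retention(result.thresholds.join(ind, on="species_code"))
    retention.to_csv(out / "retention_report.csv", index=False)
    with open(out / "runlog.jsonl", "w") as fh:
        for entry in result.log:
            fh.write(json.dumps(entry) + "\n")
    return result


INDICATOR_COLUMNS = [
    "attempted_Low", "fit_Low", "detected_Low",
    "attempted_Mid", "fit_Mid", "detected_Mid",
]


def report_retention(thresholds: pd.DataFrame) -> pd.DataFrame:
    """Retention accounting table with a totals row.

    Per species: threshold, total and retained label counts, the retained
    fraction recomputed from the counts and rounded (half-up) to 2 decimals,
    plus any per-stratum attempted/fit/detected indicator columns present.
    The totals row sums every count and indicator column and reports the
    overall retained fraction.
    """
    df = thresholds.copy()
    df["fraction_retained"] = [
        _round_half_up(r / t) if t else 0.0
        for r, t in zip(df.n_retained, df.n_total)
    ]
    indicators = [c for c in INDICATOR_COLUMNS if c in df.columns]
    total = {
        "species_code": "Total",
        "cs_threshold": np.nan,
        "n_total": int(df.n_total.sum()),
        "n_retained": int(df.n_retained.sum()),
        "fraction_retained": float(
            _round_half_up(df.n_retained.sum() / df.n_total.sum()) if df.n_total.sum() else 0.0
        ),
    }
    for c in indicators:
        total[c] = int(df[c].sum())
    cols = ["species_code", "cs_threshold", "n_total", "n_retained", "fraction_retained"]
    cols += indicators
    out = pd.concat([df[cols], pd.DataFrame([total])[cols]], ignore_index=True)
    return out
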