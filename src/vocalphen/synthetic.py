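"""Synthetic study generator: a full passive-acoustic field season in memory.

Emulates the data-generating process the pipeline assumes: recorder sites in
two elevation strata with staggered deployment windows (42 +/- 14 days), a
fixed daily schedule of analyzed 3-s segments, species-specific seasonal
vocal-activity curves on the logit scale with Gaussian site intercepts,
imperfect classifier recall, score-dependent false positives, and a
two-range manual-validation sample whose outcomes record each label's true
origin.

Truth curves are specified as a baseline logit plus Gaussian bumps
``(peak_day, amplitude, width)`` and then *rendered into the same low-rank
smooth function class the hierarchical model fits* (least-squares projection
onto the rank-``smooth_rank`` spline basis over the season window).  The
rendered curve is the ground truth: end-to-end recovery tests therefore
measure estimation error rather than basis misspecification, and the truth
phenometrics are computed by the phenometrics module applied to that curve.

Scores come from Beta distributions (true positives right-shifted, false
positives left-shifted) so that pr(TP) rises monotonically with score; an
optional linear day drift of the true-positive score location reproduces a
seasonally declining classifier precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from . import calibration, detections, phenometrics
from .hgam import PhenoCurve, spline_basis, spline_knots


@dataclass
class Bump:
    peak_day: float
    amplitude: float
    width: float


@dataclass
class StratumTruth:
    baseline_logit: float
    bumps: list[Bump] = field(default_factory=list)


@dataclass
class SpeciesTruthConfig:
    species_code: str
    strategy: str                       # R | SDM | LDM | IRR
    truth: dict[str, StratumTruth]      # stratum -> shape


@dataclass
class SimConfig:
    species: list[SpeciesTruthConfig]
    n_sites_per_stratum: int = 30
    season: tuple[int, int] = (91, 210)         # Apr 1 .. Jul 29
    deployment_mean_days: float = 42.0
    deployment_sd_days: float = 14.0
    daily_segments: int = 2800                  # 140 min of 3-s windows
    site_sigma: float = 0.5                     # SD of logit site intercepts
    recall: float = 0.5                         # P(true vocal segment -> label)
    fp_rate: float = 0.002                      # false labels per segment
    tp_score_beta: tuple[float, float] = (8.0, 2.0)
    fp_score_beta: tuple[float, float] = (2.0, 8.0)
    day_drift: float = 0.0                      # TP score-mean shift per day
    smooth_rank: int = 7
    validation_n: int = 200
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not self.species:
            raise ValueError("no species configured")
        if not 0.0 <= self.recall <= 1.0:
            raise ValueError("recall must be a probability")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        if self.deployment_mean_days < 1:
            raise ValueError("deployment length must be >= 1 day")
        if self.site_sigma < 0 or self.daily_segments <= 0:
            raise ValueError("invalid site_sigma or daily_segments")
        for sp in self.species:
            if sp.strategy not in detections.STRATEGIES:
                raise ValueError(f"unknown strategy {sp.strategy!r}")
            for st in sp.truth.values():
                if any(b.width <= 0 for b in st.bumps):
                    raise ValueError("bump widths must be positive")
        return self


@dataclass
class SimTruth:
    curves: dict[tuple[str, str], PhenoCurve]   # (species, stratum) -> truth curve
    phenometrics: pd.DataFrame                  # extraction applied to truth curves
    site_effects: dict[str, float]
    n_tp_labels: int
    n_fp_labels: int


@dataclass
class SimStudy:
    config: SimConfig
    sites: pd.DataFrame
    effort: pd.DataFrame
    detections: pd.DataFrame        # canonical columns + is_tp truth flag
    validation: pd.DataFrame
    truth: SimTruth


def render_truth_curve(truth: StratumTruth, season: tuple[int, int], rank: int) -> np.ndarray:
    """Project the bump sketch onto the rank-``rank`` spline space (logit scale)."""
    days = np.arange(season[0], season[1] + 1, dtype=float)
    eta = np.full_like(days, truth.baseline_logit)
    for b in truth.bumps:
        eta += b.amplitude * np.exp(-((days - b.peak_day) ** 2) / (2.0 * b.width**2))
    B = spline_basis(days, spline_knots(days[0], days[-1], rank))
    coef, *_ = np.linalg.lstsq(B, eta, rcond=None)
    return B @ coef


def _beta_shift(a: float, b: float, shift) -> tuple[np.ndarray, np.ndarray]:
    """Move a Beta's mean by ``shift`` at fixed concentration."""
    conc = a + b
    mu = np.clip(a / conc + np.asarray(shift), 0.02, 0.98)
    return mu * conc, (1.0 - mu) * conc


def simulate_study(config: SimConfig, seed: int | None = None) -> SimStudy:
    """Generate sites, effort, labels, validation outcomes and ground truth.

    Fully reproducible: the master seed (argument, else ``config.seed``)
    drives every draw through one generator, and iteration order is fixed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo_day, hi_day = config.season
    season_len = hi_day - lo_day + 1

    # --- sites and deployments -------------------------------------------
    elev_ranges = {"Low": (150.0, 640.0), "Mid": (660.0, 1340.0)}
    site_rows = []
    for stratum in detections.STRATA:
        for i in range(config.n_sites_per_stratum):
            dur = int(np.clip(round(rng.normal(config.deployment_mean_days,
                                               config.deployment_sd_days)), 7, season_len))
            first = int(rng.integers(lo_day, hi_day - dur + 2))
            site_rows.append(
                {
                    "site_id": f"{stratum[0]}{i + 1:03d}",
                    "stratum": stratum,
                    "elevation_m": round(float(rng.uniform(*elev_ranges[stratum])), 1),
                    "first_day": first,
                    "last_day": first + dur - 1,
                }
            )
    sites = pd.DataFrame(site_rows, columns=detections.SITE_COLUMNS)
    site_effects = {s: float(rng.normal(0.0, config.site_sigma)) for s in sites.site_id}

    effort = pd.concat(
        [
            pd.DataFrame(
                {"site_id": s.site_id,
                 "day": np.arange(s.first_day, s.last_day + 1),
                 "n_segments": config.daily_segments}
            )
            for s in sites.itertuples()
        ],
        ignore_index=True,
    )

    # --- truth curves -----------------------------------------------------
    season_days = np.arange(lo_day, hi_day + 1)
    curves: dict[tuple[str, str], PhenoCurve] = {}
    for sp in config.species:
        for stratum, st_truth in sorted(sp.truth.items()):
            eta = render_truth_curve(st_truth, config.season, config.smooth_rank)
            curves[(sp.species_code, stratum)] = PhenoCurve(
                sp.species_code, stratum, season_days.copy(), expit(eta)
            )

    # --- classifier labels ------------------------------------------------
    a_tp, b_tp = config.tp_score_beta
    a_fp, b_fp = config.fp_score_beta
    mid_day = (lo_day + hi_day) / 2.0
    seg = config.daily_segments
    cols: dict[str, list] = {c: [] for c in detections.DETECTION_COLUMNS + ["is_tp"]}
    n_tp_total = n_fp_total = 0

    for sp in config.species:
        for site in sites.itertuples():
            key = (sp.species_code, site.stratum)
            if key not in curves:
                continue
            days = np.arange(site.first_day, site.last_day + 1)
            p = expit(
                np.log(curves[key].p / (1 - curves[key].p))[days - lo_day]
                + site_effects[site.site_id]
            )
            k_true = rng.binomial(seg, p)
            n_tp = rng.binomial(k_true, config.recall)
            n_fp = rng.poisson(config.fp_rate * seg, size=len(days))
            for d, nt, nf in zip(days, n_tp, n_fp):
                total = int(nt + nf)
                if total == 0:
                    continue
                segments = rng.choice(seg, size=total, replace=False)
                if nt:
                    at, bt = _beta_shift(a_tp, b_tp, config.day_drift * (d - mid_day))
                    scores_tp = rng.beta(at, bt, size=int(nt))
                else:
                    scores_tp = np.empty(0)
                scores_fp = rng.beta(a_fp, b_fp, size=int(nf)) if nf else np.empty(0)
                scores = np.concatenate([scores_tp, scores_fp])
                cols["site_id"].extend([site.site_id] * total)
                cols["species_code"].extend([sp.species_code] * total)
                cols["day"].extend([int(d)] * total)
                cols["segment_start"].extend((segments * 3.0).tolist())
                cols["score"].extend(scores.tolist())
                cols["is_tp"].extend([True] * int(nt) + [False] * int(nf))
                n_tp_total += int(nt)
                n_fp_total += int(nf)

    labels = pd.DataFrame(cols)

    # --- validation set ---------------------------------------------------
    strat_map = dict(zip(sites.site_id, sites.stratum))
    val_frames = []
    for sp in config.species:
        pool = labels[labels.species_code == sp.species_code]
        if not len(pool):
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sample = calibration.sample_validation_clips(
            pool, n_total=config.validation_n, seed=sub_seed
        )
        val_frames.append(
            pd.DataFrame(
                {
                    "clip_id": sample.clip_id,
                    "species_code": sample.species_code,
                    "score": sample.score,
                    "outcome": sample.is_tp.astype(int),
                    "vocal_class": "song",
                    "day": sample.day,
                    "stratum": sample.site_id.map(strat_map),
                }
            )
        )
    validation = (
        pd.concat(val_frames, ignore_index=True)
        if val_frames
        else pd.DataFrame(columns=calibration.VALIDATION_COLUMNS)
    )

    truth_pm = pd.DataFrame(
        [phenometrics.extract_phenometrics(c).to_row() for c in curves.values()]
    )
    truth = SimTruth(curves, truth_pm, site_effects, n_tp_total, n_fp_total)
    return SimStudy(config, sites, effort, labels, validation, truth)


def make_paper_like_community(seed: int = 0) -> SimConfig:
    """A ready-made six-species community spanning the four migratory strategies.

    Template shapes: residents start early and stay vocal long (the early
    resident is already within 30% of its seasonal maximum on day 1 of the
    season, so its phenoperiod start is boundary-flagged); one resident is
    bimodal with a second bump 48 days after the first; long-distance
    migrants rise late and briefly; the irruptive species peaks last.  Every
    species' Mid-stratum curve lags its Low curve by 17 days.
    """
    lag = 17.0

    def pair(base: float, bumps_low: list[Bump], width_scale_mid: float = 1.0):
        bumps_mid = [Bump(b.peak_day + lag, b.amplitude, b.width * width_scale_mid)
                     for b in bumps_low]
        return {"Low": StratumTruth(base, bumps_low), "Mid": StratumTruth(base, bumps_mid)}

    species = [
        SpeciesTruthConfig("REAR", "R", pair(-5.2, [Bump(115, 2.6, 30)])),
        SpeciesTruthConfig("RBIM", "R",
                           pair(-6.0, [Bump(120, 2.5, 18), Bump(168, 2.125, 18)])),
        SpeciesTruthConfig("SDMA", "SDM", pair(-6.0, [Bump(140, 2.8, 22)])),
        SpeciesTruthConfig("LDMA", "LDM", pair(-6.5, [Bump(158, 3.0, 18)])),
        SpeciesTruthConfig("LDMB", "LDM", pair(-6.2, [Bump(150, 2.6, 20)])),
        SpeciesTruthConfig("IRRA", "IRR", pair(-6.5, [Bump(180, 2.6, 18)])),
    ]
    return SimConfig(species=species, seed=seed)


def community_traits(config: SimConfig) -> pd.DataFrame:
    """Species-trait table for a simulated community (all cells attempted)."""
    rows = [
        {
            "species_code": sp.species_code,
            "common_name": sp.species_code,
            "scientific_name": sp.species_code,
            "strategy": sp.strategy,
            "attempted_Low": "Low" in sp.truth,
            "attempted_Mid": "Mid" in sp.truth,
        }
        for sp in config.species
    ]
    return pd.DataFrame(rows)


def write_study(study: SimStudy, outdir) -> None:
    """Emit the exact file formats the pipeline consumes, plus a truth JSON."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study.sites.to_csv(out / "sites.csv", index=False)
    study.effort.to_csv(out / "effort.csv", index=False)
    study.detections.to_csv(out / "detections.csv", index=False)
    study.validation.to_csv(out / "validation.csv", index=False)
    community_traits(study.config).to_csv(out / "traits.csv", index=False)
    truth = {
        "n_tp_labels": study.truth.n_tp_labels,
        "n_fp_labels": study.truth.n_fp_labels,
        "site_effects": study.truth.site_effects,
        "curves": {
            f"{sp}|{st}": {"days": c.days.tolist(), "p": c.p.tolist()}
            for (sp, st), c in study.truth.curves.items()
        },
    }
    (out / "truth.json").write_text(json.dumps(truth))
    study.truth.phenometrics.to_csv(out / "truth_phenometrics.csv", index=False)
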