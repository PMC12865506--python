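"""Precision calibration of classifier confidence scores.

A reviewed sample of clips (binary true/false outcomes against confidence
score CS) feeds a logistic model ``logit pr(TP) = b0 + b1*CS``.  The
species-specific retention threshold is the smallest score whose fitted
true-positive probability reaches a target precision (0.95 by default);
labels below it are discarded.  The same logistic machinery, with day-of-year
or elevation-stratum terms added, screens the validation data for classifier
"distribution shift" via AIC comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit

VALIDATION_COLUMNS = ["clip_id", "species_code", "score", "outcome", "vocal_class", "day", "stratum"]

#: the verification design's score ranges; the high range intentionally
#: oversamples high-scoring labels to pin down pr(TP) near the threshold
DEFAULT_SCORE_RANGES = ((0.1, 1.0), (0.95, 1.0))


@dataclass
class CalibrationFit:
    """Maximum-likelihood logistic fit of validation outcome on score."""

    species_code: str
    params: np.ndarray          # (intercept, slope on score, extra covariates...)
    param_names: list[str]
    loglik: float
    aic: float
    n_samples: int
    n_positive: int
    converged: bool
    separated: bool = False
    #: None, "all_positive" or "all_negative" when only one outcome class is present
    degenerate: str | None = None

    @property
    def b0(self) -> float:
        return float(self.params[0])

    @property
    def b1(self) -> float:
        return float(self.params[1])


@dataclass
class ThresholdResult:
    """Solved minimum confidence score achieving the target precision."""

    species_code: str
    target_precision: float
    cs_threshold: float
    #: "ok" | "unattainable" | "all_true" | "empirical"
    status: str = "ok"
    n_total: int | None = None
    n_retained: int | None = None
    fraction_retained: float | None = None


@dataclass
class ShiftAssessment:
    """AIC comparison of score-only vs score+day vs score+stratum precision models."""

    species_code: str
    aic_base: float
    aic_day: float
    aic_stratum: float
    best_model: str  # "base" | "day" | "stratum"; ties break toward base
    notes: list[str]


def sample_validation_clips(
    records: pd.DataFrame,
    n_total: int = 200,
    score_ranges=DEFAULT_SCORE_RANGES,
    quotas: tuple[int, ...] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw clips for manual review, stratified over score ranges.

    Per-range quotas default to an even split of ``n_total``.  Sampling is
    without replacement across ranges (a clip reviewed once is not drawn
    again); if a range holds fewer records than its quota, every record in it
    is taken and a shortfall warning is emitted.  Deterministic under ``seed``.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if quotas is None:
        base, extra = divmod(n_total, len(score_ranges))
        quotas = tuple(base + (1 if i < extra else 0) for i in range(len(score_ranges)))
    if sum(quotas) != n_total:
        raise ValueError("quotas must sum to n_total")

    rng = np.random.default_rng(seed)
    taken: list[pd.DataFrame] = []
    used = pd.Index([])
    for (lo, hi), quota in zip(score_ranges, quotas):
        pool = records[(records.score >= lo) & (records.score <= hi)]
        pool = pool.loc[pool.index.difference(used)]
        if len(pool) < quota:
            warnings.warn(
                f"score range [{lo}, {hi}]: only {len(pool)} records for quota {quota}",
                stacklevel=2,
            )
            chosen = pool
        else:
            chosen = pool.loc[rng.choice(pool.index.to_numpy(), size=quota, replace=False)]
        chosen = chosen.assign(score_range=f"[{lo}, {hi}]")
        used = used.union(chosen.index)
        taken.append(chosen)
    out = pd.concat(taken).sort_index()
    out.index.name = "clip_id"
    return out.reset_index()


def _logistic_fit(y: np.ndarray, X: np.ndarray):
    """GLM binomial fit returning (params, loglik, converged, separated)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception:
            return None, np.nan, False, True
    params = np.asarray(res.params, dtype=float)
    # magnitude guard is numerical safety only; genuine one-covariate
    # separation is caught exactly upstream from the class score ordering
    separated = bool(np.any(np.abs(params) > 1e3) or not np.all(np.isfinite(params)))
    converged = bool(res.converged) and not separated
    return params, float(res.llf), converged, separated


def fit_truepositive_model(
    samples: pd.DataFrame, extra_covariates: list[str] | None = None
) -> CalibrationFit:
    """Fit ``logit pr(TP) = b0 + b1*score (+ extras)`` to reviewed clips.

    The score enters untransformed, keeping the precision threshold available
    in closed form.  One-class data are flagged ``degenerate`` and perfectly
    separated data ``separated``; neither reports a finite MLE.
    """
    species = samples.species_code.iloc[0] if len(samples) else "?"
    y = samples.outcome.to_numpy(dtype=float)
    n, n_pos = len(y), int(y.sum())
    names = ["intercept", "score"] + list(extra_covariates or [])

    if n_pos == n or n_pos == 0 or n < 2:
        kind = "all_positive" if n and n_pos == n else "all_negative"
        return CalibrationFit(species, np.full(len(names), np.nan), names,
                              np.nan, np.nan, n, n_pos, False, False, kind)

    scores = samples.score.to_numpy(dtype=float)
    cols = [np.ones(n), scores]
    for cov in extra_covariates or []:
        v = samples[cov]
        cols.append(pd.factorize(v)[0].astype(float) if v.dtype == object else v.to_numpy(float))
    X = np.column_stack(cols)

    if not extra_covariates:
        # with a single covariate, (quasi-)complete separation is exactly the
        # absence of score overlap between outcome classes: no finite MLE
        s0, s1 = scores[y == 0], scores[y == 1]
        if s0.max() <= s1.min() or s1.max() <= s0.min():
            return CalibrationFit(species, np.full(len(names), np.nan), names,
                                  np.nan, np.nan, n, n_pos, False, True)

    params, llf, converged, separated = _logistic_fit(y, X)
    if separated:
        return CalibrationFit(species, np.full(len(names), np.nan), names,
                              np.nan, np.nan, n, n_pos, False, True)
    aic = -2.0 * llf + 2.0 * len(names)
    return CalibrationFit(species, params, names, llf, aic, n, n_pos, converged)


def solve_threshold(fit: CalibrationFit, target: float = 0.95) -> ThresholdResult:
    """Invert the fitted logistic for the minimum score reaching ``target``.

    ``CS* = (logit(target) - b0) / b1`` for a positive slope, clamped into
    [0, 1].  A solution above 1 means the target precision is unattainable at
    any score (threshold 1, nothing retained); a solution below the lowest
    observed score is legal and retains everything.  Non-positive slopes are
    unattainable; degenerate all-positive data give threshold 0.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target precision must lie in (0, 1)")
    sp = fit.species_code
    if fit.degenerate == "all_positive":
        return ThresholdResult(sp, target, 0.0, "all_true")
    if fit.degenerate == "all_negative":
        return ThresholdResult(sp, target, 1.0, "unattainable")
    if fit.separated or not np.isfinite(fit.b1):
        raise ValueError(
            "separated/degenerate fit has no finite MLE; use solve_threshold_empirical"
        )
    if fit.b1 <= 0:
        return ThresholdResult(sp, target, 1.0, "unattainable")
    raw = (logit(target) - fit.b0) / fit.b1
    if raw > 1.0:
        return ThresholdResult(sp, target, 1.0, "unattainable")
    return ThresholdResult(sp, target, float(max(raw, 0.0)), "ok")


def solve_threshold_empirical(
    samples: pd.DataFrame, target: float = 0.95, step: float = 0.001
) -> ThresholdResult:
    """Fallback for separated fits: scan the empirical precision-at-threshold
    curve and return the smallest grid score whose retained-sample precision
    reaches the target (threshold 1 / unattainable if none does)."""
    sp = samples.species_code.iloc[0] if len(samples) else "?"
    scores = samples.score.to_numpy(float)
    y = samples.outcome.to_numpy(float)
    for t in np.arange(0.0, 1.0 + step / 2, step):
        keep = scores >= t
        if keep.sum() and y[keep].mean() >= target:
            return ThresholdResult(sp, target, float(t), "empirical")
    return ThresholdResult(sp, target, 1.0, "unattainable")


def filter_detections(records: pd.DataFrame, threshold: ThresholdResult):
    """Retain labels with ``score >= cs_threshold``; idempotent.

    Returns ``(retained, result)`` where ``result`` carries the retention
    accounting (total, retained, fraction; fraction 0 on empty input).
    """
    retained = records[records.score >= threshold.cs_threshold]
    n_total, n_ret = len(records), len(retained)
    frac = (n_ret / n_total) if n_total else 0.0
    return retained, replace(
        threshold, n_total=n_total, n_retained=n_ret, fraction_retained=frac
    )


def threshold_sensitivity(
    records: pd.DataFrame, fit: CalibrationFit, targets: list[float]
) -> pd.DataFrame:
    """Retention and site coverage across a ladder of precision targets.

    For each target (ascending): the solved threshold, the number of retained
    labels and the number of distinct sites that keep at least one label.
    Both counts are non-increasing in the target.
    """
    if list(targets) != sorted(targets):
        raise ValueError("targets must be sorted ascending")
    rows = []
    for tgt in targets:
        thr = solve_threshold(fit, tgt)
        retained, thr = filter_detections(records, thr)
        rows.append(
            {
                "target": tgt,
                "cs_threshold": thr.cs_threshold,
                "status": thr.status,
                "n_retained": thr.n_retained,
                "n_sites_with_labels": retained.site_id.nunique(),
            }
        )
    return pd.DataFrame(rows)


def assess_distribution_shift(samples: pd.DataFrame) -> ShiftAssessment:
    """Compare precision models with and without seasonal/stratum covariates.

    Fits score-only, score+day and score+stratum logistic models to the same
    clips and ranks them by AIC (``-2 loglik + 2k``); a lower-AIC covariate
    model signals classifier performance drifting over season or habitat.
    Ties break toward the base model (parsimony).  Missing covariates yield a
    partial assessment with the omission noted.
    """
    sp = samples.species_code.iloc[0] if len(samples) else "?"
    y = samples.outcome.to_numpy(float)
    s = samples.score.to_numpy(float)
    one = np.ones(len(y))

    def aic_of(X):
        params, llf, converged, separated = _logistic_fit(y, X)
        if separated or not converged:
            return np.nan
        return -2.0 * llf + 2.0 * X.shape[1]

    notes: list[str] = []
    aic_base = aic_of(np.column_stack([one, s]))
    if "day" in samples and samples.day.notna().all():
        aic_day = aic_of(np.column_stack([one, s, samples.day.to_numpy(float)]))
    else:
        aic_day, _ = np.nan, notes.append("day covariate unavailable")
    if "stratum" in samples and samples.stratum.notna().all():
        strat = pd.factorize(samples.stratum)[0].astype(float)
        if len(np.unique(strat)) > 1:
            aic_stratum = aic_of(np.column_stack([one, s, strat]))
        else:
            aic_stratum, _ = np.nan, notes.append("single stratum only")
    else:
        aic_stratum, _ = np.nan, notes.append("stratum covariate unavailable")

    aics = {"base": aic_base, "day": aic_day, "stratum": aic_stratum}
    finite = {k: v for k, v in aics.items() if np.isfinite(v)}
    best = "base"
    if finite:
        lowest = min(finite.values())
        if np.isfinite(aic_base) and aic_base <= lowest:
            best = "base"
        else:
            best = min(finite, key=finite.get)
    return ShiftAssessment(sp, aic_base, aic_day, aic_stratum, best, notes)


def predicted_precision(fit: CalibrationFit, score) -> np.ndarray:
    """Fitted pr(TP) at the given score(s)."""
    return expit(fit.b0 + fit.b1 * np.asarray(score, dtype=float))
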