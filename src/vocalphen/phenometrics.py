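"""Phenometrics: standardized features of a fitted vocal-activity curve.

From one daily curve of predicted vocalization probability we extract

1. qualifying **peaks** — interior local maxima whose height reaches at
   least 30% of the curve's global maximum;
2. **half-rises** — the day the curve first reaches halfway between a local
   minimum and the next chronological peak;
3. **half-declines** — the falling-side mirror image;
4. the **phenoperiod** — first half-rise to last half-decline, with a
   boundary fallback: when the curve is already (or still) within 30% of its
   seasonal maximum at the window edge, the edge date is used and flagged.

All rules operate on the daily grid; crossings are linearly interpolated to
a fractional day and floored to a whole date.  Extraction is equivariant
under shifting the day grid and invariant under rescaling the probability
axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_REL_HEIGHT = 0.30


@dataclass
class Phenometrics:
    species_code: str
    stratum: str
    peaks: list[tuple[int, float]]      # (day, p) of qualifying interior maxima
    half_rises: list[int]
    half_declines: list[int]
    start_day: int | None
    end_day: int | None
    start_is_boundary: bool
    end_is_boundary: bool
    duration_days: int | None
    phenoperiod_detected: bool

    @property
    def primary_peak_day(self) -> int | None:
        """Day of the tallest qualifying peak (first on exact ties)."""
        if not self.peaks:
            return None
        return max(self.peaks, key=lambda t: (t[1], -t[0]))[0]

    def to_row(self) -> dict:
        return {
            "species_code": self.species_code,
            "stratum": self.stratum,
            "n_peaks": len(self.peaks),
            "peak_days": ";".join(str(d) for d, _ in self.peaks),
            "primary_peak_day": self.primary_peak_day,
            "half_rises": ";".join(map(str, self.half_rises)),
            "half_declines": ";".join(map(str, self.half_declines)),
            "start_day": self.start_day,
            "end_day": self.end_day,
            "start_is_boundary": self.start_is_boundary,
            "end_is_boundary": self.end_is_boundary,
            "duration_days": self.duration_days,
            "phenoperiod_detected": self.phenoperiod_detected,
        }


def _interior_maxima(p: np.ndarray) -> list[int]:
    # plateau maxima resolve to their first day via the strict/loose asymmetry
    return [i for i in range(1, len(p) - 1) if p[i] > p[i - 1] and p[i] >= p[i + 1]]


def _interior_minima(p: np.ndarray) -> list[int]:
    return [i for i in range(1, len(p) - 1) if p[i] < p[i - 1] and p[i] <= p[i + 1]]


def find_peaks(curve, rel_height: float = DEFAULT_REL_HEIGHT) -> list[tuple[int, float]]:
    """Qualifying peaks: interior local maxima with ``p >= rel_height * max(p)``.

    A strictly monotone curve has no interior peaks (the boundary rule of the
    phenoperiod handles edge activity separately).
    """
    days, p = np.asarray(curve.days), np.asarray(curve.p)
    if len(p) < 3:
        return []
    cut = rel_height * p.max()
    return [(int(days[i]), float(p[i])) for i in _interior_maxima(p) if p[i] >= cut]


def _crossing_day(days, p, i_from, i_to, level, rising: bool):
    """First whole day in (i_from, i_to] where the curve crosses ``level``."""
    rng = range(i_from + 1, i_to + 1)
    for i in rng:
        hit = p[i] >= level if rising else p[i] <= level
        if hit:
            prev_off = p[i - 1] < level if rising else p[i - 1] > level
            if prev_off and p[i] != p[i - 1]:
                frac = (level - p[i - 1]) / (p[i] - p[i - 1])
                day = days[i - 1] + frac * (days[i] - days[i - 1])
            else:
                day = days[i]
            return int(np.floor(day))
    return None


def half_crossings(
    curve, peaks: list[tuple[int, float]], rel_height: float = DEFAULT_REL_HEIGHT
):
    """Half-rise and half-decline days for each peak episode.

    The curve's first and last days serve as local minima when no interior
    minimum precedes/follows a peak.  A window edge that sits within
    ``rel_height`` of the global maximum and falls away from it acts as a
    boundary maximum: it anchors a half-decline (start edge) or half-rise
    (end edge) even when no interior peak exists, which is how a curve that
    is already declining on day one still gets a period end.
    """
    days, p = np.asarray(curve.days), np.asarray(curve.p)
    if len(p) < 2:
        return [], []
    minima = _interior_minima(p)
    cut = rel_height * p.max()
    last = len(p) - 1

    # (index, wants_rise, wants_decline)
    anchors = [(int(np.where(days == d)[0][0]), True, True) for d, _ in peaks]
    if p[0] >= cut and len(p) > 1 and p[0] > p[1]:
        anchors.append((0, False, True))
    if p[last] >= cut and p[last] > p[last - 1]:
        anchors.append((last, True, False))
    anchors.sort()

    rises, declines = [], []
    for j, want_rise, want_decline in anchors:
        if want_rise and j > 0:
            pre = max((i for i in minima if i < j), default=0)
            if p[j] > p[pre]:
                d = _crossing_day(days, p, pre, j, (p[pre] + p[j]) / 2.0, rising=True)
                if d is not None:
                    rises.append(d)
        if want_decline and j < last:
            post = min((i for i in minima if i > j), default=last)
            if p[j] > p[post]:
                d = _crossing_day(days, p, j, post, (p[post] + p[j]) / 2.0, rising=False)
                if d is not None:
                    declines.append(d)
    return sorted(rises), sorted(declines)


def phenoperiod(
    curve,
    peaks: list[tuple[int, float]],
    crossings: tuple[list[int], list[int]],
    rel_height: float = DEFAULT_REL_HEIGHT,
):
    """Phenoperiod start/end/duration with boundary flags.

    Start is the first half-rise unless the first modeled day already sits
    within ``rel_height`` of the seasonal maximum, in which case the first
    day is used and flagged as a boundary start; the end is symmetric.  A
    curve with no qualifying structure at all (no peak, no crossing — e.g. a
    flat line) has no detectable phenoperiod even though the boundary test
    is vacuously true there.
    """
    days, p = np.asarray(curve.days), np.asarray(curve.p)
    rises, declines = crossings
    cut = rel_height * p.max() if len(p) else np.inf

    start = end = None
    start_b = end_b = False
    if len(p):
        if p[0] >= cut:
            start, start_b = int(days[0]), True
        elif rises:
            start = rises[0]
        if p[-1] >= cut:
            end, end_b = int(days[-1]), True
        elif declines:
            end = declines[-1]

    structure = bool(peaks or rises or declines)
    detected = structure and start is not None and end is not None and end >= start
    return {
        "start_day": start if detected else None,
        "end_day": end if detected else None,
        "start_is_boundary": start_b if detected else False,
        "end_is_boundary": end_b if detected else False,
        "duration_days": (end - start) if detected else None,
        "phenoperiod_detected": detected,
    }


def extract_phenometrics(curve, rel_height: float = DEFAULT_REL_HEIGHT) -> Phenometrics:
    """Run the full extraction (peaks, crossings, phenoperiod) on one curve."""
    peaks = find_peaks(curve, rel_height)
    rises, declines = half_crossings(curve, peaks, rel_height)
    period = phenoperiod(curve, peaks, (rises, declines), rel_height)
    return Phenometrics(
        species_code=curve.species_code,
        stratum=curve.stratum,
        peaks=peaks,
        half_rises=rises,
        half_declines=declines,
        **period,
    )


def summarize_groups(phenos: pd.DataFrame, traits: pd.DataFrame):
    """Group means of onset/peak/duration by migratory strategy x stratum.

    Only detected phenoperiods enter the means; boundary-flagged starts are
    included at their boundary dates (the count of such cells is reported).
    Also returns the per-species cross-stratum peak lag (Mid minus Low) for
    species modeled in both strata, and its overall mean.
    """
    df = phenos.merge(traits[["species_code", "strategy"]], on="species_code", how="left")
    det = df[df.phenoperiod_detected].copy()

    summary = (
        det.groupby(["strategy", "stratum"])
        .agg(
            mean_onset=("start_day", "mean"),
            mean_peak=("primary_peak_day", "mean"),
            mean_duration=("duration_days", "mean"),
            n_species=("species_code", "nunique"),
            n_boundary_start=("start_is_boundary", "sum"),
            n_boundary_end=("end_is_boundary", "sum"),
        )
        .reset_index()
    )

    wide = det.pivot_table(index="species_code", columns="stratum",
                           values="primary_peak_day", aggfunc="first")
    if {"Low", "Mid"} <= set(wide.columns):
        both = wide.dropna(subset=["Low", "Mid"])
        lags = (both.Mid - both.Low).rename("peak_lag_days").reset_index()
    else:
        lags = pd.DataFrame(columns=["species_code", "peak_lag_days"])
    return summary, lags
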