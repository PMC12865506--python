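"""Reading, validating and writing classifier label tables and survey metadata.

The pipeline's canonical in-memory containers are plain :class:`pandas.DataFrame`
objects with fixed column sets:

``detections``
    one row per classifier label: ``site_id``, ``species_code``, ``day``
    (1-based ordinal day of year), ``segment_start`` (seconds within the
    day's recording), ``score`` (classifier confidence in [0, 1]).
``sites``
    one row per recorder deployment: ``site_id``, ``stratum`` (``Low``/``Mid``),
    ``elevation_m``, ``first_day``, ``last_day``.
``effort``
    one row per (site, day) actually analyzed: ``site_id``, ``day``,
    ``n_segments`` (count of analyzed 3-s windows).
``traits``
    one row per species: ``species_code``, names, ``strategy`` (``R``/``SDM``/
    ``LDM``/``IRR``), elevation summary columns.

All internal time is integer ordinal day; sub-day time is retained only as
``segment_start`` provenance.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["site_id", "species_code", "day", "segment_start", "score"]
SITE_COLUMNS = ["site_id", "stratum", "elevation_m", "first_day", "last_day"]
EFFORT_COLUMNS = ["site_id", "day", "n_segments"]

STRATA = ("Low", "Mid")
STRATEGIES = ("R", "SDM", "LDM", "IRR")

#: Stratum bounds (metres): Low below ``low_max``, Mid in [``low_max``, ``mid_max``].
DEFAULT_STRATA_BOUNDS = {"low_max": 650.0, "mid_max": 1350.0}


class FormatError(ValueError):
    """Raised when an input table's header cannot be interpreted."""


@dataclass
class DetectionDialect:
    """Column and filename conventions of a classifier output table.

    Classifier CSV layouts vary between versions, so the mapping lives in
    config.  The defaults follow the common combined-output layout with
    columns ``Start (s)``, ``End (s)``, ``Scientific name``, ``Common name``,
    ``Confidence`` plus a source-file column, where the audio filename encodes
    the recording site and date (e.g. ``SITE042_20210514_0500.wav``).
    """

    sep: str = ","
    file_col: str = "File"
    start_col: str = "Start (s)"
    species_col: str = "Common name"
    score_col: str = "Confidence"
    #: regex with named groups ``site`` and ``date`` applied to the file column
    filename_pattern: str = r"(?P<site>[A-Za-z0-9-]+)_(?P<date>\d{8})_\d+\.\w+$"
    date_format: str = "%Y%m%d"
    #: optional mapping from the species column's values to 4-letter codes;
    #: when empty the column value is used verbatim
    species_map: dict[str, str] = field(default_factory=dict)
    segment_seconds: float = 3.0


def _ordinal_day(date_str: str, fmt: str) -> int:
    return datetime.strptime(date_str, fmt).timetuple().tm_yday


def read_detection_table(path, dialect: DetectionDialect | None = None):
    """Read a classifier label table into the canonical detections frame.

    Returns ``(detections, rejects)``; every input row either becomes a
    canonical record or lands in ``rejects`` with a ``reason``.  Scores
    outside [0, 1] are rejected.  Any score inside [0, 1] is retained: a
    minimum-score floor is a property of the classifier run, not of the
    reader.

    Raises :class:`FormatError` when required columns are missing.
    """
    dialect = dialect or DetectionDialect()
    raw = pd.read_csv(path, sep=dialect.sep)
    required = {dialect.file_col, dialect.start_col, dialect.species_col, dialect.score_col}
    missing = required - set(raw.columns)
    if missing:
        raise FormatError(f"missing required columns: {sorted(missing)}")

    pattern = re.compile(dialect.filename_pattern)
    rows, rejects = [], []
    for idx, row in raw.iterrows():
        reason = None
        score = row[dialect.score_col]
        start = row[dialect.start_col]
        species = row[dialect.species_col]
        m = pattern.search(str(row[dialect.file_col]))
        if m is None:
            reason = "unparsable site/date in filename"
        elif not (isinstance(score, (int, float)) and 0.0 <= score <= 1.0):
            reason = "score outside [0, 1]"
        elif not (isinstance(start, (int, float)) and start >= 0):
            reason = "negative segment start"
        elif not isinstance(species, str) or not species.strip():
            reason = "empty species"
        else:
            code = dialect.species_map.get(species, species if not dialect.species_map else None)
            if code is None:
                reason = f"unmapped species {species!r}"
            else:
                try:
                    day = _ordinal_day(m.group("date"), dialect.date_format)
                except ValueError:
                    reason = "unparsable date"
                else:
                    rows.append((m.group("site"), code, day, float(start), float(score)))
        if reason is not None:
            rejects.append((idx, reason))

    detections = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    rejects_df = pd.DataFrame(rejects, columns=["input_row", "reason"])
    if len(rejects_df):
        warnings.warn(f"{len(rejects_df)} rows rejected while reading {path}", stacklevel=2)
    return detections, rejects_df


def write_detection_table(detections: pd.DataFrame, path) -> None:
    """Write the canonical detections frame (lossless round-trip partner of
    :func:`read_canonical_detections`)."""
    detections[DETECTION_COLUMNS].to_csv(path, index=False)


def read_canonical_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing canonical columns: {sorted(missing)}")
    return df[DETECTION_COLUMNS].astype(
        {"site_id": str, "species_code": str, "day": int, "segment_start": float, "score": float}
    )


@dataclass
class RecordingSchedule:
    """Daily recording blocks, each ``(start_minute_of_day, duration_minutes)``.

    The survey design this emulates records a long post-sunrise block plus two
    short mid-morning samples (120 + 10 + 10 = 140 min/day); effort is always
    taken from the realized inventory, never assumed constant, so the schedule
    is only used to *build* an inventory.
    """

    blocks: list[tuple[float, float]]
    segment_seconds: float = 3.0

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("schedule needs at least one block")
        ordered = sorted(self.blocks)
        for (s0, d0), (s1, _) in zip(ordered, ordered[1:]):
            if s1 < s0 + d0:
                raise ValueError(f"overlapping blocks at minute {s1}")
        if any(d <= 0 for _, d in self.blocks):
            raise ValueError("block durations must be positive")

    @property
    def total_minutes(self) -> float:
        return float(sum(d for _, d in self.blocks))

    @property
    def segments_per_day(self) -> int:
        return math.floor(self.total_minutes * 60.0 / self.segment_seconds)


def build_effort_table(schedule: RecordingSchedule, sites: pd.DataFrame) -> pd.DataFrame:
    """Expand a schedule over deployment windows into a per-site-day inventory.

    One row per deployed (site, day) with ``n_segments = floor(total scheduled
    minutes * 60 / segment length)``; days outside a site's deployment window
    have no row at all (structurally missing, not zero).
    """
    n_seg = schedule.segments_per_day
    frames = []
    for _, s in sites.iterrows():
        days = np.arange(int(s.first_day), int(s.last_day) + 1)
        frames.append(pd.DataFrame({"site_id": s.site_id, "day": days, "n_segments": n_seg}))
    if not frames:
        return pd.DataFrame(columns=EFFORT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def stratum_for_elevation(elevation_m: float, bounds: dict | None = None) -> str:
    b = bounds or DEFAULT_STRATA_BOUNDS
    if elevation_m < b["low_max"]:
        return "Low"
    if elevation_m <= b["mid_max"]:
        return "Mid"
    raise ValueError(f"elevation {elevation_m} m above the Mid stratum ceiling")


def validate_sites(sites: pd.DataFrame, bounds: dict | None = None) -> pd.DataFrame:
    """Check deployment-window ordering and stratum/elevation consistency."""
    missing = set(SITE_COLUMNS) - set(sites.columns)
    if missing:
        raise FormatError(f"site table missing columns: {sorted(missing)}")
    bad_window = sites[sites.first_day > sites.last_day]
    if len(bad_window):
        raise ValueError(f"first_day > last_day for sites {list(bad_window.site_id)}")
    expected = sites.elevation_m.map(lambda e: stratum_for_elevation(e, bounds))
    mismatched = sites[expected != sites.stratum]
    if len(mismatched):
        raise ValueError(f"stratum inconsistent with elevation for sites {list(mismatched.site_id)}")
    if sites.site_id.duplicated().any():
        raise ValueError("duplicate site ids")
    return sites


def validate_effort(effort: pd.DataFrame) -> pd.DataFrame:
    if (effort.n_segments < 0).any():
        raise ValueError("negative segment counts in effort table")
    if effort.duplicated(["site_id", "day"]).any():
        raise ValueError("more than one effort row for a (site, day)")
    return effort
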