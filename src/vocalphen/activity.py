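"""Daily call density (binomial success rate) and the modeling eligibility gate.

A day's "success rate" for a species at a site is the number of retained
classifier labels divided by the number of analyzed 3-s segments that day —
a binomial proportion that intrinsically normalizes for unequal recording
effort across sites and days.
"""

from __future__ import annotations

import warnings

import pandas as pd

ACTIVITY_COLUMNS = ["species_code", "site_id", "stratum", "day", "k_labels", "n_segments", "rate"]


def daily_success_rates(
    retained: pd.DataFrame,
    effort: pd.DataFrame,
    sites: pd.DataFrame,
    species: list[str] | None = None,
) -> pd.DataFrame:
    """Build the species x site x day activity table from retained labels.

    Every deployed site-day (every effort row) appears for every species,
    including zero-label days — the smooth needs the zeros.  Days outside
    deployment are structurally absent.  Multiple labels of one species
    within the same 3-s segment collapse to one (the segment is the Bernoulli
    trial), which also keeps k <= n.

    Raises ``ValueError`` when a retained label has no effort row for its
    (site, day).
    """
    if species is None:
        species = sorted(retained.species_code.unique())

    eff = effort.merge(sites[["site_id", "stratum"]], on="site_id", how="left")

    if len(retained):
        key = retained.merge(effort[["site_id", "day"]], on=["site_id", "day"],
                             how="left", indicator=True)
        orphans = key[key._merge == "left_only"]
        if len(orphans):
            offenders = orphans[["site_id", "day"]].drop_duplicates().to_records(index=False)
            raise ValueError(f"retained labels without effort rows: {list(offenders)[:20]}")

    # one Bernoulli trial per segment: collapse duplicate labels in a segment
    dedup = retained.drop_duplicates(["species_code", "site_id", "day", "segment_start"])
    counts = (
        dedup.groupby(["species_code", "site_id", "day"]).size().rename("k_labels").reset_index()
    )

    frames = []
    for sp in species:
        block = eff.assign(species_code=sp).merge(
            counts[counts.species_code == sp], on=["species_code", "site_id", "day"], how="left"
        )
        frames.append(block)
    out = pd.concat(frames, ignore_index=True) if frames else eff.iloc[0:0].assign(
        species_code=pd.Series(dtype=str), k_labels=pd.Series(dtype=float)
    )
    out["k_labels"] = out.k_labels.fillna(0).astype(int)

    over = out.k_labels > out.n_segments
    if over.any():
        warnings.warn(f"{int(over.sum())} site-days had more labels than segments; capped",
                      stacklevel=2)
        out.loc[over, "k_labels"] = out.loc[over, "n_segments"]

    out = out[out.n_segments > 0].copy()
    out["rate"] = out.k_labels / out.n_segments
    return out[ACTIVITY_COLUMNS].sort_values(["species_code", "stratum", "site_id", "day"]).reset_index(drop=True)


def modeling_gate(activity: pd.DataFrame, min_sites: int = 5) -> pd.DataFrame:
    """Eligibility of each species x stratum cell for smooth modeling.

    A cell is eligible when at least ``min_sites`` distinct recorder sites
    have one or more retained labels.  Returns one row per cell with the site
    tally and the boolean gate; adding detections can only add eligibility.
    """
    hits = activity[activity.k_labels > 0]
    tally = (
        hits.groupby(["species_code", "stratum"]).site_id.nunique()
        .rename("n_sites_with_labels")
    )
    cells = (
        activity[["species_code", "stratum"]].drop_duplicates()
        .set_index(["species_code", "stratum"])
        .join(tally)
        .fillna({"n_sites_with_labels": 0})
        .reset_index()
    )
    cells["n_sites_with_labels"] = cells.n_sites_with_labels.astype(int)
    cells["eligible"] = cells.n_sites_with_labels >= min_sites
    return cells.sort_values(["species_code", "stratum"]).reset_index(drop=True)
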