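"""Breeding structure: nest overlap networks, neighbourhoods, dispersal.

Two nests are linked in the breeding network of a year when their
incubation intervals (clutch laid to incubation end, closed on both
ends) share at least one calendar day.  Spatial structure is summarised
per focal nest over its temporally overlapping nests: counts, mean and
minimum Euclidean distance, the count within a 100 m neighbourhood
(boundary inclusive) and the fraction of those neighbours that were
successful.  Between-year breeding dispersal records pair an
individual's nests in consecutive years.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_NEIGHBOUR_RADIUS_M = 100.0


def incubation_overlap(
    laid_a, end_a, laid_b, end_b
) -> bool:
    """True when the closed intervals [laid, incubation_end] share a day."""
    laid_a, end_a = pd.Timestamp(laid_a), pd.Timestamp(end_a)
    laid_b, end_b = pd.Timestamp(laid_b), pd.Timestamp(end_b)
    if laid_a > end_a or laid_b > end_b:
        raise ValueError("laid_date after incubation_end")
    return bool(max(laid_a, laid_b) <= min(end_a, end_b))


def nest_distance(nest_a: pd.Series, nest_b: pd.Series) -> float:
    """Planar Euclidean distance between two nest locations, in metres."""
    xa, ya = nest_a["x"], nest_a["y"]
    xb, yb = nest_b["x"], nest_b["y"]
    if any(pd.isna(v) for v in (xa, ya, xb, yb)):
        return float("nan")
    return float(np.hypot(xa - xb, ya - yb))


def overlap_matrix(nests: pd.DataFrame) -> np.ndarray:
    """Boolean matrix of pairwise incubation overlap (diagonal False)."""
    laid = pd.to_datetime(nests["laid_date"]).to_numpy()
    end = pd.to_datetime(nests["incubation_end"]).to_numpy()
    start_max = np.maximum.outer(laid, laid)
    end_min = np.minimum.outer(end, end)
    m = start_max <= end_min
    np.fill_diagonal(m, False)
    return m


def distance_matrix(nests: pd.DataFrame) -> np.ndarray:
    xy = nests[["x", "y"]].to_numpy(dtype=float)
    diff = xy[:, None, :] - xy[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def _same_pair(nests: pd.DataFrame) -> np.ndarray:
    """Mask of nest pairs sharing a male or a female (incl. diagonal)."""
    male = nests["male_id"].to_numpy()
    female = nests["female_id"].to_numpy()
    return (male[:, None] == male[None, :]) | (
        female[:, None] == female[None, :]
    )


def focal_context(
    nests: pd.DataFrame,
    radius_m: float = DEFAULT_NEIGHBOUR_RADIUS_M,
) -> pd.DataFrame:
    """Per-nest context over the same year's temporally overlapping nests.

    For each focal nest: the number of overlapping nests, mean and
    minimum distance to them (NaN when none), the number of overlapping
    nests within ``radius_m`` (inclusive), the proportion of those
    within-radius neighbours that were successful (NaN when none) and
    the Julian (day-of-year) laying date.  Nests of the focal pair
    (sharing either partner) are excluded from a nest's neighbours.
    ``julian_std``, the variance-standardised laying date, is computed
    over the whole table.
    """
    rows = []
    for _, year_nests in nests.groupby("year", sort=True):
        year_nests = year_nests.reset_index(drop=True)
        ov = overlap_matrix(year_nests) & ~_same_pair(year_nests)
        dist = distance_matrix(year_nests)
        succ = year_nests["success"].to_numpy(dtype=bool)
        for i in range(len(year_nests)):
            mask = ov[i]
            d = dist[i, mask]
            within = mask & (dist[i] <= radius_m)
            n_within = int(within.sum())
            rows.append(
                {
                    "nest_id": year_nests.at[i, "nest_id"],
                    "year": year_nests.at[i, "year"],
                    "n_overlapping": int(mask.sum()),
                    "mean_dist_overlapping": float(d.mean()) if d.size else np.nan,
                    "min_dist_overlapping": float(d.min()) if d.size else np.nan,
                    "n_overlapping_within_100m": n_within,
                    "prop_neighbours_successful": (
                        float(succ[within].mean()) if n_within else np.nan
                    ),
                    "julian_laid": int(
                        pd.Timestamp(year_nests.at[i, "laid_date"]).dayofyear
                    ),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        j = out["julian_laid"].astype(float)
        sd = j.std(ddof=1)
        out["julian_std"] = (j - j.mean()) / sd if sd > 0 else 0.0
    return out


def _individual_nests(nests: pd.DataFrame) -> pd.DataFrame:
    """Long table: one row per (individual, nest), earliest nest per year."""
    male = nests.rename(columns={"male_id": "individual_id"}).drop(
        columns=["female_id"]
    )
    female = nests.rename(columns={"female_id": "individual_id"}).drop(
        columns=["male_id"]
    )
    long = pd.concat([male, female], ignore_index=True)
    long = long.sort_values(["individual_id", "year", "laid_date", "nest_id"])
    return long.groupby(["individual_id", "year"], as_index=False).first()


def dispersal_records(
    nests: pd.DataFrame,
    first_only: bool = False,
    radius_m: float = DEFAULT_NEIGHBOUR_RADIUS_M,
) -> pd.DataFrame:
    """Between-year dispersal table for birds nesting in consecutive years.

    One record per (individual, year t -> t+1) transition, using each
    individual's earliest nest per year: previous success and habitat,
    whether the bird stayed in the same habitat, the distance between
    the two nests, and the proportion of the previous nest's overlapping
    within-radius neighbours that were successful.  ``first_only`` keeps
    only each individual's first transition (the subset the
    fixed-effects analyses use).
    """
    ctx = focal_context(nests, radius_m=radius_m).set_index("nest_id")
    long = _individual_nests(nests)
    rows = []
    for ind, grp in long.groupby("individual_id"):
        grp = grp.sort_values("year").reset_index(drop=True)
        for i in range(len(grp) - 1):
            prev, nxt = grp.iloc[i], grp.iloc[i + 1]
            if nxt["year"] != prev["year"] + 1:
                continue
            rows.append(
                {
                    "individual_id": ind,
                    "year_from": int(prev["year"]),
                    "year_to": int(nxt["year"]),
                    "prev_success": bool(prev["success"]),
                    "prev_habitat": prev["habitat"],
                    "next_habitat": nxt["habitat"],
                    "stayed_same_habitat": prev["habitat"] == nxt["habitat"],
                    "distance_m": float(
                        np.hypot(prev["x"] - nxt["x"], prev["y"] - nxt["y"])
                    ),
                    "prev_prop_neighbours_successful": ctx.at[
                        prev["nest_id"], "prop_neighbours_successful"
                    ],
                    "prev_n_neighbours_within_100m": int(
                        ctx.at[prev["nest_id"], "n_overlapping_within_100m"]
                    ),
                }
            )
    out = pd.DataFrame(rows)
    if first_only and len(out):
        out = (
            out.sort_values(["individual_id", "year_from"])
            .groupby("individual_id", as_index=False)
            .first()
        )
    return out.reset_index(drop=True)


def dispersal_summary(records: pd.DataFrame) -> dict:
    """Stay/total counts by previous success and by previous habitat."""
    by_success = {}
    for flag, grp in records.groupby("prev_success"):
        by_success[bool(flag)] = (
            int(grp["stayed_same_habitat"].sum()),
            len(grp),
        )
    by_habitat = {}
    for hab, grp in records.groupby("prev_habitat"):
        by_habitat[hab] = (int(grp["stayed_same_habitat"].sum()), len(grp))
    return {"by_prev_success": by_success, "by_prev_habitat": by_habitat}
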