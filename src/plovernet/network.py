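"""Gambit-of-the-group social networks from sighting streams.

Individuals sighted in the same 10-min sampling period are assigned to
groups by a chain rule: two birds join the same group when connected by
a chain of pairwise distances each at most ``chain_distance`` metres
(boundary inclusive by default; the threshold is configurable).  Every
within-group dyad is scored as associating in that period, and dyadic
edge weights are the simple ratio index

    SRI = x / (x + y_AB + y_A + y_B)

where x counts periods with the dyad in one group, y_AB periods with
both seen but in different groups, and y_A, y_B periods with only one of
the two seen.  Networks are year-specific and undirected.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

DEFAULT_CHAIN_DISTANCE_M = 20.0


@dataclass(frozen=True)
class GroupAssignment:
    """Partition of one sampling period's individuals into chain-rule groups."""

    period_id: str
    groups: tuple[frozenset[str], ...]

    @property
    def individuals(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return frozenset(out)


def deduplicate_sightings(raw: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeat detections of a bird within one sampling period.

    Duplicate (individual, period) rows are averaged to their mean
    coordinate; all other fields are taken from the first row.  A bird
    recorded under two different sexes anywhere in the table is an
    error.
    """
    sex_counts = raw.groupby("individual_id")["sex"].nunique()
    bad = sex_counts[sex_counts > 1]
    if len(bad):
        raise ValueError(
            f"conflicting sex records for individual(s): {', '.join(bad.index)}"
        )
    agg = {c: "first" for c in raw.columns if c not in ("individual_id", "period_id")}
    agg["x"] = "mean"
    agg["y"] = "mean"
    out = (
        raw.groupby(["individual_id", "period_id"], as_index=False, sort=False)
        .agg(agg)
    )
    return out[list(raw.columns)]


def filter_prebreeding(
    sightings: pd.DataFrame,
    season_start: Mapping[int, date],
    exclusion_days: int = 14,
    drop_may: bool = False,
) -> pd.DataFrame:
    """Drop sightings too close to (or inside) the breeding season.

    Keeps rows strictly earlier than ``season_start[year] -
    exclusion_days``.  ``exclusion_days=30`` and ``drop_may=True`` are
    the sensitivity variants (the latter additionally removes all May
    rows, the month when out-of-season breeding is most likely).
    """
    missing = set(sightings["year"].unique()) - set(season_start)
    if missing:
        raise ValueError(f"season_start missing for year(s): {sorted(missing)}")
    cutoff = sightings["year"].map(
        {y: pd.Timestamp(d) - pd.Timedelta(days=exclusion_days) for y, d in season_start.items()}
    )
    dates = pd.to_datetime(sightings["date"])
    keep = dates < cutoff
    if drop_may:
        keep &= dates.dt.month != 5
    return sightings.loc[keep].reset_index(drop=True)


def assign_groups(
    period_sightings: pd.DataFrame,
    chain_distance: float = DEFAULT_CHAIN_DISTANCE_M,
    inclusive: bool = True,
) -> GroupAssignment:
    """Chain-rule grouping of one period's sightings.

    Groups are the connected components of the graph joining birds at
    Euclidean distance <= ``chain_distance`` (or < when
    ``inclusive=False``).
    """
    periods = period_sightings["period_id"].unique()
    if len(periods) != 1:
        raise ValueError("assign_groups expects sightings of a single period")
    ids = period_sightings["individual_id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate individuals in period; deduplicate first")
    xy = period_sightings[["x", "y"]].to_numpy(dtype=float)

    parent = list(range(len(ids)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if len(ids) > 1:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(chain_distance):
            if not inclusive and np.hypot(*(xy[i] - xy[j])) >= chain_distance:
                continue
            parent[find(i)] = find(j)
    members: dict[int, set[str]] = {}
    for i in range(len(ids)):
        members.setdefault(find(i), set()).add(ids[i])
    groups = tuple(
        sorted((frozenset(g) for g in members.values()), key=lambda g: sorted(g)[0])
    )
    return GroupAssignment(period_id=str(periods[0]), groups=groups)


def assign_groups_all(
    sightings: pd.DataFrame,
    chain_distance: float = DEFAULT_CHAIN_DISTANCE_M,
    inclusive: bool = True,
) -> list[GroupAssignment]:
    """Chain-rule grouping for every sampling period of a table."""
    return [
        assign_groups(g, chain_distance, inclusive)
        for _, g in sightings.groupby("period_id", sort=True)
    ]


def _dyad_counts(
    assignments: Iterable[GroupAssignment],
) -> tuple[dict[str, int], dict[tuple[str, str], int], dict[tuple[str, str], int]]:
    """Per-individual and per-dyad period tallies.

    Returns (n_periods_seen per id, periods-together per dyad,
    periods-both-observed per dyad), dyads keyed as sorted tuples.
    """
    seen: dict[str, int] = {}
    together: dict[tuple[str, str], int] = {}
    both: dict[tuple[str, str], int] = {}
    for ga in assignments:
        inds = sorted(ga.individuals)
        for i in inds:
            seen[i] = seen.get(i, 0) + 1
        for a, b in combinations(inds, 2):
            both[(a, b)] = both.get((a, b), 0) + 1
        for g in ga.groups:
            for a, b in combinations(sorted(g), 2):
                together[(a, b)] = together.get((a, b), 0) + 1
    return seen, together, both


def compute_sri(
    assignments: Iterable[GroupAssignment],
    dyad: tuple[str, str],
) -> float:
    """Simple ratio index of one dyad over a set of sampling periods.

    Returns 0 when the dyad was never observed (zero denominator).
    """
    a, b = sorted(dyad)
    seen, together, both = _dyad_counts(assignments)
    x = together.get((a, b), 0)
    n_both = both.get((a, b), 0)
    denom = seen.get(a, 0) + seen.get(b, 0) - n_both
    return x / denom if denom else 0.0


def build_network(
    sightings: pd.DataFrame,
    year: int,
    chain_distance: float = DEFAULT_CHAIN_DISTANCE_M,
    inclusive: bool = True,
) -> nx.Graph:
    """Per-year social network with SRI edge weights.

    Nodes are all individuals sighted at least once that year (node
    attribute ``sex``); edges carry attribute ``sri`` and exist only for
    dyads grouped together at least once (SRI > 0).  Graph attributes
    record the year, the number of sampling periods and the network
    density over SRI > 0 edges.
    """
    sub = sightings[sightings["year"] == year]
    assignments = assign_groups_all(sub, chain_distance, inclusive)
    seen, together, both = _dyad_counts(assignments)

    g = nx.Graph(year=year, sampling_periods=len(assignments))
    sex_map = dict(zip(sub["individual_id"], sub["sex"]))
    for ind in sorted(seen):
        g.add_node(ind, sex=sex_map[ind])
    for (a, b), x in together.items():
        denom = seen[a] + seen[b] - both[(a, b)]
        if x > 0:
            g.add_edge(a, b, sri=x / denom)
    n = g.number_of_nodes()
    g.graph["density"] = (
        2.0 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    )
    return g


def sri_lookup(network: nx.Graph, a: str, b: str) -> float:
    """Edge SRI, 0 for non-adjacent dyads."""
    data = network.get_edge_data(a, b)
    return data["sri"] if data else 0.0


def node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Degree, strength and proportion of male associates per node.

    Degree counts associates with SRI > 0; strength sums incident SRI
    weights; ``prop_male_associates`` is NaN for isolated nodes.
    """
    rows = []
    for node, attrs in network.nodes(data=True):
        nbrs = list(network.neighbors(node))
        degree = len(nbrs)
        strength = sum(network[node][m]["sri"] for m in nbrs)
        if degree:
            prop_male = sum(
                1 for m in nbrs if network.nodes[m]["sex"] == "M"
            ) / degree
        else:
            prop_male = np.nan
        rows.append(
            {
                "individual_id": node,
                "sex": attrs.get("sex"),
                "degree": degree,
                "strength": strength,
                "prop_male_associates": prop_male,
            }
        )
    return pd.DataFrame(rows).sort_values("individual_id").reset_index(drop=True)


def network_summary(networks: Mapping[int, nx.Graph]) -> pd.DataFrame:
    """Per-year node count, edge count, density and mean degree."""
    rows = []
    for year, g in sorted(networks.items()):
        degrees = [d for _, d in g.degree()]
        rows.append(
            {
                "year": year,
                "n_nodes": g.number_of_nodes(),
                "n_edges": g.number_of_edges(),
                "density": g.graph["density"],
                "mean_degree": float(np.mean(degrees)) if degrees else 0.0,
            }
        )
    return pd.DataFrame(rows)
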