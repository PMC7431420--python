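"""The analysis suite: dataset builders, model registry, permutation runs.

Each registered analysis couples a model specification to the dataset
builder that assembles its rows from the data bundle and to the
randomisation scheme that generates its null distribution:

* ``A1*``   sex differences in sociality (data-stream null)
* ``A2*``   pair formation ~ pre-breeding SRI (mate null, with a
            habitat-stratified variant)
* ``A3*``   nest success ~ pair SRI (plus a fixed-effects habitat
            variant on first records)
* ``A4*/A5*`` breeding synchrony / nest proximity ~ sociality
            (nest null within habitat)
* ``A6*``   dyadic nest overlap and distance ~ dyad SRI (nest null)
* ``A7/A8`` nest success ~ breeding structure (with VIF check)
* ``A9–A11`` breeding dispersal ~ previous success and neighbour success
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from itertools import combinations
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import breeding, network, permutation
from .models import LRTResult, ModelFit, ModelSpec, compute_vif, fit_model, lrt_for_term
from .permutation import PermutationResult

DISTANCE_OFFSET_M = 1.0  # added to dispersal/nest distances under a log link


@dataclass
class DataBundle:
    """Filtered sightings, nests, and the derived per-year networks."""

    sightings: pd.DataFrame
    nests: pd.DataFrame
    assignments: dict[int, list[network.GroupAssignment]]
    networks: dict[int, nx.Graph]
    chain_distance: float = network.DEFAULT_CHAIN_DISTANCE_M

    @property
    def network_years(self) -> list[int]:
        return sorted(self.networks)

    def with_nests(self, nests: pd.DataFrame) -> "DataBundle":
        return replace(self, nests=nests)

    def with_assignments(
        self, assignments: dict[int, list[network.GroupAssignment]]
    ) -> "DataBundle":
        sex_map = dict(zip(self.sightings.individual_id, self.sightings.sex))
        networks = {
            year: network_from_assignments(asg, sex_map, year)
            for year, asg in assignments.items()
        }
        return replace(self, assignments=assignments, networks=networks)


def network_from_assignments(
    assignments: Sequence[network.GroupAssignment],
    sex_map: Mapping[str, str],
    year: int,
) -> nx.Graph:
    """SRI network from pre-computed group assignments (see network module)."""
    seen, together, both = network._dyad_counts(assignments)
    g = nx.Graph(year=year, sampling_periods=len(assignments))
    for ind in sorted(seen):
        g.add_node(ind, sex=sex_map[ind])
    for (a, b), x in together.items():
        if x > 0:
            g.add_edge(a, b, sri=x / (seen[a] + seen[b] - both[(a, b)]))
    n = g.number_of_nodes()
    g.graph["density"] = 2.0 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
    return g


def default_season_start(years: Sequence[int]) -> dict[int, date]:
    """August 1st of each year: onset of the core breeding season."""
    return {int(y): date(int(y), 8, 1) for y in years}


def build_bundle(
    sightings: pd.DataFrame,
    nests: pd.DataFrame,
    season_start: Mapping[int, date] | None = None,
    exclusion_days: int = 14,
    drop_may: bool = False,
    chain_distance: float = network.DEFAULT_CHAIN_DISTANCE_M,
    inclusive: bool = True,
) -> DataBundle:
    """Deduplicate and filter sightings, then build per-year networks."""
    sightings = network.deduplicate_sightings(sightings)
    if season_start is None:
        season_start = default_season_start(sightings["year"].unique())
    sightings = network.filter_prebreeding(
        sightings, season_start, exclusion_days=exclusion_days, drop_may=drop_may
    )
    assignments = {}
    networks = {}
    for year, sub in sightings.groupby("year", sort=True):
        asg = network.assign_groups_all(sub, chain_distance, inclusive)
        assignments[int(year)] = asg
        sex_map = dict(zip(sub.individual_id, sub.sex))
        networks[int(year)] = network_from_assignments(asg, sex_map, int(year))
    return DataBundle(
        sightings=sightings,
        nests=nests.reset_index(drop=True),
        assignments=assignments,
        networks=networks,
        chain_distance=chain_distance,
    )


# ---------------------------------------------------------------------------
# dataset builders


def sociality_table(bundle: DataBundle) -> pd.DataFrame:
    """Per individual-year node metrics with sex, for the A1 models."""
    frames = []
    for year in bundle.network_years:
        m = network.node_metrics(bundle.networks[year])
        m["year"] = year
        frames.append(m)
    out = pd.concat(frames, ignore_index=True)
    out["is_male"] = (out["sex"] == "M").astype(int)
    return out


def _pair_set(nests: pd.DataFrame) -> set[tuple[str, str, int]]:
    return set(
        zip(nests["male_id"], nests["female_id"], nests["year"].astype(int))
    )


def pairing_table(bundle: DataBundle) -> pd.DataFrame:
    """All male x female combinations with social and breeding data.

    For each year with both a pre-breeding network and nests, rows are
    every combination of a breeding male and a breeding female that
    also appear in that year's network, with their SRI and whether they
    actually bred together (``is_pair``).
    """
    pairs = _pair_set(bundle.nests)
    rows = []
    for year in bundle.network_years:
        g = bundle.networks[year]
        nests_y = bundle.nests[bundle.nests["year"] == year]
        males = sorted(set(nests_y["male_id"]) & set(g.nodes))
        females = sorted(set(nests_y["female_id"]) & set(g.nodes))
        for m in males:
            for f in females:
                rows.append(
                    {
                        "year": year,
                        "male_id": m,
                        "female_id": f,
                        "sri": network.sri_lookup(g, m, f),
                        "is_pair": int((m, f, year) in pairs),
                    }
                )
    return pd.DataFrame(rows)


def success_sri_table(bundle: DataBundle, first_only: bool = False) -> pd.DataFrame:
    """Nests whose pair members both appear in that year's network."""
    rows = []
    for year in bundle.network_years:
        g = bundle.networks[year]
        nests_y = bundle.nests[bundle.nests["year"] == year]
        for rec in nests_y.itertuples():
            if rec.male_id in g.nodes and rec.female_id in g.nodes:
                rows.append(
                    {
                        "year": year,
                        "nest_id": rec.nest_id,
                        "male_id": rec.male_id,
                        "female_id": rec.female_id,
                        "habitat": rec.habitat,
                        "sri": network.sri_lookup(g, rec.male_id, rec.female_id),
                        "success": int(rec.success),
                    }
                )
    out = pd.DataFrame(rows)
    if first_only and len(out):
        out = (
            out.sort_values(["male_id", "female_id", "year"])
            .groupby(["male_id", "female_id"], as_index=False)
            .first()
        )
    return out


def structure_sociality_table(bundle: DataBundle) -> pd.DataFrame:
    """Focal-bird rows linking node metrics to their nest's context (A4/A5)."""
    ctx = breeding.focal_context(bundle.nests).set_index("nest_id")
    frames = []
    for year in bundle.network_years:
        metrics = network.node_metrics(bundle.networks[year]).set_index(
            "individual_id"
        )
        nests_y = bundle.nests[bundle.nests["year"] == year]
        for rec in nests_y.itertuples():
            for role, ind in (("M", rec.male_id), ("F", rec.female_id)):
                if ind not in metrics.index:
                    continue
                c = ctx.loc[rec.nest_id]
                frames.append(
                    {
                        "individual_id": ind,
                        "sex": role,
                        "year": year,
                        "nest_id": rec.nest_id,
                        "habitat": rec.habitat,
                        "degree": metrics.at[ind, "degree"],
                        "strength": metrics.at[ind, "strength"],
                        "n_overlapping": c["n_overlapping"],
                        "mean_dist_overlapping": c["mean_dist_overlapping"],
                    }
                )
    out = pd.DataFrame(frames)
    if len(out):
        out["mean_dist_pos"] = out["mean_dist_overlapping"] + DISTANCE_OFFSET_M
    return out


def dyad_structure_table(bundle: DataBundle) -> pd.DataFrame:
    """Dyads of breeding birds with SRI, nest overlap and nest distance (A6).

    All pairs of individuals that appear in the year's network and have
    a nest that year, excluding actual breeding pairs.  Uses each
    individual's earliest nest of the year.
    """
    pairs = _pair_set(bundle.nests)
    pair_keys = {(m, f, y) for m, f, y in pairs} | {
        (f, m, y) for m, f, y in pairs
    }
    long = breeding._individual_nests(bundle.nests)
    rows = []
    for year in bundle.network_years:
        g = bundle.networks[year]
        l_y = long[long["year"] == year].set_index("individual_id")
        inds = sorted(set(l_y.index) & set(g.nodes))
        for a, b in combinations(inds, 2):
            if (a, b, year) in pair_keys:
                continue
            na, nb = l_y.loc[a], l_y.loc[b]
            if na["nest_id"] == nb["nest_id"]:
                continue
            rows.append(
                {
                    "year": year,
                    "id_a": a,
                    "id_b": b,
                    "nest_a": na["nest_id"],
                    "nest_b": nb["nest_id"],
                    "habitat": na["habitat"],
                    "sri": network.sri_lookup(g, a, b),
                    "overlap": int(
                        breeding.incubation_overlap(
                            na["laid_date"],
                            na["incubation_end"],
                            nb["laid_date"],
                            nb["incubation_end"],
                        )
                    ),
                    "distance_m": float(
                        np.hypot(na["x"] - nb["x"], na["y"] - nb["y"])
                    ),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["distance_pos"] = out["distance_m"] + DISTANCE_OFFSET_M
    return out


def nest_success_structure_table(bundle: DataBundle) -> pd.DataFrame:
    """Nest-level success vs breeding-structure covariates (A7/A8)."""
    ctx = breeding.focal_context(bundle.nests)
    out = ctx.merge(
        bundle.nests[["nest_id", "habitat", "success", "year"]].assign(
            success=lambda d: d["success"].astype(int)
        ),
        on=["nest_id", "year"],
    )
    return out


def dispersal_table(bundle: DataBundle, first_only: bool = False) -> pd.DataFrame:
    recs = breeding.dispersal_records(bundle.nests, first_only=first_only)
    if len(recs):
        recs = recs.assign(
            stayed=recs["stayed_same_habitat"].astype(int),
            prev_success_int=recs["prev_success"].astype(int),
            distance_pos=recs["distance_m"] + DISTANCE_OFFSET_M,
        )
    return recs


# ---------------------------------------------------------------------------
# registry


@dataclass(frozen=True)
class AnalysisSpec:
    key: str
    description: str
    model: ModelSpec
    builder: Callable[[DataBundle], pd.DataFrame]
    null_scheme: str  # datastream | mate | nest | none
    stratum: tuple[str, ...] = ()
    vif_terms: tuple[str, ...] = ()


def analysis_registry() -> dict[str, AnalysisSpec]:
    """The full registered analysis suite, keyed A1…A11."""
    reg: dict[str, AnalysisSpec] = {}

    def add(spec: AnalysisSpec) -> None:
        reg[spec.key] = spec

    for resp, fam, link in (
        ("degree", "poisson", "log"),
        ("strength", "gaussian", "identity"),
        ("prop_male_associates", "binomial", "logit"),
    ):
        add(
            AnalysisSpec(
                key=f"A1_{resp.split('_')[0]}",
                description=f"sex difference in {resp} (data-stream null)",
                model=ModelSpec(
                    name=f"sex_{resp}",
                    response=resp,
                    family=fam,
                    link=link,
                    fixed_terms=("is_male", "C(year)"),
                    random_terms=("individual_id",),
                    focal_term="is_male",
                    data_filter="individuals in pre-breeding networks",
                ),
                builder=sociality_table,
                null_scheme="datastream",
            )
        )

    pairing_model = ModelSpec(
        name="pairing_sri",
        response="is_pair",
        family="binomial",
        link="logit",
        fixed_terms=("sri", "C(year)"),
        random_terms=("male_id", "female_id"),
        focal_term="sri",
        data_filter="all male x female combinations with social + breeding data",
    )
    add(
        AnalysisSpec(
            key="A2_pairing",
            description="pair formation ~ pre-breeding SRI (mate null)",
            model=pairing_model,
            builder=pairing_table,
            null_scheme="mate",
            stratum=("year",),
        )
    )
    add(
        AnalysisSpec(
            key="A2_pairing_habitat",
            description="pair formation ~ SRI, habitat-constrained mate null",
            model=pairing_model,
            builder=pairing_table,
            null_scheme="mate",
            stratum=("year", "habitat"),
        )
    )

    add(
        AnalysisSpec(
            key="A3_success_sri",
            description="nest success ~ pair SRI",
            model=ModelSpec(
                name="success_sri",
                response="success",
                family="binomial",
                link="logit",
                fixed_terms=("sri", "C(year)"),
                random_terms=("male_id", "female_id"),
                focal_term="sri",
                data_filter="nests with both pair members in the network",
            ),
            builder=success_sri_table,
            null_scheme="none",
        )
    )
    add(
        AnalysisSpec(
            key="A3_success_sri_habitat",
            description="nest success ~ SRI + habitat (GLM, first records)",
            model=ModelSpec(
                name="success_sri_habitat",
                response="success",
                family="binomial",
                link="logit",
                fixed_terms=("sri", "C(year)", "C(habitat)"),
                focal_term="sri",
                data_filter="first nest per pair, habitat known",
            ),
            builder=lambda b: success_sri_table(b, first_only=True),
            null_scheme="none",
        )
    )

    for metric in ("degree", "strength"):
        add(
            AnalysisSpec(
                key=f"A4_overlap_{metric}",
                description=f"n overlapping nests ~ {metric} (nest null)",
                model=ModelSpec(
                    name=f"n_overlapping_{metric}",
                    response="n_overlapping",
                    family="poisson",
                    link="log",
                    fixed_terms=(metric, "C(year)"),
                    random_terms=("individual_id", "nest_id"),
                    focal_term=metric,
                    data_filter="focal birds with network metrics and a nest",
                ),
                builder=structure_sociality_table,
                null_scheme="nest",
                stratum=("year", "habitat"),
            )
        )
        add(
            AnalysisSpec(
                key=f"A5_distance_{metric}",
                description=f"mean distance to overlapping nests ~ {metric}",
                model=ModelSpec(
                    name=f"mean_dist_{metric}",
                    response="mean_dist_pos",
                    family="gaussian",
                    link="log",
                    fixed_terms=(metric, "C(year)"),
                    random_terms=("individual_id", "nest_id"),
                    focal_term=metric,
                    data_filter="focal birds with >=1 overlapping nest",
                ),
                builder=lambda b: structure_sociality_table(b).dropna(
                    subset=["mean_dist_overlapping"]
                ),
                null_scheme="nest",
                stratum=("year", "habitat"),
            )
        )

    add(
        AnalysisSpec(
            key="A6_dyad_overlap",
            description="dyad nest concurrency ~ dyad SRI (nest null)",
            model=ModelSpec(
                name="dyad_overlap_sri",
                response="overlap",
                family="binomial",
                link="logit",
                fixed_terms=("sri", "C(habitat)", "C(year)"),
                random_terms=("id_a", "id_b", "nest_a", "nest_b"),
                focal_term="sri",
                data_filter="non-pair dyads, both with nests",
            ),
            builder=dyad_structure_table,
            null_scheme="nest",
            stratum=("year", "habitat"),
        )
    )
    add(
        AnalysisSpec(
            key="A6_dyad_distance",
            description="dyad nest distance ~ dyad SRI (nest null)",
            model=ModelSpec(
                name="dyad_distance_sri",
                response="distance_pos",
                family="gaussian",
                link="log",
                fixed_terms=("sri", "C(habitat)", "C(year)"),
                random_terms=("id_a", "id_b", "nest_a", "nest_b"),
                focal_term="sri",
                data_filter="non-pair dyads, both with nests",
            ),
            builder=dyad_structure_table,
            null_scheme="nest",
            stratum=("year", "habitat"),
        )
    )

    structure_terms = (
        "n_overlapping",
        "mean_dist_overlapping",
        "min_dist_overlapping",
        "C(habitat)",
        "julian_std",
        "I(julian_std**2)",
    )
    add(
        AnalysisSpec(
            key="A7_success_structure",
            description="nest success ~ breeding structure (VIF-checked)",
            model=ModelSpec(
                name="success_structure",
                response="success",
                family="binomial",
                link="logit",
                fixed_terms=structure_terms,
                random_terms=("year",),
                focal_term="n_overlapping",
                data_filter="nests with >=1 overlapping nest",
            ),
            builder=lambda b: nest_success_structure_table(b).dropna(
                subset=["mean_dist_overlapping"]
            ),
            null_scheme="none",
            vif_terms=(
                "n_overlapping",
                "mean_dist_overlapping",
                "min_dist_overlapping",
                "julian_std",
                "I(julian_std**2)",
            ),
        )
    )
    add(
        AnalysisSpec(
            key="A8_success_density100",
            description="nest success ~ overlapping nests within 100 m",
            model=ModelSpec(
                name="success_density100",
                response="success",
                family="binomial",
                link="logit",
                fixed_terms=(
                    "n_overlapping_within_100m",
                    "C(habitat)",
                    "julian_std",
                    "I(julian_std**2)",
                ),
                random_terms=("year",),
                focal_term="n_overlapping_within_100m",
                data_filter="all nests",
            ),
            builder=nest_success_structure_table,
            null_scheme="none",
        )
    )

    add(
        AnalysisSpec(
            key="A9_stay_prev_success",
            description="stayed in habitat ~ previous nest success",
            model=ModelSpec(
                name="stay_prev_success",
                response="stayed",
                family="binomial",
                link="logit",
                fixed_terms=("prev_success_int", "C(prev_habitat)"),
                random_terms=("individual_id", "year_from"),
                focal_term="prev_success_int",
                data_filter="consecutive-year breeders",
            ),
            builder=dispersal_table,
            null_scheme="none",
        )
    )
    add(
        AnalysisSpec(
            key="A10_distance_prev_success",
            description="dispersal distance ~ previous nest success",
            model=ModelSpec(
                name="distance_prev_success",
                response="distance_pos",
                family="gaussian",
                link="log",
                fixed_terms=("prev_success_int", "C(prev_habitat)"),
                random_terms=("individual_id", "year_from"),
                focal_term="prev_success_int",
                data_filter="consecutive-year breeders",
            ),
            builder=dispersal_table,
            null_scheme="none",
        )
    )
    add(
        AnalysisSpec(
            key="A11_distance_neighbour_success",
            description="dispersal distance ~ neighbours' success (GLM)",
            model=ModelSpec(
                name="distance_neighbour_success",
                response="distance_pos",
                family="gaussian",
                link="log",
                fixed_terms=(
                    "prev_success_int",
                    "prev_prop_neighbours_successful",
                    "C(prev_habitat)",
                ),
                focal_term="prev_prop_neighbours_successful",
                data_filter="first records with >=1 previous 100 m neighbour",
            ),
            builder=lambda b: dispersal_table(b, first_only=True).dropna(
                subset=["prev_prop_neighbours_successful"]
            ),
            null_scheme="none",
        )
    )
    return reg


# ---------------------------------------------------------------------------
# running analyses


@dataclass
class AnalysisResult:
    spec: AnalysisSpec
    fit: ModelFit
    focal_lrt: LRTResult | None
    perm: PermutationResult | None
    vif: pd.Series | None
    n_obs: int

    def summary_row(self) -> dict:
        row = {
            "analysis": self.spec.key,
            "focal_term": self.spec.model.focal_term,
            "estimate": self.fit.focal_estimate,
            "n_obs": self.n_obs,
            "converged": self.fit.converged,
        }
        if self.focal_lrt is not None:
            row.update(
                lrt_chi_sq=self.focal_lrt.chi_sq,
                lrt_df=self.focal_lrt.df,
                lrt_p=self.focal_lrt.p,
            )
        if self.perm is not None:
            row.update(p_rand=self.perm.p_two_tailed, n_perm=self.perm.n_perm)
        return row


def _randomised_bundle(
    bundle: DataBundle, spec: AnalysisSpec, rng: np.random.Generator
) -> DataBundle:
    if spec.null_scheme == "datastream":
        new_assignments = {
            year: permutation.datastream_randomise(asg, rng)
            for year, asg in bundle.assignments.items()
        }
        return bundle.with_assignments(new_assignments)
    if spec.null_scheme == "mate":
        return bundle.with_nests(
            permutation.mate_randomise(bundle.nests, rng, stratum=spec.stratum)
        )
    if spec.null_scheme == "nest":
        return bundle.with_nests(
            permutation.nest_randomise(bundle.nests, rng, stratum=spec.stratum)
        )
    raise ValueError(f"no randomiser for null scheme {spec.null_scheme!r}")


def run_analysis(
    bundle: DataBundle,
    spec: AnalysisSpec | str,
    n_perm: int = 10_000,
    seed: int = 0,
    p_method: str = "doubled",
    with_lrt: bool = True,
) -> AnalysisResult:
    """Fit one registered analysis and (where defined) its permutation test."""
    if isinstance(spec, str):
        spec = analysis_registry()[spec]
    data = spec.builder(bundle)
    fit = fit_model(spec.model, data)
    focal_lrt = None
    if with_lrt and spec.model.focal_term is not None and not fit.degenerate:
        focal_lrt = lrt_for_term(spec.model, data, spec.model.focal_term)
    vif = (
        compute_vif(data, spec.vif_terms) if len(spec.vif_terms) >= 2 else None
    )

    perm = None
    if spec.null_scheme != "none" and n_perm > 0:
        if spec.key.startswith("A2"):
            perm = pairing_permutation_test(
                bundle, n_perm=n_perm, seed=seed,
                stratum=spec.stratum, p_method=p_method,
            )
        else:
            def statistic(b: DataBundle) -> float:
                return fit_model(spec.model, spec.builder(b)).focal_estimate

            perm = permutation.run_permutation_test(
                statistic,
                lambda b, rng: _randomised_bundle(b, spec, rng),
                bundle,
                n_perm=n_perm,
                seed=seed,
                statistic_name=spec.model.focal_term or spec.key,
                method=p_method,
            )
    return AnalysisResult(
        spec=spec, fit=fit, focal_lrt=focal_lrt, perm=perm, vif=vif,
        n_obs=fit.n_obs,
    )


def pairing_permutation_test(
    bundle: DataBundle,
    n_perm: int = 10_000,
    seed: int = 0,
    stratum: Sequence[str] = ("year",),
    p_method: str = "doubled",
) -> PermutationResult:
    """Mate-randomisation test of the SRI coefficient on pair formation.

    Fast path for the A2 analyses: the male x female design (SRI and
    year effects) is fixed under mate randomisation — only the
    ``is_pair`` response changes — so the grid and design matrix are
    precomputed once and each replicate refits a plain logistic GLM.
    """
    grid = pairing_table(bundle)
    if grid.empty:
        raise ValueError("no overlap between networks and nests")
    years = sorted(grid["year"].unique())
    X = [np.ones(len(grid)), grid["sri"].to_numpy(dtype=float)]
    for y in years[1:]:
        X.append((grid["year"] == y).to_numpy(dtype=float))
    X = np.column_stack(X)

    nests = bundle.nests.copy()

    def response(nests_df: pd.DataFrame) -> np.ndarray:
        pairs = _pair_set(nests_df)
        return np.fromiter(
            (
                (m, f, y) in pairs
                for m, f, y in zip(
                    grid["male_id"], grid["female_id"], grid["year"]
                )
            ),
            dtype=float,
            count=len(grid),
        )

    def slope(nests_df: pd.DataFrame) -> float:
        y = response(nests_df)
        if y.sum() == 0 or y.sum() == len(y):
            return np.nan
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        return float(res.params[1])

    return permutation.run_permutation_test(
        statistic_fn=slope,
        randomiser=lambda d, rng: permutation.mate_randomise(
            d, rng, stratum=stratum
        ),
        data=nests,
        n_perm=n_perm,
        seed=seed,
        statistic_name="sri_pairing_slope",
        method=p_method,
    )
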