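"""End-to-end orchestration: simulate/load -> networks -> analyses -> report.

A run is described by a :class:`RunConfig` (either input file paths or a
simulation configuration), executes its stages in dependency order, and
writes every output table together with a JSON manifest sufficient to
reproduce the run exactly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import analyses, breeding, io, network, synthetic
from .config import PopulationConfig, SurveyDesign

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``sightings_path`` + ``nests_path``) or ``simulate``
    must be provided.  ``exclusion_days`` supports the 14- and 30-day
    pre-season windows; ``drop_may`` additionally removes May sightings
    (the sensitivity variants).
    """

    sightings_path: str | None = None
    nests_path: str | None = None
    habitats_path: str | None = None
    simulate: PopulationConfig | None = None
    survey_design: SurveyDesign = field(default_factory=SurveyDesign)
    analyses: Sequence[str] = ()
    n_perm: int = 10_000
    seed: int = 0
    exclusion_days: int = 14
    drop_may: bool = False
    chain_distance: float = network.DEFAULT_CHAIN_DISTANCE_M
    neighbourhood_radius: float = breeding.DEFAULT_NEIGHBOUR_RADIUS_M
    output_dir: str = "plovernet_out"

    def __post_init__(self) -> None:
        has_paths = self.sightings_path is not None and self.nests_path is not None
        if has_paths == (self.simulate is not None):
            raise ValueError(
                "provide either input paths or a simulation config, not both/neither"
            )


def validate_inputs(
    sightings: pd.DataFrame,
    nests: pd.DataFrame,
    habitats: dict | None = None,
) -> list[dict]:
    """Schema and consistency checks; returns a list of violations.

    Checks: required columns, finite coordinates, date order of
    incubation intervals, sex consistency per individual, and (when
    habitat polygons are given) that sightings fall inside the polygon
    of their habitat label (a warning, since birds range beyond habitat
    cores).
    """
    report: list[dict] = []
    for col in io.SIGHTING_REQUIRED:
        if col not in sightings.columns:
            report.append({"table": "sightings", "error": f"missing column {col}"})
    for col in io.NEST_REQUIRED:
        if col not in nests.columns:
            report.append({"table": "nests", "error": f"missing column {col}"})
    if report:
        return report

    bad_xy = ~np.isfinite(sightings[["x", "y"]].to_numpy(dtype=float)).all(axis=1)
    for i in sightings.index[bad_xy]:
        report.append(
            {"table": "sightings", "row": int(i), "error": "non-finite coordinates"}
        )
    sex_counts = sightings.groupby("individual_id")["sex"].nunique()
    for ind in sex_counts[sex_counts > 1].index:
        report.append(
            {
                "table": "sightings",
                "individual_id": ind,
                "error": "conflicting sex records",
            }
        )
    laid = pd.to_datetime(nests["laid_date"])
    end = pd.to_datetime(nests["incubation_end"])
    for i in nests.index[laid > end]:
        report.append(
            {
                "table": "nests",
                "nest_id": nests.at[i, "nest_id"],
                "error": "laid_date after incubation_end",
            }
        )
    if habitats:
        from shapely.geometry import Point

        for i, row in sightings.iterrows():
            poly = habitats.get(row["habitat"])
            if poly is None:
                report.append(
                    {
                        "table": "sightings",
                        "row": int(i),
                        "error": f"unknown habitat label {row['habitat']!r}",
                    }
                )
            elif not poly.buffer(1e-9).contains(Point(row["x"], row["y"])):
                report.append(
                    {
                        "table": "sightings",
                        "row": int(i),
                        "warning": "sighting outside its labelled habitat polygon",
                    }
                )
    return report


def run(config: RunConfig) -> dict:
    """Execute a full pipeline run; returns the manifest dictionary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
        "warnings": [],
    }

    if config.simulate is not None:
        sim = synthetic.simulate_dataset(config.simulate, config.survey_design)
        sightings, nests = sim.sightings, sim.nests
        io.write_sightings(sightings, outdir / "sightings.csv")
        io.write_nests(nests, outdir / "nests.csv")
        io.write_habitats_geojson(
            config.simulate.habitats, outdir / "habitats.geojson"
        )
        io.write_ground_truth(sim.ground_truth, outdir / "ground_truth.json")
        habitats = io.habitat_polygons(config.simulate.habitats)
    else:
        sightings = io.read_sightings(config.sightings_path)
        nests = io.read_nests(config.nests_path)
        habitats = (
            io.read_habitats_geojson(config.habitats_path)
            if config.habitats_path
            else None
        )
    manifest["stages"]["input"] = {
        "n_sightings": len(sightings),
        "n_nests": len(nests),
    }

    report = validate_inputs(sightings, nests, habitats)
    errors = [r for r in report if "error" in r]
    manifest["warnings"] = [r for r in report if "warning" in r]
    if errors:
        manifest["stages"]["validation"] = {"errors": errors}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise ValueError(f"input validation failed with {len(errors)} error(s)")

    bundle = analyses.build_bundle(
        sightings,
        nests,
        exclusion_days=config.exclusion_days,
        drop_may=config.drop_may,
        chain_distance=config.chain_distance,
    )
    manifest["stages"]["networks"] = {
        "n_prebreeding_sightings": len(bundle.sightings),
        "years": bundle.network_years,
    }
    summary = network.network_summary(bundle.networks)
    summary.to_csv(outdir / "network_summary.csv", index=False)
    metrics_frames = []
    for year, g in bundle.networks.items():
        io.write_edge_list(g, outdir / f"edges_{year}.csv")
        m = network.node_metrics(g)
        m["year"] = year
        metrics_frames.append(m)
    pd.concat(metrics_frames, ignore_index=True).to_csv(
        outdir / "node_metrics.csv", index=False
    )
    breeding.focal_context(nests, radius_m=config.neighbourhood_radius).to_csv(
        outdir / "nest_context.csv", index=False
    )
    breeding.dispersal_records(
        nests, radius_m=config.neighbourhood_radius
    ).to_csv(outdir / "dispersal.csv", index=False)

    if config.analyses:
        registry = analyses.analysis_registry()
        rows = []
        for key in config.analyses:
            if key not in registry:
                raise KeyError(f"unknown analysis {key!r}")
            result = analyses.run_analysis(
                bundle, registry[key], n_perm=config.n_perm, seed=config.seed
            )
            rows.append(result.summary_row())
            if result.perm is not None:
                pd.DataFrame({"null_value": result.perm.null_values}).to_csv(
                    outdir / f"null_{key}.csv", index=False
                )
        results = pd.DataFrame(rows)
        results.to_csv(outdir / "analysis_results.csv", index=False)
        manifest["stages"]["analyses"] = {
            "keys": list(config.analyses),
            "n_perm": config.n_perm,
        }

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=str)
    )
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return json.loads(json.dumps(d, default=str))
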