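"""Reading and writing the interchange formats.

Tables are UTF-8 comma-separated CSV with a header row and ISO-8601
dates; habitat outlines travel as GeoJSON polygons; simulation ground
truth as a JSON sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import Polygon, mapping, shape

from .config import GroundTruth, HabitatRect

SIGHTING_REQUIRED = ["individual_id", "sex", "date", "period_id", "x", "y", "habitat", "year"]
NEST_REQUIRED = [
    "nest_id", "male_id", "female_id", "x", "y", "habitat",
    "laid_date", "incubation_end", "success", "year",
]


def write_sightings(sightings: pd.DataFrame, path: str | Path) -> None:
    out = sightings.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


def read_sightings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in SIGHTING_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sightings file missing columns: {missing}")
    return df


def write_nests(nests: pd.DataFrame, path: str | Path) -> None:
    out = nests.copy()
    for c in ("laid_date", "incubation_end"):
        out[c] = pd.to_datetime(out[c]).dt.date
    out["success"] = out["success"].astype(int)
    out.to_csv(path, index=False)


def read_nests(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["laid_date", "incubation_end"])
    missing = [c for c in NEST_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"nests file missing columns: {missing}")
    df["success"] = df["success"].astype(bool)
    return df


def habitat_polygons(habitats: Sequence[HabitatRect]) -> dict[str, Polygon]:
    return {
        h.label: Polygon(
            [
                (h.xmin, h.ymin),
                (h.xmax, h.ymin),
                (h.xmax, h.ymax),
                (h.xmin, h.ymax),
            ]
        )
        for h in habitats
    }


def write_habitats_geojson(
    habitats: Sequence[HabitatRect] | Mapping[str, Polygon], path: str | Path
) -> None:
    if not isinstance(habitats, Mapping):
        habitats = habitat_polygons(habitats)
    features = [
        {
            "type": "Feature",
            "properties": {"habitat": label},
            "geometry": mapping(poly),
        }
        for label, poly in habitats.items()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_habitats_geojson(path: str | Path) -> dict[str, Polygon]:
    data = json.loads(Path(path).read_text())
    out = {}
    for feat in data["features"]:
        label = feat["properties"]["habitat"]
        out[label] = shape(feat["geometry"])
    return out


def write_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(gt.to_json_dict(), indent=1))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    rows = [
        {"id_a": a, "id_b": b, "sri": d["sri"]}
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["id_a", "id_b", "sri"]).to_csv(path, index=False)


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path)
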