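"""Readers and writers for the pipeline's plain-text formats.

Vector data travel as GeoJSON FeatureCollections (road class, village id
and centroid in feature properties), the population raster as an ESRI
ASCII grid (plain text, origin/cell-size header), and traces as CSV.
Coordinates are metric planar; no CRS handling happens here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, mapping, shape

from .types import (
    Hotspot,
    Landscape,
    MonitorReading,
    PopulationGrid,
    RoadNetwork,
    Village,
    readings_from_dataframe,
    trace_dataframe,
)


def _feature(geom, properties) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _collection(features) -> dict:
    return {"type": "FeatureCollection", "features": list(features)}


def write_roads_geojson(roads: RoadNetwork, path: str | Path) -> None:
    fc = _collection(_feature(g, {"road_class": c}) for g, c in roads.segments)
    Path(path).write_text(json.dumps(fc))


def read_roads_geojson(path: str | Path) -> RoadNetwork:
    fc = json.loads(Path(path).read_text())
    segments = [
        (shape(f["geometry"]), f["properties"]["road_class"]) for f in fc["features"]
    ]
    return RoadNetwork(segments)


def write_villages_geojson(villages: list[Village], path: str | Path) -> None:
    fc = _collection(
        _feature(v.boundary, {"village_id": v.id,
                              "centroid": [v.centroid.x, v.centroid.y]})
        for v in villages
    )
    Path(path).write_text(json.dumps(fc))


def read_villages_geojson(path: str | Path) -> list[Village]:
    fc = json.loads(Path(path).read_text())
    out = []
    for f in fc["features"]:
        boundary: Polygon = shape(f["geometry"])
        props = f["properties"]
        if "centroid" in props:
            centroid = Point(*props["centroid"])
        else:
            centroid = boundary.representative_point()
        out.append(Village(id=str(props["village_id"]), boundary=boundary, centroid=centroid))
    return out


def write_buildings_geojson(buildings: list[Polygon], path: str | Path) -> None:
    fc = _collection(_feature(b, {"building_id": i}) for i, b in enumerate(buildings))
    Path(path).write_text(json.dumps(fc))


def read_buildings_geojson(path: str | Path) -> list[Polygon]:
    fc = json.loads(Path(path).read_text())
    return [shape(f["geometry"]) for f in fc["features"]]


def write_population_asc(grid: PopulationGrid, path: str | Path) -> None:
    """ESRI ASCII grid; rows are written north-to-south per the format."""
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size}\n"
        "NODATA_value -9999\n"
    )
    body = "\n".join(
        " ".join(f"{v:.6g}" for v in row) for row in grid.counts[::-1]
    )
    Path(path).write_text(header + body + "\n")


def read_population_asc(path: str | Path) -> PopulationGrid:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and not lines[i].lstrip()[0].lstrip("-").replace(".", "").isdigit():
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    rows = [np.array(l.split(), dtype=float) for l in lines[i:] if l.strip()]
    counts = np.array(rows)[::-1]
    return PopulationGrid(
        origin=(hdr["xllcorner"], hdr["yllcorner"]),
        cell_size=hdr["cellsize"],
        counts=counts,
    )


def write_traces_csv(readings: list[MonitorReading], path: str | Path) -> None:
    trace_dataframe(readings).to_csv(path, index=False, float_format="%.6f")


def read_traces_csv(path: str | Path) -> list[MonitorReading]:
    return readings_from_dataframe(pd.read_csv(path))


def write_landscape(landscape: Landscape, outdir: str | Path) -> dict[str, str]:
    """Write all landscape layers into ``outdir``; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "roads": outdir / "roads.geojson",
        "villages": outdir / "villages.geojson",
        "buildings": outdir / "buildings.geojson",
        "population": outdir / "population.asc",
        "meta": outdir / "landscape.json",
    }
    write_roads_geojson(landscape.roads, paths["roads"])
    write_villages_geojson(landscape.villages, paths["villages"])
    write_buildings_geojson(landscape.buildings, paths["buildings"])
    write_population_asc(landscape.population, paths["population"])
    meta = {
        "extent": list(landscape.extent),
        "hotspots": [
            {"x": h.point.x, "y": h.point.y, "amplitude": h.amplitude,
             "decay_length": h.decay_length}
            for h in landscape.hotspots
        ],
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}


def read_landscape(outdir: str | Path) -> Landscape:
    outdir = Path(outdir)
    meta = json.loads((outdir / "landscape.json").read_text())
    return Landscape(
        extent=tuple(meta["extent"]),
        roads=read_roads_geojson(outdir / "roads.geojson"),
        population=read_population_asc(outdir / "population.asc"),
        villages=read_villages_geojson(outdir / "villages.geojson"),
        buildings=read_buildings_geojson(outdir / "buildings.geojson"),
        hotspots=[
            Hotspot(point=Point(h["x"], h["y"]), amplitude=h["amplitude"],
                    decay_length=h["decay_length"])
            for h in meta.get("hotspots", [])
        ],
    )
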