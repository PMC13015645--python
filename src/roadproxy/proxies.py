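"""Road-traffic exposure proxies per village.

Three proxies are computed from classed road polylines, a gridded
population raster and village geometries, all in a common metric frame:

* WRND — population-weighted road network density. Road length is summed
  per cell of a fishnet grid aligned to the population raster, converted
  to a density RND = length / area (km/km2), and averaged over the
  village's cells with the cell population counts as weights:
  ``WRND = sum(RND_i * pop_i) / sum(pop_i)``.
* EM — Euclidean distance (km) from the village centroid to the nearest
  main-road segment.
* EH — the same for highways.

Distances are point-to-polyline with interior projection (the nearest
location along the geometry, not only vertices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .types import Landscape, PopulationGrid, RoadNetwork, Village

FLAG_ZERO_POPULATION = "zero-population-fallback"
FLAG_NO_MAIN = "no-main-road"
FLAG_NO_HIGHWAY = "no-highway"


@dataclass
class CellDensity:
    """Road density and population for one fishnet cell."""

    cell_id: tuple[int, int]  # (row, col) in the population grid
    road_length: float  # km
    area: float  # km2
    population: float  # people

    @property
    def rnd(self) -> float:
        """Road network density, km/km2."""
        return self.road_length / self.area


@dataclass
class VillageProxyRecord:
    village_id: str
    wrnd: float  # km/km2, population-weighted
    em: float  # km, NaN when no main road exists
    eh: float  # km, NaN when no highway exists
    flags: set[str] = field(default_factory=set)
    n_cells: int = 0
    total_population: float = 0.0


def build_fishnet(
    grid: PopulationGrid, boundary: Polygon
) -> list[tuple[tuple[int, int], Polygon]]:
    """Cells of the population raster that overlap ``boundary``.

    A cell is included iff its intersection with the boundary has positive
    area (cells merely touched along an edge are excluded). Cell polygons
    coincide exactly with raster cells, so the fishnet is aligned by
    construction.
    """
    gx0, gy0, gx1, gy1 = grid.extent
    bx0, by0, bx1, by1 = boundary.bounds
    if bx1 <= gx0 or bx0 >= gx1 or by1 <= gy0 or by0 >= gy1:
        raise ValueError(
            f"boundary bounds {boundary.bounds} are disjoint from the grid extent {grid.extent}"
        )
    s = grid.cell_size
    c0 = max(0, int(np.floor((bx0 - gx0) / s)))
    c1 = min(grid.ncols - 1, int(np.floor((bx1 - gx0) / s)))
    r0 = max(0, int(np.floor((by0 - gy0) / s)))
    r1 = min(grid.nrows - 1, int(np.floor((by1 - gy0) / s)))
    cells = []
    for row in range(r0, r1 + 1):
        for col in range(c0, c1 + 1):
            poly = grid.cell_polygon(row, col)
            inter = poly.intersection(boundary)
            if inter.area > 0:
                cells.append(((row, col), poly))
    if not cells:
        raise ValueError("boundary does not overlap any grid cell with positive area")
    return cells


def road_length_per_cell(
    roads: RoadNetwork,
    cells: list[tuple[tuple[int, int], Polygon]],
    boundary: Polygon,
    grid: PopulationGrid | None = None,
) -> list[CellDensity]:
    """Per-cell road length (km) after clipping the network to ``boundary``.

    Populations are taken from ``grid`` when given, else 0. Cells with no
    roads get length 0.
    """
    clipped = [g.intersection(boundary) for g in roads.geometries()]
    clipped = [g for g in clipped if not g.is_empty]
    merged = shapely.union_all(clipped) if clipped else None
    out = []
    for (row, col), poly in cells:
        length_m = 0.0
        if merged is not None:
            piece = merged.intersection(poly)
            length_m = piece.length if not piece.is_empty else 0.0
        area_km2 = (poly.area) / 1e6
        pop = float(grid.counts[row, col]) if grid is not None else 0.0
        out.append(CellDensity(cell_id=(row, col), road_length=length_m / 1000.0,
                               area=area_km2, population=pop))
    return out


def wrnd(cells: list[CellDensity]) -> tuple[float, set[str]]:
    """Population-weighted mean road density over the village's cells.

    ``sum(rnd_i * pop_i) / sum(pop_i)``; when the total population is
    zero the unweighted mean RND is returned with a flag.
    """
    if not cells:
        raise ValueError("wrnd requires at least one cell")
    rnds = np.array([c.rnd for c in cells])
    pops = np.array([c.population for c in cells])
    total = pops.sum()
    if total <= 0:
        return float(rnds.mean()), {FLAG_ZERO_POPULATION}
    return float((rnds * pops).sum() / total), set()


def euclidean_distance_to_class(
    centroid: Point, roads: RoadNetwork, road_class: str
) -> float:
    """Shortest straight-line distance (km) from a point to the nearest
    road segment of ``road_class``; NaN when no such segment exists."""
    geoms = roads.of_class(road_class)
    if not geoms:
        return float("nan")
    if len(geoms) > 8:
        tree = STRtree(geoms)
        idx = tree.nearest(centroid)
        # STRtree.nearest is exact for distance queries
        return float(centroid.distance(geoms[int(idx)])) / 1000.0
    return float(min(centroid.distance(g) for g in geoms)) / 1000.0


def compute_village_proxies(
    roads: RoadNetwork,
    population: PopulationGrid,
    village: Village,
) -> VillageProxyRecord:
    """WRND, EM and EH for one village (deterministic)."""
    cells = build_fishnet(population, village.boundary)
    dens = road_length_per_cell(roads, cells, village.boundary, grid=population)
    w, flags = wrnd(dens)
    em = euclidean_distance_to_class(village.centroid, roads, "main")
    eh = euclidean_distance_to_class(village.centroid, roads, "highway")
    if np.isnan(em):
        flags = flags | {FLAG_NO_MAIN}
    if np.isnan(eh):
        flags = flags | {FLAG_NO_HIGHWAY}
    return VillageProxyRecord(
        village_id=village.id,
        wrnd=w,
        em=em,
        eh=eh,
        flags=flags,
        n_cells=len(dens),
        total_population=float(sum(c.population for c in dens)),
    )


def proxy_table(landscape: Landscape):
    """Per-village proxy table for a whole landscape (DataFrame)."""
    import pandas as pd

    rows = []
    for v in landscape.villages:
        rec = compute_village_proxies(landscape.roads, landscape.population, v)
        rows.append((rec.village_id, rec.wrnd, rec.em, rec.eh,
                     ";".join(sorted(rec.flags)), rec.n_cells, rec.total_population))
    return pd.DataFrame(
        rows,
        columns=["village_id", "wrnd_kmkm2", "em_km", "eh_km", "flags", "n_cells", "population"],
    )
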