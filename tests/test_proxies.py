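"""WRND fishnet computation and distance proxies against brute-force
oracles and conservation/invariance properties."""

import numpy as np
import pytest
from shapely.affinity import translate
from shapely.geometry import LineString, Point, Polygon, box

import roadproxy as rp
from roadproxy.proxies import (
    FLAG_NO_MAIN,
    FLAG_ZERO_POPULATION,
    build_fishnet,
    euclidean_distance_to_class,
    road_length_per_cell,
    wrnd,
)
from roadproxy.types import PopulationGrid, RoadNetwork, Village

from brute import dense_sample_polyline_distance, weighted_mean


def _grid(n=10, cell=100.0, origin=(0.0, 0.0), counts=None):
    if counts is None:
        counts = np.zeros((n, n))
    return PopulationGrid(origin=origin, cell_size=cell, counts=counts)


class TestFishnet:
    def test_single_full_cell(self):
        grid = _grid()
        cells = build_fishnet(grid, box(200, 300, 300, 400))
        assert [cid for cid, _ in cells] == [(3, 2)]

    def test_three_by_three_block(self):
        cells = build_fishnet(_grid(), box(100, 100, 400, 400))
        assert len(cells) == 9

    def test_touching_neighbours_excluded(self):
        # boundary exactly one cell: edge-adjacent cells share only a line
        cells = build_fishnet(_grid(), box(500, 500, 600, 600))
        assert len(cells) == 1

    def test_disjoint_boundary_rejected(self):
        with pytest.raises(ValueError):
            build_fishnet(_grid(), box(5000, 5000, 5100, 5100))

    def test_cell_areas_partition_boundary(self, rng):
        """Sum of cell-boundary intersection areas equals the boundary area."""
        for _ in range(20):
            pts = rng.uniform(50, 950, size=(8, 2))
            hull = Polygon(pts).convex_hull
            cells = build_fishnet(_grid(), hull)
            total = sum(poly.intersection(hull).area for _, poly in cells)
            assert total == pytest.approx(hull.area, rel=1e-6)


class TestRoadLengthPerCell:
    def test_segment_within_one_cell(self):
        grid = _grid()
        roads = RoadNetwork([(LineString([(100, 150), (200, 150)]), "main")])
        cells = build_fishnet(grid, box(100, 100, 200, 200))
        dens = road_length_per_cell(roads, cells, box(100, 100, 200, 200), grid=grid)
        assert dens[0].road_length == pytest.approx(0.1)
        assert dens[0].rnd == pytest.approx(10.0)

    def test_segment_split_across_cells(self):
        grid = _grid()
        roads = RoadNetwork([(LineString([(40, 50), (140, 50)]), "main")])
        boundary = box(0, 0, 200, 100)
        cells = build_fishnet(grid, boundary)
        dens = {c.cell_id: c.road_length for c in
                road_length_per_cell(roads, cells, boundary, grid=grid)}
        assert dens[(0, 0)] == pytest.approx(0.06)
        assert dens[(0, 1)] == pytest.approx(0.04)

    def test_length_conservation_random_networks(self, rng):
        grid = _grid()
        for _ in range(20):
            segs = [
                (LineString(rng.uniform(0, 1000, size=(3, 2))), "main")
                for _ in range(4)
            ]
            roads = RoadNetwork(segs)
            hull = Polygon(rng.uniform(100, 900, size=(6, 2))).convex_hull
            cells = build_fishnet(grid, hull)
            dens = road_length_per_cell(roads, cells, hull, grid=grid)
            clipped_km = sum(g.intersection(hull).length for g, _ in segs) / 1000
            assert sum(c.road_length for c in dens) == pytest.approx(clipped_km, rel=1e-6, abs=1e-12)


class TestWrnd:
    def test_direct_formula(self):
        cells = [
            rp.CellDensity(cell_id=(0, 0), road_length=0.02, area=0.01, population=100),
            rp.CellDensity(cell_id=(0, 1), road_length=0.04, area=0.01, population=300),
        ]
        # rnd 2 and 4 -> (2*100 + 4*300)/400 = 3.5
        value, flags = wrnd(cells)
        assert value == pytest.approx(3.5)
        assert flags == set()

    def test_uniform_population_reduces_to_mean(self, rng):
        cells = [rp.CellDensity((0, i), float(rng.uniform(0, 0.1)), 0.01, 50.0)
                 for i in range(10)]
        value, _ = wrnd(cells)
        assert value == pytest.approx(np.mean([c.rnd for c in cells]))

    def test_matches_brute_force_and_bounds(self, rng):
        for _ in range(30):
            cells = [rp.CellDensity((0, i), float(rng.uniform(0, 0.2)), 0.01,
                                    float(rng.uniform(0, 500)))
                     for i in range(50)]
            value, flags = wrnd(cells)
            oracle = weighted_mean([c.rnd for c in cells], [c.population for c in cells])
            assert value == pytest.approx(oracle, abs=1e-12)
            populated = [c.rnd for c in cells if c.population > 0]
            assert min(populated) - 1e-12 <= value <= max(populated) + 1e-12

    def test_zero_population_fallback(self):
        cells = [rp.CellDensity((0, 0), 0.05, 0.01, 0.0),
                 rp.CellDensity((0, 1), 0.15, 0.01, 0.0)]
        value, flags = wrnd(cells)
        assert value == pytest.approx(10.0)  # unweighted mean of 5 and 15
        assert FLAG_ZERO_POPULATION in flags

    def test_empty_cells_rejected(self):
        with pytest.raises(ValueError):
            wrnd([])

    def test_population_scaling_leaves_wrnd_unchanged(self, rng):
        cells = [rp.CellDensity((0, i), float(rng.uniform(0, 0.2)), 0.01,
                                float(rng.uniform(1, 100))) for i in range(20)]
        doubled = [rp.CellDensity(c.cell_id, c.road_length, c.area, 2 * c.population)
                   for c in cells]
        assert wrnd(cells)[0] == pytest.approx(wrnd(doubled)[0], abs=1e-12)


class TestDistances:
    def test_perpendicular_foot_inside_segment(self):
        roads = RoadNetwork([(LineString([(3000, -4000), (3000, 4000)]), "main")])
        d = euclidean_distance_to_class(Point(0, 0), roads, "main")
        assert d == pytest.approx(3.0)

    def test_centroid_on_highway_gives_zero(self):
        roads = RoadNetwork([(LineString([(0, 0), (100, 0)]), "highway")])
        assert euclidean_distance_to_class(Point(50, 0), roads, "highway") == 0.0

    def test_missing_class_gives_nan(self):
        roads = RoadNetwork([(LineString([(0, 0), (100, 0)]), "highway")])
        assert np.isnan(euclidean_distance_to_class(Point(0, 0), roads, "main"))

    def test_matches_dense_sampling_oracle(self, rng):
        for _ in range(20):
            segs = [(LineString(rng.uniform(0, 5000, size=(4, 2))), "main")
                    for _ in range(5)]
            roads = RoadNetwork(segs)
            p = Point(*rng.uniform(0, 5000, size=2))
            d = euclidean_distance_to_class(p, roads, "main")
            oracle = min(
                dense_sample_polyline_distance(p.x, p.y, list(g.coords), spacing=1.0)
                for g, _ in segs
            ) / 1000.0
            assert d == pytest.approx(oracle, abs=1e-3)

    def test_adding_segments_never_increases_distance(self, rng):
        p = Point(2500, 2500)
        segs = []
        last = np.inf
        for _ in range(10):
            segs.append((LineString(rng.uniform(0, 5000, size=(3, 2))), "highway"))
            d = euclidean_distance_to_class(p, RoadNetwork(list(segs)), "highway")
            assert d <= last + 1e-12
            last = d


class TestVillageProxies:
    def _toy(self):
        """2x2-cell village with a vertical highway at x=50: hand-computable."""
        grid = _grid(n=2, cell=100.0, counts=np.full((2, 2), 25.0))
        roads = RoadNetwork([(LineString([(50, 0), (50, 200)]), "highway")])
        village = Village(id="toy", boundary=box(0, 0, 200, 200), centroid=Point(100, 100))
        return roads, grid, village

    def test_hand_computed_toy_fixture(self):
        roads, grid, village = self._toy()
        rec = rp.compute_village_proxies(roads, grid, village)
        # left cells: 100 m road in 0.01 km2 -> rnd 10; right cells 0.
        # uniform population -> wrnd = (10+10+0+0)/4 = 5.
        assert rec.wrnd == pytest.approx(5.0)
        # centroid (100,100) is 50 m from the highway
        assert rec.eh == pytest.approx(0.05)
        assert np.isnan(rec.em) and FLAG_NO_MAIN in rec.flags

    def test_translation_invariance(self):
        roads, grid, village = self._toy()
        dx, dy = 12345.0, -6789.0
        roads2 = RoadNetwork([(translate(g, dx, dy), c) for g, c in roads.segments])
        grid2 = PopulationGrid(origin=(grid.origin[0] + dx, grid.origin[1] + dy),
                               cell_size=grid.cell_size, counts=grid.counts.copy())
        village2 = Village(id="toy", boundary=translate(village.boundary, dx, dy),
                           centroid=translate(village.centroid, dx, dy))
        a = rp.compute_village_proxies(roads, grid, village)
        b = rp.compute_village_proxies(roads2, grid2, village2)
        assert b.wrnd == pytest.approx(a.wrnd, abs=1e-9)
        assert b.eh == pytest.approx(a.eh, abs=1e-9)

    def test_determinism(self, small_landscape):
        v = small_landscape.villages[0]
        a = rp.compute_village_proxies(small_landscape.roads, small_landscape.population, v)
        b = rp.compute_village_proxies(small_landscape.roads, small_landscape.population, v)
        assert (a.wrnd, a.em, a.eh, a.flags) == (b.wrnd, b.em, b.eh, b.flags)

    def test_proxy_table_covers_all_villages(self, small_landscape):
        table = rp.proxy_table(small_landscape)
        assert list(table["village_id"]) == [v.id for v in small_landscape.villages]
        assert (table["eh_km"] >= 0).all()
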