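"""Synthetic landscapes and personal-monitor traces with known ground truth.

The generator emulates the structure of a rural/peri-urban personal PM2.5
monitoring campaign: classed road networks, village polygons with clustered
population, small building footprints, and minute-resolution participant
traces that alternate indoor dwells (inside a home building) with outdoor
walking episodes. PM2.5 follows a traffic distance-decay kernel plus
optional non-traffic hotspot sources with multiplicative lognormal noise,
so both road-dominated and hotspot-dominated pollution regimes are
reachable with known truth labels.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon, box
from shapely.strtree import STRtree

from .types import (
    INDOOR,
    OUTDOOR,
    ConfigurationError,
    ExposureModelParams,
    Hotspot,
    Landscape,
    MonitorReading,
    PopulationGrid,
    RoadNetwork,
    Village,
)

DEFAULT_EXTENT = (0.0, 0.0, 10_000.0, 10_000.0)
DEFAULT_STEP_RANGE = (60.0, 110.0)  # m/min, consistent with adult walking speed


def _pad_extent(extent, cell_size):
    """Pad xmax/ymax upward so cell_size divides both dimensions."""
    xmin, ymin, xmax, ymax = (float(v) for v in extent)
    ncols = max(1, math.ceil((xmax - xmin) / cell_size - 1e-9))
    nrows = max(1, math.ceil((ymax - ymin) / cell_size - 1e-9))
    return (xmin, ymin, xmin + ncols * cell_size, ymin + nrows * cell_size), nrows, ncols


def _edge_crossing_line(rng: np.random.Generator, extent, n_vertices: int = 4) -> LineString:
    """A polyline crossing the extent between two distinct edges, with mild
    jitter at interior vertices so roads are not perfectly straight."""
    xmin, ymin, xmax, ymax = extent
    w, h = xmax - xmin, ymax - ymin

    def point_on_edge(edge, t):
        if edge == 0:
            return (xmin + t * w, ymin)
        if edge == 1:
            return (xmin + t * w, ymax)
        if edge == 2:
            return (xmin, ymin + t * h)
        return (xmax, ymin + t * h)

    e1 = rng.integers(0, 4)
    e2 = (e1 + 1 + rng.integers(0, 3)) % 4
    p1 = np.array(point_on_edge(e1, rng.uniform(0.1, 0.9)))
    p2 = np.array(point_on_edge(e2, rng.uniform(0.1, 0.9)))
    ts = np.linspace(0, 1, n_vertices)
    pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
    jitter_scale = 0.03 * min(w, h)
    jitter = rng.normal(0, jitter_scale, size=(n_vertices, 2))
    jitter[0] = jitter[-1] = 0.0
    pts = pts + jitter
    pts[:, 0] = np.clip(pts[:, 0], xmin, xmax)
    pts[:, 1] = np.clip(pts[:, 1], ymin, ymax)
    return LineString(pts)


def generate_landscape(
    seed: int,
    extent: tuple[float, float, float, float] = DEFAULT_EXTENT,
    n_highways: int = 2,
    n_main: int = 3,
    n_villages: int = 12,
    n_buildings_per_village: int = 8,
    cell_size: float = 100.0,
    n_other: int = 0,
    village_radius_range: tuple[float, float] = (200.0, 400.0),
    village_population_range: tuple[float, float] = (500.0, 3000.0),
    hotspots: list[Hotspot] | None = None,
) -> Landscape:
    """Generate a deterministic synthetic landscape.

    Roads are edge-to-edge polylines; villages are irregular star-convex
    polygons with the stated radius range; population is a sum of isotropic
    Gaussian bumps centred on village centroids, discretised to a
    ``cell_size`` raster; buildings are small rectangles scattered inside
    each village boundary. The same seed gives a bit-identical landscape.
    """
    xmin, ymin, xmax, ymax = (float(v) for v in extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must have positive area")
    if min(n_highways, n_main, n_villages, n_buildings_per_village, n_other) < 0:
        raise ValueError("counts must be >= 0")

    extent, nrows, ncols = _pad_extent(extent, cell_size)
    xmin, ymin, xmax, ymax = extent
    rng = np.random.default_rng(seed)
    region = box(*extent)

    segments: list[tuple[LineString, str]] = []
    for _ in range(n_highways):
        segments.append((_edge_crossing_line(rng, extent), "highway"))
    for _ in range(n_main):
        segments.append((_edge_crossing_line(rng, extent), "main"))
    for _ in range(n_other):
        segments.append((_edge_crossing_line(rng, extent), "other"))
    roads = RoadNetwork(segments)

    # Villages: rejection-sample centroids keeping a modest separation.
    # Settlements cluster along roads: most centroids are drawn as a random
    # point along a road plus a lateral offset, the rest uniformly.
    villages: list[Village] = []
    margin = village_radius_range[1] * 1.3
    centroids: list[np.ndarray] = []
    min_sep = 2.2 * village_radius_range[1]
    road_geoms = roads.geometries()
    p_near_road = 0.7 if road_geoms else 0.0
    for i in range(n_villages):
        for _ in range(200):
            if rng.uniform() < p_near_road:
                g = road_geoms[rng.integers(len(road_geoms))]
                anchor = g.interpolate(rng.uniform(0, g.length))
                c = np.array([anchor.x, anchor.y]) + rng.normal(0, 350.0, size=2)
                c = np.clip(c, [xmin + margin, ymin + margin], [xmax - margin, ymax - margin])
            else:
                c = rng.uniform([xmin + margin, ymin + margin], [xmax - margin, ymax - margin])
            if all(np.hypot(*(c - o)) >= min_sep for o in centroids):
                break
        centroids.append(c)
        radius = rng.uniform(*village_radius_range)
        angles = np.linspace(0, 2 * np.pi, 13)[:-1]
        radii = radius * rng.uniform(0.75, 1.0, size=angles.size)
        ring = np.column_stack([c[0] + radii * np.cos(angles), c[1] + radii * np.sin(angles)])
        boundary = Polygon(ring).intersection(region)
        villages.append(Village(id=f"v{i:03d}", boundary=boundary, centroid=Point(*c)))

    # Population: Gaussian bumps on cell centres.
    counts = np.zeros((nrows, ncols))
    if villages:
        xs = xmin + (np.arange(ncols) + 0.5) * cell_size
        ys = ymin + (np.arange(nrows) + 0.5) * cell_size
        gx, gy = np.meshgrid(xs, ys)
        for v, c in zip(villages, centroids):
            total = rng.uniform(*village_population_range)
            sigma = 0.5 * np.sqrt(v.boundary.area / np.pi)
            r2 = (gx - c[0]) ** 2 + (gy - c[1]) ** 2
            bump = np.exp(-r2 / (2 * sigma**2))
            s = bump.sum()
            if s > 0:
                counts += total * bump / s
    population = PopulationGrid(origin=(xmin, ymin), cell_size=cell_size, counts=counts)

    # Buildings: small rectangles inside each village boundary.
    buildings: list[Polygon] = []
    for v, c in zip(villages, centroids):
        sigma = 0.4 * np.sqrt(v.boundary.area / np.pi)
        placed = 0
        attempts = 0
        while placed < n_buildings_per_village and attempts < 500:
            attempts += 1
            bc = rng.normal(c, sigma)
            hw = rng.uniform(4.0, 7.0)  # half-width 4-7 m
            hh = rng.uniform(3.0, 6.0)
            b = box(bc[0] - hw, bc[1] - hh, bc[0] + hw, bc[1] + hh)
            if v.boundary.contains(b) and all(not b.intersects(o) for o in buildings[-placed:] if placed):
                buildings.append(b)
                placed += 1

    return Landscape(
        extent=extent,
        roads=roads,
        population=population,
        villages=villages,
        buildings=buildings,
        hotspots=list(hotspots or []),
    )


# ---------------------------------------------------------------------------
# Exposure field


def exposure_field(
    x: np.ndarray, y: np.ndarray, landscape: Landscape, params: ExposureModelParams
) -> np.ndarray:
    """Deterministic (noise-free, outdoor) PM2.5 concentration at points.

    background + traffic_amplitude * exp(-d_road / decay) + hotspot terms,
    where d_road is the distance to the nearest road segment of any class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    conc = np.full(x.shape, params.background, dtype=float)
    road_geoms = landscape.roads.geometries()
    if road_geoms and params.traffic_amplitude > 0:
        pts = shapely.points(x, y)
        merged = shapely.union_all(road_geoms)
        d = shapely.distance(pts, merged)
        conc = conc + params.traffic_amplitude * np.exp(-d / params.traffic_decay_length)
    for h in landscape.hotspots:
        d = np.hypot(x - h.point.x, y - h.point.y)
        conc = conc + h.amplitude * np.exp(-d / h.decay_length)
    return conc


def participant_villages(n_participants: int, n_villages: int) -> list[int]:
    """Deterministic home-village assignment: participant i -> i mod n_villages."""
    if n_villages <= 0:
        raise ConfigurationError("landscape has no villages to assign participants to")
    return [i % n_villages for i in range(n_participants)]


def _buildings_by_village(landscape: Landscape) -> list[list[int]]:
    out: list[list[int]] = [[] for _ in landscape.villages]
    for bi, b in enumerate(landscape.buildings):
        for vi, v in enumerate(landscape.villages):
            if v.boundary.covers(b.centroid):
                out[vi].append(bi)
                break
    return out


def simulate_traces(
    landscape: Landscape,
    params: ExposureModelParams,
    n_participants: int,
    minutes_per_participant: int,
    step_range: tuple[float, float] = DEFAULT_STEP_RANGE,
    mean_indoor_minutes: float = 30.0,
    mean_outdoor_minutes: float = 20.0,
    roam_radius: float = 1200.0,
) -> list[MonitorReading]:
    """Simulate minute-resolution traces for ``n_participants``.

    Each participant is assigned a home building in their home village
    (round-robin over villages) and alternates geometrically-distributed
    indoor dwell episodes (position jittered < 2 m inside the building) and
    outdoor walking episodes (uniform step lengths in ``step_range`` m/min,
    reflected at the extent, biased homeward beyond ``roam_radius``).
    PM2.5 is the exposure field at the logged position with multiplicative
    lognormal noise, attenuated indoors. ``truth_env`` is recorded for every
    reading. Deterministic given (landscape, params).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if minutes_per_participant < 2:
        raise ValueError("minutes_per_participant must be >= 2")
    want_indoor = mean_indoor_minutes > 0
    if want_indoor and not landscape.buildings:
        raise ConfigurationError(
            "indoor episodes requested (mean_indoor_minutes > 0) but the landscape has no buildings"
        )

    rng = np.random.default_rng(params.seed)
    xmin, ymin, xmax, ymax = landscape.extent
    b_tree = STRtree(landscape.buildings) if landscape.buildings else None
    by_village = _buildings_by_village(landscape) if landscape.villages else []
    homes = participant_villages(n_participants, max(1, len(landscape.villages))) if landscape.villages else None

    def inside_building(px, py) -> bool:
        if b_tree is None:
            return False
        for idx in b_tree.query(Point(px, py), predicate="covered_by"):
            return True
        return False

    readings: list[MonitorReading] = []
    positions = np.empty((n_participants * minutes_per_participant, 2))
    envs: list[bool] = []  # True = indoor
    meta: list[tuple[str, int]] = []

    for pi in range(n_participants):
        pid = f"p{pi:04d}"
        if landscape.villages:
            vi = homes[pi]
            cand = by_village[vi] or list(range(len(landscape.buildings)))
        else:
            cand = list(range(len(landscape.buildings)))
        if cand:
            home = landscape.buildings[int(rng.choice(cand))]
            hc = np.array([home.centroid.x, home.centroid.y])
        else:
            hc = np.array([(xmin + xmax) / 2, (ymin + ymax) / 2])
            home = None

        indoor = want_indoor and home is not None
        pos = hc.copy() if indoor else rng.uniform([xmin, ymin], [xmax, ymax])
        remaining = _episode_length(rng, mean_indoor_minutes if indoor else mean_outdoor_minutes)
        for t in range(minutes_per_participant):
            if remaining <= 0:
                if home is not None and want_indoor:
                    indoor = not indoor
                remaining = _episode_length(
                    rng, mean_indoor_minutes if indoor else mean_outdoor_minutes
                )
                if indoor and home is not None:
                    pos = hc.copy()
            if indoor:
                # consecutive displacement < 2 m, stays inside the footprint
                pos = hc + rng.uniform(-0.7, 0.7, size=2)
            else:
                pos = _outdoor_step(rng, pos, hc, step_range, roam_radius,
                                    (xmin, ymin, xmax, ymax), inside_building)
            idx = pi * minutes_per_participant + t
            positions[idx] = pos
            envs.append(indoor)
            meta.append((pid, t))
            remaining -= 1

    x = positions[:, 0]
    y = positions[:, 1]
    conc = exposure_field(x, y, landscape, params)
    indoor_mask = np.array(envs)
    conc = np.where(indoor_mask, conc * params.indoor_attenuation, conc)
    if params.noise_sigma_log > 0:
        eps = rng.normal(0.0, params.noise_sigma_log, size=conc.size)
        conc = conc * np.exp(eps)

    # RH / temperature: smooth diurnal sinusoids + noise; carried, unused downstream.
    t_arr = np.array([m[1] for m in meta], dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    rh = np.clip(70 + 15 * np.sin(2 * np.pi * t_arr / 1440 + phase) + rng.normal(0, 2, t_arr.size), 5, 100)
    temp = 25 + 6 * np.sin(2 * np.pi * t_arr / 1440 + phase + np.pi) + rng.normal(0, 0.5, t_arr.size)

    for i, (pid, t) in enumerate(meta):
        readings.append(
            MonitorReading(
                participant_id=pid,
                timestamp=float(t),
                x=float(x[i]),
                y=float(y[i]),
                pm25=float(conc[i]),
                rh=float(rh[i]),
                temp=float(temp[i]),
                truth_env=INDOOR if indoor_mask[i] else OUTDOOR,
            )
        )
    return readings


def _episode_length(rng: np.random.Generator, mean_minutes: float) -> int:
    if mean_minutes <= 0:
        return 10**9  # never leave the other state
    return int(rng.geometric(1.0 / max(1.0, mean_minutes)))


def _outdoor_step(rng, pos, home, step_range, roam_radius, extent, inside_building):
    xmin, ymin, xmax, ymax = extent
    step = rng.uniform(*step_range)
    to_home = home - pos
    dist_home = float(np.hypot(*to_home))
    for _ in range(100):
        if dist_home > roam_radius:
            base = math.atan2(to_home[1], to_home[0])
            theta = rng.normal(base, 0.5)
        else:
            theta = rng.uniform(0, 2 * np.pi)
        cand = pos + step * np.array([math.cos(theta), math.sin(theta)])
        # reflect at the extent
        cand[0] = _reflect(cand[0], xmin, xmax)
        cand[1] = _reflect(cand[1], ymin, ymax)
        if not inside_building(cand[0], cand[1]):
            return cand
    raise RuntimeError("could not place an outdoor step outside all buildings")


def _reflect(v, lo, hi):
    span = hi - lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return lo + v


# ---------------------------------------------------------------------------
# Village-level exposure sampling


def sample_village_exposure(
    landscape: Landscape,
    params: ExposureModelParams,
    n_samples: int = 25,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean outdoor PM2.5 per village from points sampled in its boundary.

    Stands in for the village aggregation of outdoor-filtered readings when
    full trace simulation is not needed: draws ``n_samples`` uniform points
    inside each village boundary, evaluates the noisy outdoor exposure
    model there, and returns per-village means.

    Returns a DataFrame with columns village_id, pm25, n.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for v in landscape.villages:
        bxmin, bymin, bxmax, bymax = v.boundary.bounds
        pts = []
        while len(pts) < n_samples:
            cand = rng.uniform([bxmin, bymin], [bxmax, bymax], size=(4 * n_samples, 2))
            inside = shapely.contains(v.boundary, shapely.points(cand[:, 0], cand[:, 1]))
            pts.extend(cand[inside][: n_samples - len(pts)].tolist())
        pts = np.array(pts)
        conc = exposure_field(pts[:, 0], pts[:, 1], landscape, params)
        if params.noise_sigma_log > 0:
            conc = conc * np.exp(rng.normal(0, params.noise_sigma_log, conc.size))
        rows.append((v.id, float(np.mean(conc)), n_samples))
    return pd.DataFrame(rows, columns=["village_id", "pm25", "n"])


def hotspot_far_from_highways(landscape: Landscape, amplitude: float = 60.0,
                              decay_length: float = 1500.0) -> Hotspot:
    """Place a hotspot at the village centroid farthest from any highway."""
    highways = landscape.roads.of_class("highway")
    if not highways or not landscape.villages:
        raise ConfigurationError("needs at least one highway and one village")
    merged = shapely.union_all(highways)
    best = max(landscape.villages, key=lambda v: v.centroid.distance(merged))
    return Hotspot(point=best.centroid, amplitude=amplitude, decay_length=decay_length)


def with_hotspots(landscape: Landscape, hotspots: list[Hotspot]) -> Landscape:
    return replace(landscape, hotspots=list(hotspots))
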