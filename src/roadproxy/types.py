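"""Shared domain containers for the road-proxy validation pipeline.

All geometries live in a metric planar frame (metres). Real-world inputs
must be projected (e.g. to the UTM zone of the study-area centroid) before
they enter the pipeline; the synthetic generator produces planar
coordinates directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box

ROAD_CLASSES = ("highway", "main", "other")

INDOOR = "indoor"
OUTDOOR = "outdoor"


class ConfigurationError(ValueError):
    """Raised when requested behaviour is inconsistent with the inputs."""


@dataclass(frozen=True)
class ExposureModelParams:
    """Parameters of the generative PM2.5 exposure model.

    Concentration at an outdoor point ``p`` is

        [background + traffic_amplitude * exp(-d_road(p) / traffic_decay_length)
         + sum_h amp_h * exp(-d_h(p) / len_h)] * exp(eps),

    with ``eps ~ Normal(0, noise_sigma_log^2)``; indoor readings are further
    multiplied by ``indoor_attenuation``. ``d_road`` is the distance (m) to
    the nearest road segment of any class.
    """

    background: float = 15.0  # ug/m3
    traffic_amplitude: float = 40.0  # ug/m3 at the kerb
    traffic_decay_length: float = 250.0  # m
    indoor_attenuation: float = 0.6  # unitless, (0, 1]
    noise_sigma_log: float = 0.3  # sigma of multiplicative lognormal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.background > 0:
            raise ValueError("background must be > 0")
        if not self.traffic_decay_length > 0:
            raise ValueError("traffic_decay_length must be > 0")
        if not 0 < self.indoor_attenuation <= 1:
            raise ValueError("indoor_attenuation must be in (0, 1]")
        if self.noise_sigma_log < 0:
            raise ValueError("noise_sigma_log must be >= 0")
        if self.traffic_amplitude < 0:
            raise ValueError("traffic_amplitude must be >= 0")


@dataclass
class MonitorReading:
    """One minute of personal monitoring."""

    participant_id: str
    timestamp: float  # minutes since trace start
    x: float  # m, landscape frame
    y: float  # m
    pm25: float  # ug/m3
    rh: float = float("nan")  # %
    temp: float = float("nan")  # degC
    truth_env: str | None = None  # "indoor" | "outdoor" | None


@dataclass
class RoadNetwork:
    """Classed road polylines in a metric planar frame."""

    segments: list[tuple[LineString, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for geom, cls in self.segments:
            if cls not in ROAD_CLASSES:
                raise ValueError(f"unknown road class {cls!r}; expected one of {ROAD_CLASSES}")
            if geom.length <= 0 or len(geom.coords) < 2:
                import warnings

                warnings.warn(f"dropping degenerate zero-length road segment ({cls})")
                continue
            cleaned.append((geom, cls))
        self.segments = cleaned

    def of_class(self, road_class: str) -> list[LineString]:
        return [g for g, c in self.segments if c == road_class]

    def geometries(self) -> list[LineString]:
        return [g for g, _ in self.segments]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, c in self.segments:
            out[c] = out.get(c, 0) + 1
        return out

    def total_length(self) -> float:
        """Total length in metres."""
        return float(sum(g.length for g, _ in self.segments))


@dataclass
class PopulationGrid:
    """Axis-aligned square-cell raster of population counts.

    ``counts`` has shape (nrows, ncols); row 0 is the southernmost row
    (y increases with row index), matching the cell ids used by the
    fishnet operations.
    """

    origin: tuple[float, float]  # (x0, y0), lower-left corner, m
    cell_size: float  # m
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("population counts must be finite and >= 0")

    @property
    def nrows(self) -> int:
        return self.counts.shape[0]

    @property
    def ncols(self) -> int:
        return self.counts.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def cell_polygon(self, row: int, col: int) -> Polygon:
        x0, y0 = self.origin
        s = self.cell_size
        return box(x0 + col * s, y0 + row * s, x0 + (col + 1) * s, y0 + (row + 1) * s)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre coordinates, shape (nrows, ncols) each."""
        x0, y0 = self.origin
        s = self.cell_size
        xs = x0 + (np.arange(self.ncols) + 0.5) * s
        ys = y0 + (np.arange(self.nrows) + 0.5) * s
        return np.meshgrid(xs, ys)


@dataclass
class Village:
    id: str
    boundary: Polygon
    centroid: Point

    def __post_init__(self) -> None:
        if not self.boundary.covers(self.centroid):
            raise ValueError(f"village {self.id}: centroid lies outside its boundary")


@dataclass
class Hotspot:
    """A non-traffic point source (e.g. market, crop burning) with
    exponential distance decay."""

    point: Point
    amplitude: float  # ug/m3 at the source
    decay_length: float  # m


@dataclass
class Landscape:
    """A synthetic study area: roads, population, villages, buildings."""

    extent: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax (m)
    roads: RoadNetwork
    population: PopulationGrid
    villages: list[Village] = field(default_factory=list)
    buildings: list[Polygon] = field(default_factory=list)
    hotspots: list[Hotspot] = field(default_factory=list)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("extent must have positive area")
        region = box(xmin, ymin, xmax, ymax)
        for v in self.villages:
            if not region.covers(v.boundary):
                raise ValueError(f"village {v.id} boundary extends outside the landscape extent")
        for i, b in enumerate(self.buildings):
            if not region.covers(b):
                raise ValueError(f"building {i} extends outside the landscape extent")

    @property
    def extent_polygon(self) -> Polygon:
        return box(*self.extent)


def as_point(p: Point | Sequence[float]) -> Point:
    return p if isinstance(p, Point) else Point(float(p[0]), float(p[1]))


def trace_dataframe(readings: Iterable[MonitorReading]):
    """Readings -> tidy DataFrame with the canonical trace-CSV columns."""
    import pandas as pd

    rows = [
        (r.participant_id, r.timestamp, r.x, r.y, r.pm25, r.rh, r.temp,
         r.truth_env if r.truth_env is not None else "unknown")
        for r in readings
    ]
    return pd.DataFrame(
        rows,
        columns=["participant_id", "timestamp_min", "x_m", "y_m",
                 "pm25_ugm3", "rh_pct", "temp_c", "truth_env"],
    )


def readings_from_dataframe(df) -> list[MonitorReading]:
    out = []
    for row in df.itertuples(index=False):
        env = getattr(row, "truth_env", "unknown")
        out.append(
            MonitorReading(
                participant_id=str(row.participant_id),
                timestamp=float(row.timestamp_min),
                x=float(row.x_m),
                y=float(row.y_m),
                pm25=float(row.pm25_ugm3),
                rh=float(getattr(row, "rh_pct", float("nan"))),
                temp=float(getattr(row, "temp_c", float("nan"))),
                truth_env=None if env == "unknown" else str(env),
            )
        )
    return out
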