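"""Hexagonal aggregation of village-level PM2.5 and proxies.

Village records are spatially joined to a regular hexagonal tessellation
(default 5 km flat-to-flat, flat-top orientation) and summarised by the
arithmetic mean per hexagon, then assigned the bivariate display classes
used for mapping: fixed WRND breakpoints (10, 20 km/km2), fixed EM
breakpoints (2, 4 km), data-driven EH terciles and PM2.5 quintiles.
All class intervals are left-closed, right-open; the last class is open
above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

WRND_BREAKS = (10.0, 20.0)  # km/km2
WRND_LABELS = ("0-10", "10-20", ">20")
EM_BREAKS = (2.0, 4.0)  # km
EM_LABELS = ("0-2 km", "2-4 km", ">4 km")


@dataclass
class HexAggregate:
    hex_id: str
    hex_polygon: Polygon
    n_villages: int
    mean_pm25: float
    mean_wrnd: float
    mean_em: float
    mean_eh: float
    wrnd_class: str | None = None
    em_class: str | None = None
    eh_class: int | None = None  # tercile index 1..3
    pm25_class: int | None = None  # quintile index 1..5
    village_ids: list[str] = field(default_factory=list)


def _flat_top_hexagon(cx: float, cy: float, circumradius: float) -> Polygon:
    angles = np.deg2rad([0, 60, 120, 180, 240, 300])
    return Polygon(np.column_stack([cx + circumradius * np.cos(angles),
                                    cy + circumradius * np.sin(angles)]))


def make_hex_grid(
    extent: tuple[float, float, float, float], width: float = 5000.0
) -> list[tuple[str, Polygon]]:
    """Regular flat-top hexagons tiling ``extent`` with no gaps/overlaps.

    ``width`` is the flat-to-flat distance (m). Ids are deterministic,
    row-major from the south-west corner.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must have positive area")
    if width <= 0:
        raise ValueError("width must be > 0")
    r = width / np.sqrt(3.0)  # circumradius
    dx = 1.5 * r  # horizontal centre spacing between columns
    dy = width  # vertical centre spacing within a column
    ncols = int(np.ceil((xmax - xmin) / dx)) + 2
    nrows = int(np.ceil((ymax - ymin) / dy)) + 2
    hexes = []
    for row in range(nrows):
        for col in range(ncols):
            cx = xmin + col * dx
            cy = ymin + row * dy + (width / 2 if col % 2 else 0.0)
            poly = _flat_top_hexagon(cx, cy, r)
            bx0, by0, bx1, by1 = poly.bounds
            if bx1 < xmin or bx0 > xmax or by1 < ymin or by0 > ymax:
                continue
            hexes.append((f"h{row:03d}_{col:03d}", poly))
    return hexes


def aggregate_to_hex(
    hexes: Sequence[tuple[str, Polygon]],
    village_records: pd.DataFrame,
) -> list[HexAggregate]:
    """Assign each village to the hexagon containing its centroid and
    average pm25 and proxies per hexagon.

    ``village_records`` needs columns village_id, x, y, pm25, wrnd, em, eh.
    Boundary ties go to the lowest hex_id; hexagons with no villages are
    omitted. A village outside every hexagon is an error (the grid must
    cover the extent of the data).
    """
    ordered = sorted(hexes, key=lambda t: t[0])
    groups: dict[str, list[int]] = {}
    for i, row in enumerate(village_records.itertuples(index=False)):
        pt = Point(row.x, row.y)
        hit = None
        for hid, poly in ordered:
            if poly.covers(pt):
                hit = hid
                break
        if hit is None:
            raise ValueError(f"village {row.village_id} falls outside the hexagonal grid")
        groups.setdefault(hit, []).append(i)
    lookup = dict(hexes)
    out = []
    for hid in sorted(groups):
        idx = groups[hid]
        sub = village_records.iloc[idx]
        out.append(
            HexAggregate(
                hex_id=hid,
                hex_polygon=lookup[hid],
                n_villages=len(idx),
                mean_pm25=float(sub["pm25"].mean()),
                mean_wrnd=float(sub["wrnd"].mean()),
                mean_em=float(sub["em"].mean()),
                mean_eh=float(sub["eh"].mean()),
                village_ids=list(sub["village_id"]),
            )
        )
    return out


def _fixed_class(value: float, breaks: tuple[float, float], labels: tuple[str, str, str]) -> str:
    if value < breaks[0]:
        return labels[0]
    if value < breaks[1]:
        return labels[1]
    return labels[2]


def _quantile_class(values: np.ndarray, k: int) -> np.ndarray:
    """1-based quantile class indices, left-closed; degenerate (constant)
    distributions collapse to class 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.array([], dtype=int)
    if np.all(values == values[0]):
        return np.ones(values.size, dtype=int)
    edges = np.quantile(values, np.linspace(0, 1, k + 1)[1:-1])
    cls = np.searchsorted(edges, values, side="right") + 1
    return np.clip(cls, 1, k)


def assign_classes(aggregates: Sequence[HexAggregate]) -> list[HexAggregate]:
    """Attach bivariate display classes in place (and return the list)."""
    if not aggregates:
        raise ValueError("assign_classes requires at least one aggregate")
    eh_cls = _quantile_class(np.array([a.mean_eh for a in aggregates]), 3)
    pm_cls = _quantile_class(np.array([a.mean_pm25 for a in aggregates]), 5)
    for a, ec, pc in zip(aggregates, eh_cls, pm_cls):
        a.wrnd_class = _fixed_class(a.mean_wrnd, WRND_BREAKS, WRND_LABELS)
        a.em_class = _fixed_class(a.mean_em, EM_BREAKS, EM_LABELS)
        a.eh_class = int(ec)
        a.pm25_class = int(pc)
    return list(aggregates)


def hex_table(aggregates: Sequence[HexAggregate]) -> pd.DataFrame:
    rows = [
        (a.hex_id, a.n_villages, a.mean_pm25, a.mean_wrnd, a.mean_em, a.mean_eh,
         a.wrnd_class, a.em_class, a.eh_class, a.pm25_class)
        for a in aggregates
    ]
    return pd.DataFrame(
        rows,
        columns=["hex_id", "n_villages", "mean_pm25", "mean_wrnd", "mean_em",
                 "mean_eh", "wrnd_class", "em_class", "eh_class", "pm25_class"],
    )
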