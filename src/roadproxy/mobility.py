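"""Indoor/outdoor classification of personal-monitor traces.

Two independent classifiers are reconciled: a displacement-speed rule
(outdoor when minute-to-minute speed reaches a threshold, default
100 m/min) and a building-footprint point-in-polygon rule. Where building
data cover a reading, the building-derived label is treated as ground
truth and overrides the speed label; a confusion matrix of the speed
labels against the building labels is reported before correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely import make_valid
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .types import INDOOR, OUTDOOR, MonitorReading

SPEED_THRESHOLD_M_PER_MIN = 100.0  # displacement threshold separating outdoor movement
GAP_CUTOFF_MIN = 5.0  # speed undefined across longer recording gaps

LABEL_OUTDOOR = "outdoor"
LABEL_NOT_OUTDOOR = "not-outdoor"
LABEL_UNCOVERED = "uncovered"


@dataclass
class ClassifiedReading:
    reading: MonitorReading
    speed: float  # m/min, NaN when missing
    speed_label: str  # outdoor | not-outdoor
    building_label: str  # indoor | outdoor | uncovered
    final_label: str  # indoor | outdoor


@dataclass
class ConfusionMatrix:
    """Speed labels vs building-derived labels over covered readings.

    Positive class is "outdoor": sensitivity is the fraction of
    building-outdoor readings the speed rule also calls outdoor.
    """

    true_outdoor: int = 0
    false_outdoor: int = 0
    true_not_outdoor: int = 0
    false_not_outdoor: int = 0

    @property
    def n_covered(self) -> int:
        return self.true_outdoor + self.false_outdoor + self.true_not_outdoor + self.false_not_outdoor

    @property
    def accuracy(self) -> float:
        n = self.n_covered
        return (self.true_outdoor + self.true_not_outdoor) / n if n else float("nan")

    @property
    def sensitivity(self) -> float:
        denom = self.true_outdoor + self.false_not_outdoor
        return self.true_outdoor / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.true_not_outdoor + self.false_outdoor
        return self.true_not_outdoor / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {
            "true_outdoor": self.true_outdoor,
            "false_outdoor": self.false_outdoor,
            "true_not_outdoor": self.true_not_outdoor,
            "false_not_outdoor": self.false_not_outdoor,
            "n_covered": self.n_covered,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def compute_speeds(
    trace: Sequence[MonitorReading], gap_cutoff: float = GAP_CUTOFF_MIN
) -> np.ndarray:
    """Per-reading displacement speed (m/min) for one participant's trace.

    speed_i = |p_i - p_{i-1}| / (t_i - t_{i-1}); the first reading carries
    back the second reading's speed; speed is NaN across gaps longer than
    ``gap_cutoff`` minutes.
    """
    n = len(trace)
    if n == 0:
        return np.array([])
    if n == 1:
        warnings.warn("single-reading trace: all speeds missing")
        return np.array([np.nan])
    ts = np.array([r.timestamp for r in trace], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise ValueError("trace timestamps must be strictly increasing")
    xy = np.array([(r.x, r.y) for r in trace], dtype=float)
    dt = np.diff(ts)
    disp = np.hypot(*np.diff(xy, axis=0).T)
    speeds = np.empty(n)
    speeds[1:] = np.where(dt > gap_cutoff, np.nan, disp / dt)
    speeds[0] = speeds[1]
    return speeds


def classify_by_speed(
    speeds: np.ndarray, threshold: float = SPEED_THRESHOLD_M_PER_MIN
) -> list[str]:
    """outdoor iff speed >= threshold (inclusive); missing -> not-outdoor."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    speeds = np.asarray(speeds, dtype=float)
    return [
        LABEL_OUTDOOR if (np.isfinite(s) and s >= threshold) else LABEL_NOT_OUTDOOR
        for s in speeds
    ]


def _validated(buildings: Sequence[Polygon]) -> list[Polygon]:
    out = []
    for i, poly in enumerate(buildings):
        if not poly.is_valid:
            repaired = make_valid(poly)
            if repaired.is_valid and repaired.area > 0:
                poly = repaired
            else:
                raise ValueError(f"building polygon {i} is invalid and could not be repaired")
        out.append(poly)
    return out


def classify_by_buildings(
    readings: Sequence[MonitorReading],
    buildings: Sequence[Polygon],
    coverage: Polygon | None = None,
) -> list[str]:
    """Point-in-polygon labels: indoor iff the point lies inside or on the
    boundary of any footprint; outdoor iff in none but within the coverage
    region of the building data; uncovered otherwise.

    ``coverage=None`` means the building data cover everywhere.
    """
    polys = _validated(buildings)
    tree = STRtree(polys) if polys else None
    labels = []
    for r in readings:
        pt = Point(r.x, r.y)
        if coverage is not None and not coverage.covers(pt):
            labels.append(LABEL_UNCOVERED)
            continue
        hit = len(tree.query(pt, predicate="covered_by")) > 0 if tree is not None else False
        labels.append(INDOOR if hit else OUTDOOR)
    return labels


def reconcile(
    speed_labels: Sequence[str], building_labels: Sequence[str]
) -> tuple[list[str], ConfusionMatrix]:
    """Final labels and pre-correction confusion matrix.

    Where the building label covers a reading it wins (mapped to
    indoor/outdoor); where the point is uncovered the speed label decides
    (not-outdoor falls back to indoor). The confusion matrix tallies speed
    vs building labels over covered readings only.
    """
    if len(speed_labels) != len(building_labels):
        raise ValueError("speed and building label lists must be aligned")
    cm = ConfusionMatrix()
    final = []
    for s, b in zip(speed_labels, building_labels):
        if b == LABEL_UNCOVERED:
            final.append(OUTDOOR if s == LABEL_OUTDOOR else INDOOR)
            continue
        speed_out = s == LABEL_OUTDOOR
        building_out = b == OUTDOOR
        if speed_out and building_out:
            cm.true_outdoor += 1
        elif speed_out and not building_out:
            cm.false_outdoor += 1
        elif not speed_out and building_out:
            cm.false_not_outdoor += 1
        else:
            cm.true_not_outdoor += 1
        final.append(OUTDOOR if building_out else INDOOR)
    return final, cm


def classify_trace(
    trace: Sequence[MonitorReading],
    buildings: Sequence[Polygon],
    coverage: Polygon | None = None,
    threshold: float = SPEED_THRESHOLD_M_PER_MIN,
    gap_cutoff: float = GAP_CUTOFF_MIN,
) -> tuple[list[ClassifiedReading], ConfusionMatrix]:
    """Full classification of one participant's ordered trace."""
    speeds = compute_speeds(trace, gap_cutoff=gap_cutoff)
    s_labels = classify_by_speed(speeds, threshold=threshold)
    b_labels = classify_by_buildings(trace, buildings, coverage=coverage)
    final, cm = reconcile(s_labels, b_labels)
    out = [
        ClassifiedReading(reading=r, speed=float(sp), speed_label=sl,
                          building_label=bl, final_label=fl)
        for r, sp, sl, bl, fl in zip(trace, speeds, s_labels, b_labels, final)
    ]
    return out, cm


def classify_readings(
    readings: Sequence[MonitorReading],
    buildings: Sequence[Polygon],
    coverage: Polygon | None = None,
    threshold: float = SPEED_THRESHOLD_M_PER_MIN,
    gap_cutoff: float = GAP_CUTOFF_MIN,
) -> tuple[list[ClassifiedReading], ConfusionMatrix]:
    """Classify a multi-participant reading list; traces are grouped by
    participant_id (input order preserved within each participant) and the
    confusion matrices pooled."""
    by_pid: dict[str, list[MonitorReading]] = {}
    for r in readings:
        by_pid.setdefault(r.participant_id, []).append(r)
    classified: list[ClassifiedReading] = []
    total = ConfusionMatrix()
    for pid, trace in by_pid.items():
        cls, cm = classify_trace(trace, buildings, coverage=coverage,
                                 threshold=threshold, gap_cutoff=gap_cutoff)
        classified.extend(cls)
        total.true_outdoor += cm.true_outdoor
        total.false_outdoor += cm.false_outdoor
        total.true_not_outdoor += cm.true_not_outdoor
        total.false_not_outdoor += cm.false_not_outdoor
    return classified, total


def filter_outdoor(classified: Sequence[ClassifiedReading]) -> list[MonitorReading]:
    """Readings with final_label = outdoor, order preserved."""
    out = [c.reading for c in classified if c.final_label == OUTDOOR]
    if not out:
        warnings.warn("no outdoor readings after classification")
    return out
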