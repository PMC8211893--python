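"""Template-curve selection and resampling.

The cohort template is the subject whose CC area is closest to the mean
area over all subjects (pixel-count dialect, matching the reported area
tables); ties break to the lexicographically smallest subject id so runs
are deterministic.  The template is resampled to K equally arc-length
spaced points (K = 200 by default); its points index every pointwise
statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .curves import BoundaryCurve

DEFAULT_K = 200


@dataclass
class TemplateCurve:
    source_subject_id: str
    points: np.ndarray          # (K, 2) mm, closed, clockwise
    labels: np.ndarray          # (K,) sub-region codes
    source_curve: BoundaryCurve | None = None
    selection: dict = field(default_factory=dict)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def k(self) -> int:
        return len(self.points)

    @property
    def area_mm2(self) -> float:
        if self.source_curve is not None:
            return self.source_curve.area_mm2
        return geometry.polygon_area(self.points)

    @property
    def arc_positions(self) -> np.ndarray:
        """Arc-length coordinate of each template point (mm from the start)."""
        return geometry.cumulative_arclength(self.points)[:-1]

    @property
    def perimeter_mm(self) -> float:
        return geometry.perimeter(self.points)


def resample_closed_curve(curve: BoundaryCurve, k: int):
    """Resample a closed boundary curve to ``k`` equal arc-length points.

    Preserves orientation and start point; each output point inherits the
    sub-region label of the nearest original vertex (by arc position).
    Returns (points, labels).
    """
    if k < 8:
        raise ValueError("K must be >= 8")
    pts, arc = geometry.resample_closed(curve.points, k)
    cum = geometry.cumulative_arclength(curve.points)[:-1]
    # nearest original vertex along the (cyclic) arc coordinate
    idx = np.searchsorted(cum, arc)
    idx = np.clip(idx, 0, len(cum) - 1)
    prev = (idx - 1) % len(cum)
    total = curve.perimeter_mm
    d_next = np.abs(cum[idx] - arc)
    d_prev = np.minimum(np.abs(arc - cum[prev]), total - np.abs(arc - cum[prev]))
    nearest = np.where(d_prev < d_next, prev, idx)
    return pts, curve.labels[nearest]


def select_template(curves, k: int = DEFAULT_K) -> TemplateCurve:
    """Select the curve with area closest to the cohort mean and resample it."""
    curves = list(curves)
    if len(curves) < 2:
        raise ValueError("template selection needs at least 2 curves")
    areas = np.array([c.area_mm2 for c in curves], dtype=float)
    mean = areas.mean()
    dist = np.abs(areas - mean)
    best = min(range(len(curves)), key=lambda i: (dist[i], curves[i].subject_id))
    chosen = curves[best]
    pts, labels = resample_closed_curve(chosen, k)
    return TemplateCurve(
        source_subject_id=chosen.subject_id,
        points=pts,
        labels=labels,
        source_curve=chosen,
        selection={
            "mean_area_mm2": float(mean),
            "areas": {c.subject_id: float(a) for c, a in zip(curves, areas)},
            "abs_deviation": {c.subject_id: float(d) for c, d in zip(curves, dist)},
        },
    )
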