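"""Straightness and orientation metrics for filament centerlines.

Filaments arrive as ordered polylines (e.g. exported from a curvelet-based
extraction tool).  Straightness is the tip-to-tip distance d divided by
the arc length L (1 for a perfectly straight filament); orientation is the
angle of the tip-to-tip chord relative to the stretch (+x) axis, folded
into [-90, +90) degrees.  A chi-square test of homogeneity compares binned
orientation distributions before and after stretch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("polyline must be an (N>=2, 2) array of (x, y)")
    return pts


def arc_length(points) -> float:
    """Sum of segment lengths of the polyline, pixels."""
    pts = _as_points(points)
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def tip_distance(points) -> float:
    """Euclidean distance between the two endpoints, pixels."""
    pts = _as_points(points)
    return float(np.hypot(*(pts[-1] - pts[0])))


def straightness(points) -> float:
    """Tip distance divided by arc length, in (0, 1].

    A closed loop (coincident tips) returns 0 with a warning; a degenerate
    polyline with zero arc length raises.
    """
    pts = _as_points(points)
    L = arc_length(pts)
    if L == 0:
        raise ValueError("polyline has zero length (coincident points)")
    d = tip_distance(pts)
    if d == 0:
        logger.warning("closed-loop filament (tips coincide); straightness 0")
        return 0.0
    # d <= L mathematically; clamp the floating-point ratio to the bound
    return min(d / L, 1.0)


def orientation(points, method: str = "chord") -> float:
    """Filament orientation in degrees in [-90, +90) from the +x axis.

    ``method='chord'`` uses the tip-to-tip chord (consistent with the
    straightness tip convention); ``method='pca'`` uses the major axis of
    the point cloud.  Returns NaN for a closed loop under the chord
    convention (direction undefined).
    """
    pts = _as_points(points)
    if method == "chord":
        dx, dy = pts[-1] - pts[0]
        if dx == 0 and dy == 0:
            return float("nan")
    elif method == "pca":
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        dx, dy = v[:, np.argmax(w)]
    else:
        raise ValueError("method must be 'chord' or 'pca'")
    ang = np.degrees(np.arctan2(dy, dx))
    return float((ang + 90.0) % 180.0 - 90.0)


@dataclass
class FilamentTrace:
    """An ordered filament centerline with derived metrics."""

    points: np.ndarray                 # (N, 2) as (x, y) pixels
    filament_id: int = 0

    def __post_init__(self) -> None:
        self.points = _as_points(self.points)

    @property
    def length(self) -> float:
        return arc_length(self.points)

    @property
    def tip_distance(self) -> float:
        return tip_distance(self.points)

    @property
    def straightness(self) -> float:
        return straightness(self.points)

    @property
    def orientation(self) -> float:
        return orientation(self.points)


def length_filter(traces, min_length: float = 20.0) -> list:
    """Keep traces with arc length >= min_length pixels (inclusive bound)."""
    if min_length <= 0:
        raise ValueError("min_length must be > 0")
    return [t for t in traces if arc_length(getattr(t, "points", t)) >= min_length]


def straightness_classes(traces, cut: float = 0.9) -> tuple[float, float]:
    """Fractions of filaments with straightness below / at-or-above ``cut``."""
    if not 0 < cut < 1:
        raise ValueError("cut must lie in (0, 1)")
    vals = [t.straightness if isinstance(t, FilamentTrace) else float(t)
            for t in traces]
    if not vals:
        raise ValueError("no filaments to classify")
    vals = np.asarray(vals, dtype=float)
    below = float(np.mean(vals < cut))
    return below, 1.0 - below


def orientation_histogram(
    angles_deg, n_bins: int = 18
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of orientations over [-90, 90) degrees.

    Returns (counts, bin_edges); default 18 bins of 10 degrees.
    """
    angles = np.asarray(angles_deg, dtype=float)
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return counts, edges


def orientation_chi2(bins_a, bins_b) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on two binned orientation counts.

    The 2 x K contingency table of (before, after) counts is tested with
    df = K - 1 (no continuity correction).  Bins whose expected count is
    zero raise with advice to merge bins.
    """
    a = np.asarray(bins_a, dtype=float)
    b = np.asarray(bins_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("count vectors must share one binning")
    table = np.stack([a, b])
    col = table.sum(axis=0)
    if np.any(col == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero expected count in some bin; merge adjacent "
                         "bins before testing")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_filaments(path) -> list[FilamentTrace]:
    """Read polylines from CSV with columns filament_id, point_index, x, y."""
    df = pd.read_csv(path)
    required = {"filament_id", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for fid, grp in df.groupby("filament_id", sort=True):
        grp = grp.sort_values("point_index")
        traces.append(FilamentTrace(grp[["x", "y"]].to_numpy(), filament_id=int(fid)))
    return traces


def write_filaments(path, traces: list[FilamentTrace]) -> None:
    rows = []
    for t in traces:
        for i, (x, y) in enumerate(t.points):
            rows.append({"filament_id": t.filament_id, "point_index": i,
                         "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def filament_table(traces: list[FilamentTrace]) -> pd.DataFrame:
    """Per-filament metrics table: length, tip distance, straightness, angle."""
    return pd.DataFrame(
        {
            "filament_id": [t.filament_id for t in traces],
            "length_px": [t.length for t in traces],
            "tip_distance_px": [t.tip_distance for t in traces],
            "straightness": [t.straightness for t in traces],
            "orientation_deg": [t.orientation for t in traces],
        }
    )
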