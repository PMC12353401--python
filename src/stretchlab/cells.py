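"""Per-cell strain from tracked segmentation label images.

Cells arrive as 16-bit label stacks from an external segmenter with
persistent labels over time (0 = background).  Each cell's engineering
step strain along the stretch axis is defined through the stretch ratio of
its second central moment: eps_xx = sqrt(M_xx(t1) / M_xx(t0)) - 1, which
is exact for axis-aligned affine shape changes and robust to boundary
pixelation.  Tissue strain under the cell footprint is the mean of the
valid strain-field pixels beneath the mask of the *earlier* frame of each
interval, matching step-strain semantics.

Inclusion rules: only cells present at every timepoint that never divided
and never left the imaging frame enter the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .strain import StrainField

logger = logging.getLogger(__name__)

FATE_COMPLETE = "complete"
FATE_DIVIDED = "divided"
FATE_LEFT_FRAME = "left_frame"
FATE_LOST = "lost"  # disappeared away from the border with no division
FATE_APPEARED = "appeared"  # entered mid-series (e.g. division offspring)


@dataclass
class CellObservation:
    """One cell at one timepoint: footprint and shape tensor."""

    t: int
    area: float                       # px^2
    centroid: tuple[float, float]     # (x, y) px
    m_xx: float                       # central second moments, px^2
    m_yy: float
    m_xy: float
    touches_border: bool
    bbox_slice: tuple[slice, slice] = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)  # bool, bbox-local

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.bbox_slice] = self.mask
        return out


@dataclass
class CellTrack:
    """One cell's identity across the time series."""

    label: int
    n_timepoints: int
    obs: dict[int, CellObservation] = field(default_factory=dict)
    fate: str = FATE_COMPLETE

    @property
    def present_at(self) -> list[int]:
        return sorted(self.obs)

    def present(self, t: int) -> bool:
        return t in self.obs


def _observe_frame(labels_t: np.ndarray, t: int) -> dict[int, CellObservation]:
    H, W = labels_t.shape
    out = {}
    for rp in regionprops(labels_t):
        mu = rp.moments_central
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == H or c1 == W
        out[rp.label] = CellObservation(
            t=t,
            area=float(rp.area),
            centroid=(float(rp.centroid[1]), float(rp.centroid[0])),  # (x, y)
            m_xx=float(mu[0, 2] / mu[0, 0]),
            m_yy=float(mu[2, 0] / mu[0, 0]),
            m_xy=float(mu[1, 1] / mu[0, 0]),
            touches_border=touches,
            bbox_slice=(slice(r0, r1), slice(c0, c1)),
            mask=rp.image.copy(),
        )
    return out


def track_cells(
    labels: np.ndarray, division_coverage: float = 0.6
) -> list[CellTrack]:
    """Build per-cell tracks from a T x H x W persistent-label stack.

    Fate assignment on disappearance at step t:

    * divided — the cell's last mask is covered at least ``division_coverage``
      by two or more labels that are new at t;
    * left_frame — the last mask touched the image border;
    * lost — otherwise (unexplained disappearance).

    A track is ``complete`` only if present at every timepoint and never
    divided.
    """
    labels = np.asarray(labels)
    if labels.ndim == 2:
        labels = labels[None]
    if labels.min() < 0:
        raise ValueError("labels must be non-negative (0 = background)")
    T = len(labels)
    per_frame = [_observe_frame(labels[t], t) for t in range(T)]
    all_labels = sorted(set().union(*[set(f) for f in per_frame])) if per_frame else []

    tracks = []
    for lab in all_labels:
        track = CellTrack(label=lab, n_timepoints=T)
        for t in range(T):
            if lab in per_frame[t]:
                track.obs[t] = per_frame[t][lab]
        tracks.append(track)

    for track in tracks:
        present = track.present_at
        if len(present) == T:
            track.fate = FATE_COMPLETE
            continue
        t_last = present[-1]
        t_gone = t_last + 1
        if t_gone >= T:
            track.fate = FATE_APPEARED  # entered late, survived to the end
            continue
        last = track.obs[t_last]
        parent_mask = last.full_mask(labels.shape[1:])
        new_labels = set(per_frame[t_gone]) - set(per_frame[t_last])
        covered = np.zeros_like(parent_mask)
        n_children = 0
        for nl in new_labels:
            child = per_frame[t_gone][nl].full_mask(labels.shape[1:])
            if (child & parent_mask).any():
                n_children += 1
                covered |= child & parent_mask
        coverage = covered.sum() / parent_mask.sum()
        if n_children >= 2 and coverage >= division_coverage:
            track.fate = FATE_DIVIDED
        elif last.touches_border:
            track.fate = FATE_LEFT_FRAME
        else:
            track.fate = FATE_LOST
    return tracks


def filter_cells(
    tracks: list[CellTrack],
) -> tuple[list[CellTrack], dict[int, str]]:
    """Keep only complete tracks; report excluded labels with reasons."""
    retained, report = [], {}
    for t in tracks:
        if t.fate == FATE_COMPLETE:
            retained.append(t)
        else:
            report[t.label] = t.fate
    return retained, report


def cell_step_strain(
    track: CellTrack, t0: int, t1: int, axis: str = "x"
) -> float:
    """Engineering step strain of one cell from its shape-tensor change.

    Returns sqrt(M(t1) / M(t0)) - 1 for the chosen axis second moment,
    i.e. the axis stretch ratio of the mask minus one.
    """
    if not (track.present(t0) and track.present(t1)):
        raise ValueError(f"cell {track.label} absent at t={t0} or t={t1}")
    key = {"x": "m_xx", "y": "m_yy"}.get(axis)
    if key is None:
        raise ValueError("axis must be 'x' or 'y'")
    m0 = getattr(track.obs[t0], key)
    m1 = getattr(track.obs[t1], key)
    if m0 <= 0 or m1 <= 0:
        raise ValueError(
            f"cell {track.label}: degenerate second moment along {axis} "
            "(1-px-wide mask?)")
    return float(np.sqrt(m1 / m0) - 1.0)


def tissue_strain_under_cell(
    strain: StrainField, track: CellTrack, t0: int, component: str = "xx"
) -> float:
    """Mean tissue strain over the valid pixels under the cell's t0 mask.

    Returns NaN when no valid strain pixel lies under the mask.
    """
    if not track.present(t0):
        raise ValueError(f"cell {track.label} absent at t={t0}")
    mask = track.obs[t0].full_mask(strain.shape)
    sel = mask & strain.valid
    if not sel.any():
        return float("nan")
    return float(np.mean(strain.component(component)[sel]))


def cell_strain_table(
    labels: np.ndarray,
    strain_fields: list[StrainField] | None = None,
    division_coverage: float = 0.6,
) -> pd.DataFrame:
    """Full per-cell pipeline: track, filter, per-interval cell strain.

    ``strain_fields[k]`` must be the tissue step-strain field for interval
    (k, k+1); when given, the tissue strain under each retained cell's
    earlier-frame footprint is reported alongside the cellular strain.

    Returns one row per retained cell and interval with columns label, t0,
    t1, eps_xx_cell, eps_xx_tissue, area_t0, fate.
    """
    tracks = track_cells(labels, division_coverage)
    retained, report = filter_cells(tracks)
    if report:
        logger.info("excluded %d cells: %s", len(report), report)
    T = len(np.asarray(labels)) if np.asarray(labels).ndim == 3 else 1
    rows = []
    for track in retained:
        for t0 in range(T - 1):
            t1 = t0 + 1
            eps_cell = cell_step_strain(track, t0, t1)
            eps_tissue = float("nan")
            if strain_fields is not None:
                eps_tissue = tissue_strain_under_cell(strain_fields[t0], track, t0)
            rows.append({
                "label": track.label, "t0": t0, "t1": t1,
                "eps_xx_cell": eps_cell, "eps_xx_tissue": eps_tissue,
                "area_t0": track.obs[t0].area, "fate": track.fate,
            })
    return pd.DataFrame(rows, columns=["label", "t0", "t1", "eps_xx_cell",
                                       "eps_xx_tissue", "area_t0", "fate"])
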