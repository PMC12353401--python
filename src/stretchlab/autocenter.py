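"""Drift correction for stage-top stretching acquisitions.

At each acquisition timepoint the sharpest slice of a z-stack serves as a
reference image; the xy drift since the previous timepoint is estimated by
Fourier cross-correlation (inverse transform of the conjugate spectral
product, peak deviation from the image center) and converted into the
compensating stage move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)


@dataclass
class DriftEstimate:
    """Estimated xy drift of the current frame relative to the previous one.

    dx, dy are the correlation-peak deviations from the image center in
    pixels (fftshift convention, so |dx| < W/2 and |dy| < H/2); positive dx
    means the scene moved toward larger x (columns).
    """

    dx: float
    dy: float
    z_index: int = 0
    sharpness: np.ndarray | None = field(default=None, repr=False)


def sharpness_metric(frame: np.ndarray, metric: str = "variance_of_laplacian") -> float:
    """Scalar focus metric of a single frame; larger = sharper."""
    frame = np.asarray(frame, dtype=float)
    if metric == "variance_of_laplacian":
        return float(ndimage.laplace(frame).var())
    if metric == "tenengrad":
        gx = ndimage.sobel(frame, axis=1)
        gy = ndimage.sobel(frame, axis=0)
        return float(np.mean(gx * gx + gy * gy))
    raise ValueError(f"unknown sharpness metric {metric!r}")


def sharpest_z(zstack: np.ndarray, metric: str = "variance_of_laplacian") -> int:
    """Index of the sharpest slice of a Z x H x W stack.

    Ties (including fully featureless stacks) resolve to the lowest index
    with a logged warning.
    """
    zstack = np.asarray(zstack, dtype=float)
    if zstack.ndim == 2:
        zstack = zstack[None]
    scores = np.array([sharpness_metric(s, metric) for s in zstack])
    best = int(np.argmax(scores))
    if np.count_nonzero(scores == scores[best]) > 1:
        logger.warning("sharpness tie across slices; picking lowest index %d", best)
    return best


def xy_drift(
    ref_prev: np.ndarray,
    ref_now: np.ndarray,
    subpixel: bool = False,
    normalize: bool = False,
) -> DriftEstimate:
    """Drift of ``ref_now`` relative to ``ref_prev`` by Fourier correlation.

    Computes the inverse transform of F(ref_prev) * conj(F(ref_now))
    (magnitude-normalized when ``normalize``, i.e. true phase correlation),
    center-shifts the surface and reads the brightest pixel's deviation
    from the image center.  Exact for integer circular shifts; with
    ``subpixel`` a 1D parabola fit refines each axis.  Drifts beyond a
    quarter frame are reported with a warning (the fftshift convention is
    ambiguous beyond half a frame).
    """
    a = np.asarray(ref_prev, dtype=float)
    b = np.asarray(ref_now, dtype=float)
    if a.shape != b.shape:
        raise ValueError("reference images must share one shape")
    if a.std() == 0 or b.std() == 0:
        logger.warning("zero-variance reference image; reporting zero drift")
        return DriftEstimate(0.0, 0.0)
    H, W = a.shape
    prod = np.fft.fft2(a) * np.conj(np.fft.fft2(b))
    if normalize:
        mag = np.abs(prod)
        prod = prod / np.where(mag > 0, mag, 1.0)
    surf = np.fft.fftshift(np.fft.ifft2(prod).real)
    cy, cx = H // 2, W // 2
    peak = float(surf.max())
    cand = np.argwhere(surf >= peak - 1e-12 * max(1.0, abs(peak)))
    dev = cand - np.array([cy, cx])
    kbest = int(np.argmin((dev * dev).sum(axis=1)))
    py, px = cand[kbest]
    # the conjugate-product correlation peaks at minus the scene shift
    dy = float(py - cy)
    dx = float(px - cx)
    if subpixel:
        if 0 < py < H - 1:
            c0, c1, c2 = surf[py - 1, px], surf[py, px], surf[py + 1, px]
            den = c0 - 2 * c1 + c2
            if den < -1e-12:
                dy += 0.5 * (c0 - c2) / den
        if 0 < px < W - 1:
            c0, c1, c2 = surf[py, px - 1], surf[py, px], surf[py, px + 1]
            den = c0 - 2 * c1 + c2
            if den < -1e-12:
                dx += 0.5 * (c0 - c2) / den
    dx, dy = -dx, -dy
    if abs(dx) > W / 4 or abs(dy) > H / 4:
        logger.warning("large drift (%.1f, %.1f) px; shift ambiguity beyond "
                       "half the frame", dx, dy)
    return DriftEstimate(dx, dy)


def recenter_move(est: DriftEstimate, pixel_size: float) -> tuple[float, float]:
    """Stage move (um) that re-registers the view with the earlier timepoint.

    The move is the negated drift converted to micrometres.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    return (-est.dx * pixel_size, -est.dy * pixel_size)


def autocenter_series(
    stacks: np.ndarray,
    pixel_size: float = 1.0,
    metric: str = "variance_of_laplacian",
    subpixel: bool = True,
    normalize: bool = False,
) -> pd.DataFrame:
    """Run the drift-correction loop over a T x Z x H x W acquisition.

    For each timepoint: pick the sharpest z slice, estimate drift against
    the previous timepoint's reference slice, and log the compensating
    stage move.  Returns a table with columns timepoint, z_index, dx_px,
    dy_px, move_x_um, move_y_um.
    """
    stacks = np.asarray(stacks, dtype=float)
    if stacks.ndim == 3:
        stacks = stacks[:, None]
    if stacks.ndim != 4:
        raise ValueError("expected a T x Z x H x W array")
    rows = []
    prev_ref = None
    for t, zstack in enumerate(stacks):
        zi = sharpest_z(zstack, metric)
        ref = zstack[zi]
        if prev_ref is None:
            est = DriftEstimate(0.0, 0.0, z_index=zi)
        else:
            est = xy_drift(prev_ref, ref, subpixel=subpixel, normalize=normalize)
            est.z_index = zi
        mv = recenter_move(est, pixel_size)
        rows.append({"timepoint": t, "z_index": zi, "dx_px": est.dx,
                     "dy_px": est.dy, "move_x_um": mv[0], "move_y_um": mv[1]})
        prev_ref = ref
    return pd.DataFrame(rows)
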