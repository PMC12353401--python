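"""Translation pre-registration and dense displacement estimation.

Large stretches are handled by registering *consecutive* frames (step
displacements), never frame 0 to frame k directly; cumulative strain is
then composed downstream through true-strain summation.

The dense estimator is coarse-to-fine normalized cross-correlation block
matching with subpixel parabola refinement, bilinear densification of the
match grid and Gaussian smoothing.  It accepts externally produced raw
displacement files as a drop-in alternative (see
:func:`stretchlab.io.load_displacement`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation
from skimage.transform import pyramid_reduce, resize

from .io import load_displacement  # noqa: F401  (re-exported convenience)
from .strain import DisplacementField, FrameStack

logger = logging.getLogger(__name__)


@dataclass
class BlockMatchParams:
    """Parameters of the block-matching displacement estimator.

    block
        Template size in pixels (square).
    spacing
        Grid spacing between match nodes, pixels.
    search_radius
        Search half-width at the *coarsest* pyramid level; the effective
        full-resolution reach is roughly search_radius * 2**(levels-1).
    pyramid_levels
        Number of resolution levels (1 = single scale).
    smoothing_sigma
        Gaussian sigma (full-resolution pixels) applied to the dense field.
    min_correlation
        Matches with peak NCC below this are discarded and in-filled from
        their nearest valid neighbour.
    refine_radius
        Search half-width at all finer levels (around the upsampled prior).
    """

    block: int = 32
    spacing: int = 8
    search_radius: int = 16
    pyramid_levels: int = 3
    smoothing_sigma: float = 4.0
    min_correlation: float = 0.3
    refine_radius: int = 3

    def __post_init__(self) -> None:
        if self.block <= self.spacing:
            raise ValueError("block must exceed spacing")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


# ---------------------------------------------------------------------------
# Translation pre-registration
# ---------------------------------------------------------------------------

def translation_register(
    stack: FrameStack, subpixel: bool = True
) -> tuple[FrameStack, np.ndarray]:
    """Align every frame to the first by pure translation.

    Each frame is registered to its predecessor by the shift maximizing
    cross-correlation (subpixel by upsampled DFT when ``subpixel``); shifts
    are accumulated so frame k aligns with frame 0.  Returns the aligned
    stack (out-of-frame pixels NaN) and the cumulative content drift per
    frame as an (T, 2) array of (dx, dy) in pixels.
    """
    frames = np.asarray(stack.frames, dtype=float)
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to register")
    upsample = 20 if subpixel else 1
    drifts = np.zeros((len(frames), 2))
    for k in range(1, len(frames)):
        a, b = frames[k - 1], frames[k]
        if a.std() == 0 or b.std() == 0:
            logger.warning("blank frame at index %d; assuming zero shift", k)
            step = np.zeros(2)
        else:
            # (row, col) shift that moves frame k back onto frame k-1
            shift, _, _ = phase_cross_correlation(a, b, upsample_factor=upsample)
            step = np.array([-shift[1], -shift[0]])  # content drift (dx, dy)
        drifts[k] = drifts[k - 1] + step
    aligned = np.empty_like(frames)
    aligned[0] = frames[0]
    for k in range(1, len(frames)):
        dx, dy = drifts[k]
        aligned[k] = ndimage.shift(frames[k], (-dy, -dx), order=1,
                                   mode="constant", cval=np.nan)
    out = FrameStack(aligned, pixel_size=stack.pixel_size, times=stack.times.copy())
    return out, drifts


# ---------------------------------------------------------------------------
# Block matching
# ---------------------------------------------------------------------------

def _match_nodes(src, tgt, prior_u, prior_v, spacing, block, radius, min_corr):
    """NCC block matching on a regular grid with a dense prior field.

    Returns node coordinate vectors (ys, xs) and per-node (u, v, valid).
    """
    H, W = src.shape
    b2 = block // 2
    ys = np.arange(b2, H - b2 + 1, spacing)
    xs = np.arange(b2, W - b2 + 1, spacing)
    nu = np.zeros((len(ys), len(xs)))
    nv = np.zeros((len(ys), len(xs)))
    nvalid = np.zeros((len(ys), len(xs)), dtype=bool)

    for i, yc in enumerate(ys):
        for j, xc in enumerate(xs):
            pu = int(round(prior_u[yc, xc]))
            pv = int(round(prior_v[yc, xc]))
            tpl = src[yc - b2: yc + b2, xc - b2: xc + b2]
            if tpl.std() == 0:
                continue
            y0 = yc + pv - b2 - radius
            x0 = xc + pu - b2 - radius
            y1, x1 = y0 + block + 2 * radius, x0 + block + 2 * radius
            cy0, cx0 = max(y0, 0), max(x0, 0)
            cy1, cx1 = min(y1, H), min(x1, W)
            if cy1 - cy0 < block + 2 or cx1 - cx0 < block + 2:
                continue
            region = tgt[cy0:cy1, cx0:cx1]
            if region.std() == 0:
                continue
            corr = match_template(region, tpl)
            peak = float(corr.max())
            if not np.isfinite(peak) or peak < min_corr:
                continue
            # candidate peaks (ties broken toward smaller displacement)
            cand = np.argwhere(corr >= peak - 1e-12)
            du = cand[:, 1] + cx0 - (xc - b2)
            dv = cand[:, 0] + cy0 - (yc - b2)
            kbest = int(np.argmin(du * du + dv * dv))
            pi, pj = cand[kbest]
            u, v = float(du[kbest]), float(dv[kbest])
            # subpixel parabola through the peak, each axis independently
            if 0 < pi < corr.shape[0] - 1:
                c0, c1, c2 = corr[pi - 1, pj], corr[pi, pj], corr[pi + 1, pj]
                den = c0 - 2 * c1 + c2
                if den < -1e-12:
                    v += 0.5 * (c0 - c2) / den
            if 0 < pj < corr.shape[1] - 1:
                c0, c1, c2 = corr[pi, pj - 1], corr[pi, pj], corr[pi, pj + 1]
                den = c0 - 2 * c1 + c2
                if den < -1e-12:
                    u += 0.5 * (c0 - c2) / den
            nu[i, j], nv[i, j], nvalid[i, j] = u, v, True
    return ys, xs, nu, nv, nvalid


def _fill_invalid(nu, nv, nvalid):
    """Replace invalid nodes by their nearest valid neighbour's value."""
    if nvalid.all():
        return nu, nv
    _, (ri, ci) = ndimage.distance_transform_edt(
        ~nvalid, return_indices=True)
    return nu[ri, ci], nv[ri, ci]


def _densify(ys, xs, nodes, shape):
    """Bilinear interpolation of node values to a dense image grid."""
    H, W = shape
    if len(ys) == 1 or len(xs) == 1:
        out = np.full(shape, float(np.mean(nodes)))
        return out
    interp = RegularGridInterpolator((ys, xs), nodes, method="linear")
    gy = np.clip(np.arange(H), ys[0], ys[-1])
    gx = np.clip(np.arange(W), xs[0], xs[-1])
    pts = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1)
    return interp(pts.reshape(-1, 2)).reshape(shape)


def estimate_displacement(
    src: np.ndarray,
    tgt: np.ndarray,
    params: BlockMatchParams | None = None,
) -> DisplacementField:
    """Dense displacement field mapping ``src`` coordinates to ``tgt``.

    Coarse-to-fine pyramid of normalized cross-correlation block matching:
    the coarsest level searches ``search_radius`` pixels; finer levels
    search ``refine_radius`` around the upsampled prior.  Peak locations
    are refined by 1D parabola fits; low-correlation nodes are discarded
    and in-filled from nearest valid neighbours before bilinear
    densification and Gaussian smoothing.
    """
    params = params or BlockMatchParams()
    src = np.asarray(src, dtype=float)
    tgt = np.asarray(tgt, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError("src and tgt must share one shape")
    if src.std() == 0 or tgt.std() == 0:
        raise ValueError("insufficient texture: zero-variance input")

    # build pyramids, finest first
    levels_src, levels_tgt = [src], [tgt]
    for _ in range(params.pyramid_levels - 1):
        nxt = pyramid_reduce(levels_src[-1], downscale=2)
        if min(nxt.shape) < params.block + 2:
            break
        levels_src.append(nxt)
        levels_tgt.append(pyramid_reduce(levels_tgt[-1], downscale=2))

    prior_u = np.zeros(levels_src[-1].shape)
    prior_v = np.zeros(levels_src[-1].shape)
    valid = None
    for li in range(len(levels_src) - 1, -1, -1):
        s, t = levels_src[li], levels_tgt[li]
        radius = params.search_radius if li == len(levels_src) - 1 \
            else params.refine_radius
        ys, xs, nu, nv, nvalid = _match_nodes(
            s, t, prior_u, prior_v, params.spacing, params.block,
            radius, params.min_correlation)
        if not nvalid.any():
            raise ValueError("insufficient texture: no block matched above "
                             f"min_correlation={params.min_correlation}")
        nu, nv = _fill_invalid(nu, nv, nvalid)
        u = _densify(ys, xs, nu, s.shape)
        v = _densify(ys, xs, nv, s.shape)
        sigma = params.smoothing_sigma / (2 ** li)
        if sigma > 0.25:
            u = ndimage.gaussian_filter(u, sigma)
            v = ndimage.gaussian_filter(v, sigma)
        if li == 0:
            # pixel validity: whether the nearest match node was accepted
            vy = np.clip(np.round((np.arange(s.shape[0]) - ys[0]) / params.spacing),
                         0, len(ys) - 1).astype(int)
            vx = np.clip(np.round((np.arange(s.shape[1]) - xs[0]) / params.spacing),
                         0, len(xs) - 1).astype(int)
            valid = nvalid[np.ix_(vy, vx)]
            prior_u, prior_v = u, v
        else:
            shape_next = levels_src[li - 1].shape
            prior_u = resize(u, shape_next, order=1) * 2.0
            prior_v = resize(v, shape_next, order=1) * 2.0

    return DisplacementField(prior_u, prior_v, valid)


def displacement_series(
    stack: FrameStack, params: BlockMatchParams | None = None
) -> list[DisplacementField]:
    """Consecutive-pair displacement fields for a whole time series."""
    fields = []
    for k in range(len(stack) - 1):
        f = estimate_displacement(stack.frames[k], stack.frames[k + 1], params)
        f.source_index, f.target_index = k, k + 1
        fields.append(f)
    return fields
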