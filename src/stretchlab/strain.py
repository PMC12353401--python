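"""Strain algebra for uniaxial stretch experiments.

This module turns dense displacement fields into pixel-wise engineering
strain fields, converts between engineering and true (logarithmic) strain,
composes step strains into cumulative strains, computes strain rates, and
summarizes strain fields by box-wise spatial statistics.

Conventions
-----------
* x = column index = stretch axis; y = row index.
* Elongation along an axis is positive strain.
* Strains are dimensionless fractions (0.5 means 50%); rates are min^-1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

StrainKind = Literal["step_eng", "true", "cum_eng"]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class FrameStack:
    """An ordered stack of 2D grayscale frames.

    Parameters
    ----------
    frames
        Array of shape (T, H, W), any numeric dtype.
    pixel_size
        Physical pixel size in micrometres per pixel (> 0).
    times
        Acquisition time of each frame in minutes, strictly increasing.
        Defaults to 0, 1, ..., T-1.
    """

    frames: np.ndarray
    pixel_size: float = 1.0
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {self.frames.shape}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.times is None:
            self.times = np.arange(len(self.frames), dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (len(self.frames),):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class DisplacementField:
    """Per-pixel displacement (in pixels) mapping a source frame to a target.

    ``u`` is displacement along x (columns), ``v`` along y (rows).  Pixels
    where ``valid`` is False carry no information and propagate as invalid
    through strain computation.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray | None = None
    source_index: int = 0
    target_index: int = 1

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 2:
            raise ValueError("u and v must be 2D arrays of equal shape")
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.u.shape:
                raise ValueError("valid mask shape must match u/v")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int], **kw) -> "DisplacementField":
        return cls(np.zeros(shape), np.zeros(shape), **kw)


@dataclass
class StrainField:
    """Pixel-wise symmetric 2D strain components with a kind flag."""

    eps_xx: np.ndarray
    eps_yy: np.ndarray
    eps_xy: np.ndarray
    kind: StrainKind = "step_eng"
    interval: tuple[float, float] = (0.0, 1.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.eps_xx = np.asarray(self.eps_xx, dtype=float)
        self.eps_yy = np.asarray(self.eps_yy, dtype=float)
        self.eps_xy = np.asarray(self.eps_xy, dtype=float)
        if not (self.eps_xx.shape == self.eps_yy.shape == self.eps_xy.shape):
            raise ValueError("strain components must share one shape")
        if self.valid is None:
            self.valid = np.isfinite(self.eps_xx) & np.isfinite(self.eps_yy)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.kind not in ("step_eng", "true", "cum_eng"):
            raise ValueError(f"unknown strain kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.eps_xx.shape

    def component(self, name: str) -> np.ndarray:
        try:
            return {"xx": self.eps_xx, "yy": self.eps_yy, "xy": self.eps_xy}[name]
        except KeyError:
            raise ValueError(f"component must be xx, yy or xy, got {name!r}") from None


@dataclass
class BoxStats:
    """Box-wise spatial statistics of one strain component."""

    box_size: int
    component: str
    means: np.ndarray       # (n_rows, n_cols) per-box mean
    sds: np.ndarray         # (n_rows, n_cols) per-box SD
    global_mean: float      # mean over box means
    global_sd: float        # SD over box means

    @property
    def n_boxes(self) -> int:
        return self.means.size

    def to_frame(self) -> pd.DataFrame:
        rows, cols = np.indices(self.means.shape)
        return pd.DataFrame(
            {
                "box_row": rows.ravel(),
                "box_col": cols.ravel(),
                "mean": self.means.ravel(),
                "sd": self.sds.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# Scalar strain algebra
# ---------------------------------------------------------------------------

def engineering_strain(l0, l):
    """Engineering strain (l - l0) / l0 of a length change.

    ``l0`` must be strictly positive (elementwise for arrays).
    """
    l0 = np.asarray(l0, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(l0 <= 0):
        raise ValueError("original length l0 must be > 0")
    out = (l - l0) / l0
    return float(out) if out.ndim == 0 else out


def eng_to_true(eps_eng):
    """Convert engineering strain to true (logarithmic) strain, ln(1 + eps).

    Defined only for eps > -1; at -1 the material would be annihilated.
    """
    eps = np.asarray(eps_eng, dtype=float)
    finite = np.isfinite(eps)
    if np.any(eps[finite] <= -1):
        raise ValueError("engineering strain must be > -1")
    out = np.log1p(eps)
    return float(out) if out.ndim == 0 else out


def true_to_eng(eps_true):
    """Convert true strain back to engineering strain, exp(eps) - 1."""
    eps = np.asarray(eps_true, dtype=float)
    out = np.expm1(eps)
    return float(out) if out.ndim == 0 else out


def accumulate(steps: Sequence) -> float | np.ndarray:
    """Compose ordered engineering step strains into a cumulative strain.

    Each step is converted to true strain, the true strains are summed, and
    the sum is converted back: exp(sum ln(1+eps_i)) - 1, which equals
    prod(1+eps_i) - 1.  Works on scalars or same-shape arrays (pixelwise,
    at fixed pixel coordinates); NaNs propagate so invalid pixels stay
    invalid in the cumulative field.
    """
    steps = list(steps)
    if not steps:
        return 0.0
    total = None
    for s in steps:
        s = np.asarray(s, dtype=float)
        finite = np.isfinite(s)
        if np.any(s[finite] <= -1):
            raise ValueError("every step strain must be > -1")
        t = np.log1p(s)
        total = t if total is None else total + t
    out = np.expm1(total)
    return float(out) if np.ndim(out) == 0 else out


def accumulate_fields(fields: Sequence[StrainField]) -> StrainField:
    """Pixelwise cumulative engineering strain from ordered step-strain fields.

    Accumulation is Eulerian: each pixel composes the step strains observed
    at its own (pre-registered) coordinates.  Validity is the conjunction of
    the step validities; pixels carrying a nonphysical normal strain
    (<= -1, e.g. estimator outliers near the frame edge) are marked invalid
    with a warning instead of poisoning the composition.
    """
    fields = list(fields)
    if not fields:
        raise ValueError("need at least one step field")
    shape = fields[0].shape
    valid = np.ones(shape, dtype=bool)
    for f in fields:
        if f.shape != shape:
            raise ValueError("all step fields must share one shape")
        if f.kind != "step_eng":
            raise ValueError("accumulate_fields expects kind='step_eng' fields")
        valid &= f.valid
        with np.errstate(invalid="ignore"):
            physical = (f.eps_xx > -1) & (f.eps_yy > -1)
        n_bad = int(np.count_nonzero(valid & ~physical))
        if n_bad:
            logger.warning("%d pixels with step strain <= -1 marked invalid",
                           n_bad)
            valid &= physical
    comps = {}
    for name in ("eps_xx", "eps_yy", "eps_xy"):
        stack = [np.where(valid, getattr(f, name), np.nan) for f in fields]
        comps[name] = accumulate(stack)
    return StrainField(
        comps["eps_xx"], comps["eps_yy"], comps["eps_xy"],
        kind="cum_eng",
        interval=(fields[0].interval[0], fields[-1].interval[1]),
        valid=valid,
    )


def strain_rate(eps_cum, elapsed_min: float):
    """Strain rate: cumulative strain divided by elapsed time (min^-1)."""
    if elapsed_min <= 0:
        raise ValueError("elapsed time must be > 0")
    out = np.asarray(eps_cum, dtype=float) / elapsed_min
    return float(out) if out.ndim == 0 else out


@dataclass
class StrainSeries:
    """Ordered step strains plus derived cumulative strains and rates.

    ``steps`` may hold scalars (region means) or StrainFields; ``times``
    holds the T+1 interval boundaries in minutes (t0, t1, ..., tn).
    """

    steps: list = field(default_factory=list)
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.steps) + 1:
                raise ValueError("times must have len(steps)+1 boundaries")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    def cumulative(self, upto: int | None = None):
        """Cumulative engineering strain composed from steps 1..upto."""
        k = len(self.steps) if upto is None else upto
        sub = self.steps[:k]
        if sub and isinstance(sub[0], StrainField):
            return accumulate_fields(sub)
        return accumulate(sub)

    def rates(self) -> np.ndarray:
        """Strain rate at each step boundary: cumulative / elapsed time."""
        if self.times is None:
            raise ValueError("times are required to compute rates")
        out = []
        for k in range(1, len(self.steps) + 1):
            cum = self.cumulative(k)
            if isinstance(cum, StrainField):
                raise TypeError("rates() supports scalar series only")
            out.append(strain_rate(cum, self.times[k] - self.times[0]))
        return np.asarray(out)


# ---------------------------------------------------------------------------
# Displacement -> strain
# ---------------------------------------------------------------------------

def _plane_fit_gradients(
    f: np.ndarray, mask: np.ndarray, window: int, min_pixels: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares plane-fit gradients of f over a sliding window.

    At each pixel a plane a + b*dx + c*dy is fitted to the masked values in
    the window; (b, c) are the x/y gradients.  Returns (dfdx, dfdy, ok)
    where ok marks pixels with enough well-spread neighbours for a unique
    fit.  Exact for affine fields regardless of the mask geometry.
    """
    r = window // 2
    off = np.arange(-r, r + 1, dtype=float)
    kx = np.tile(off, (window, 1))           # kernel of x-offsets
    ky = kx.T                                 # kernel of y-offsets
    ones = np.ones((window, window))

    m = mask.astype(float)
    fm = np.where(mask, f, 0.0)

    def corr(img, ker):
        return ndimage.correlate(img, ker, mode="constant", cval=0.0)

    s1 = corr(m, ones)
    sx = corr(m, kx)
    sy = corr(m, ky)
    sxx = corr(m, kx * kx)
    sxy = corr(m, kx * ky)
    syy = corr(m, ky * ky)
    sf = corr(fm, ones)
    sxf = corr(fm, kx)
    syf = corr(fm, ky)

    # Normal equations [[s1,sx,sy],[sx,sxx,sxy],[sy,sxy,syy]] @ (a,b,c) = rhs
    A = np.stack(
        [
            np.stack([s1, sx, sy], axis=-1),
            np.stack([sx, sxx, sxy], axis=-1),
            np.stack([sy, sxy, syy], axis=-1),
        ],
        axis=-2,
    )
    rhs = np.stack([sf, sxf, syf], axis=-1)

    det = np.linalg.det(A)
    ok = (s1 >= min_pixels) & (np.abs(det) > 1e-9)
    A_safe = np.where(ok[..., None, None], A, np.eye(3))
    sol = np.linalg.solve(A_safe, rhs[..., None])[..., 0]
    dfdx = np.where(ok, sol[..., 1], np.nan)
    dfdy = np.where(ok, sol[..., 2], np.nan)
    return dfdx, dfdy, ok


def strain_from_displacement(
    disp: DisplacementField,
    window: int = 3,
    boundary: Literal["shrink", "invalid"] = "shrink",
    min_pixels: int = 4,
    interval: tuple[float, float] | None = None,
) -> StrainField:
    """Engineering step-strain field from a dense displacement field.

    At each pixel a least-squares plane is fitted to u and to v over a
    ``window`` x ``window`` subarray (default 3x3); the plane slopes give
    eps_xx = du/dx, eps_yy = dv/dy and eps_xy = (du/dy + dv/dx) / 2.  The
    plane fit reproduces the gradient of any affine displacement exactly.

    ``boundary='shrink'`` fits over the in-image part of the window near the
    borders (at least ``min_pixels`` pixels); ``boundary='invalid'`` marks
    border pixels invalid instead.  Invalid input pixels never contribute
    and come out invalid.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    H, W = disp.shape
    if window > min(H, W):
        raise ValueError(f"window {window} exceeds image extent {min(H, W)}")

    mask = disp.valid & np.isfinite(disp.u) & np.isfinite(disp.v)
    if not mask.any():
        nan = np.full((H, W), np.nan)
        return StrainField(nan, nan.copy(), nan.copy(), kind="step_eng",
                           interval=interval or (0.0, 1.0),
                           valid=np.zeros((H, W), bool))

    dudx, dudy, ok_u = _plane_fit_gradients(disp.u, mask, window, min_pixels)
    dvdx, dvdy, ok_v = _plane_fit_gradients(disp.v, mask, window, min_pixels)
    ok = ok_u & ok_v & mask

    if boundary == "invalid":
        r = window // 2
        border = np.zeros((H, W), dtype=bool)
        border[r:H - r, r:W - r] = True
        ok &= border
    elif boundary != "shrink":
        raise ValueError("boundary must be 'shrink' or 'invalid'")

    eps_xx = np.where(ok, dudx, np.nan)
    eps_yy = np.where(ok, dvdy, np.nan)
    eps_xy = np.where(ok, 0.5 * (dudy + dvdx), np.nan)
    return StrainField(eps_xx, eps_yy, eps_xy, kind="step_eng",
                       interval=interval or (0.0, 1.0), valid=ok)


# ---------------------------------------------------------------------------
# Box statistics
# ---------------------------------------------------------------------------

def box_stats(
    strain: StrainField | np.ndarray,
    component: str = "xx",
    box: int = 20,
) -> BoxStats:
    """Tile a strain component with non-overlapping box x box tiles.

    Partial tiles at the right/bottom edges are dropped (with a logged
    warning) so every box carries the same number of pixels.  Per-box means
    and SDs ignore invalid pixels; the global mean +/- SD is taken over the
    box means.
    """
    if box < 2:
        raise ValueError("box must be >= 2 pixels")
    if isinstance(strain, StrainField):
        data = np.where(strain.valid, strain.component(component), np.nan)
    else:
        data = np.asarray(strain, dtype=float)
    H, W = data.shape
    if box > min(H, W):
        raise ValueError(f"box {box} exceeds image extent {min(H, W)}")
    nr, nc = H // box, W // box
    if nr * box != H or nc * box != W:
        logger.warning(
            "image %dx%d is not an exact multiple of box %d; "
            "partial edge tiles dropped", H, W, box,
        )
    tiles = data[: nr * box, : nc * box].reshape(nr, box, nc, box)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tiles
        means = np.nanmean(tiles, axis=(1, 3))
        sds = np.nanstd(tiles, axis=(1, 3))
        gmean = float(np.nanmean(means))
        gsd = float(np.nanstd(means))
    return BoxStats(box_size=box, component=component if isinstance(strain, StrainField) else "raw",
                    means=means, sds=sds, global_mean=gmean, global_sd=gsd)
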