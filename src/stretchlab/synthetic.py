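"""Seeded generators of ground-truthed synthetic inputs.

Every stage of the toolkit can be exercised without real microscope data:

* deformed fluorescent-bead time series with analytic displacement fields,
* tracked cell-label stacks with controllable per-cell strain
  heterogeneity, divisions and frame exits,
* tortuous filament centerlines with known orientation statistics,
* defocused, drifting z-stack acquisitions for the drift-correction loop.

All generators are deterministic given their seed (bit-identical arrays).
Deformations are applied about the image center; the default lateral
contraction ratio nu = 0.27 makes uniaxially stretched synthetic data
visually comparable to an elastomeric substrate that thins sideways about
a quarter as fast as it elongates.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from shapely.affinity import affine_transform as shp_affine
from shapely.geometry import LineString, Polygon, box as shp_box
from shapely.ops import split as shp_split
from scipy.spatial import Voronoi
from skimage.draw import polygon as draw_polygon

from .autocenter import recenter_move, sharpest_z, xy_drift
from .strain import DisplacementField, FrameStack, accumulate
from .filaments import FilamentTrace

DEFAULT_NU = 0.27


# ---------------------------------------------------------------------------
# Deformation schedules
# ---------------------------------------------------------------------------

@dataclass
class DeformationSchedule:
    """Ordered per-step engineering strains applied about the image center.

    ``step_eps_xx[k]`` is the engineering step strain of interval k along
    the stretch axis; the lateral step strain is -nu * eps_xx.  An optional
    ``nonuniformity`` amplitude adds a linear ramp of the local step strain
    across x (phenomenological grip-thinning stand-in).
    """

    step_eps_xx: np.ndarray
    nu: float = DEFAULT_NU
    nonuniformity: float = 0.0
    dt_min: float = 2.0

    def __post_init__(self) -> None:
        self.step_eps_xx = np.asarray(self.step_eps_xx, dtype=float)
        if np.any(self.step_eps_xx <= -1):
            raise ValueError("every step strain must be > -1")

    @property
    def n_steps(self) -> int:
        return len(self.step_eps_xx)

    @property
    def step_eps_yy(self) -> np.ndarray:
        return -self.nu * self.step_eps_xx

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt_min

    def cumulative_eng(self, upto: int | None = None) -> float:
        return accumulate(self.step_eps_xx[: upto])

    # -- constructors ------------------------------------------------------

    @classmethod
    def uniform(cls, n_steps: int, eps_xx: float, **kw) -> "DeformationSchedule":
        """n identical engineering step strains."""
        return cls(np.full(n_steps, float(eps_xx)), **kw)

    @classmethod
    def from_grip_displacement(
        cls, l0_um: float = 2000.0, step_um: float = 375.0, n_steps: int = 8, **kw
    ) -> "DeformationSchedule":
        """Stepwise grip protocol: equal grip increments from a 2 mm gap.

        Eight 375 um steps from 2 mm telescope to a 150% cumulative
        grip-to-grip strain.
        """
        lengths = l0_um + step_um * np.arange(n_steps + 1)
        return cls(np.diff(lengths) / lengths[:-1], **kw)

    @classmethod
    def constant_velocity(
        cls, l0_um: float = 2000.0, velocity_um_min: float = 42.6,
        interval_min: float = 5.0, n_steps: int = 24, **kw
    ) -> "DeformationSchedule":
        """Constant grip velocity sampled at fixed imaging intervals."""
        lengths = l0_um + velocity_um_min * interval_min * np.arange(n_steps + 1)
        kw.setdefault("dt_min", interval_min)
        return cls(np.diff(lengths) / lengths[:-1], **kw)


def _step_displacement(
    shape: tuple[int, int], eps_xx: float, eps_yy: float, nonuniformity: float
) -> DisplacementField:
    """Analytic displacement of one step on the pixel grid (center-anchored)."""
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    y, x = np.mgrid[0:H, 0:W].astype(float)
    local_xx = eps_xx * (1.0 + nonuniformity * (x - cx) / (W / 2.0))
    u = local_xx * (x - cx)
    v = eps_yy * (y - cy)
    return DisplacementField(u, v)


def _advect(points: np.ndarray, center: np.ndarray, eps_xx: float,
            eps_yy: float, nonuniformity: float, half_width: float) -> np.ndarray:
    """Forward-advect (x, y) points by one deformation step about center."""
    rel = points - center
    local_xx = eps_xx * (1.0 + nonuniformity * rel[:, 0] / half_width)
    out = points.copy()
    out[:, 0] = center[0] + rel[:, 0] * (1.0 + local_xx)
    out[:, 1] = center[1] + rel[:, 1] * (1.0 + eps_yy)
    return out


# ---------------------------------------------------------------------------
# Bead series
# ---------------------------------------------------------------------------

def _render_spots(shape, positions, sigma, amplitude=1.0) -> np.ndarray:
    """Render Gaussian spots at subpixel positions onto a zero image."""
    H, W = shape
    img = np.zeros(shape)
    r = max(3, int(np.ceil(4 * sigma)))
    for x, y in positions:
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        xs = slice(max(x0 - r, 0), min(x0 + r + 1, W))
        ys = slice(max(y0 - r, 0), min(y0 + r + 1, H))
        if xs.start >= xs.stop or ys.start >= ys.stop:
            continue
        gy, gx = np.mgrid[ys, xs].astype(float)
        img[ys, xs] += amplitude * np.exp(
            -((gx - x) ** 2 + (gy - y) ** 2) / (2 * sigma * sigma))
    return img


@dataclass
class BeadSeries:
    """Synthetic bead acquisition with per-step analytic truth."""

    stack: FrameStack
    fields: list[DisplacementField]        # truth, one per step
    positions: np.ndarray                  # (T, n_beads, 2) as (x, y)
    schedule: DeformationSchedule


def gen_bead_series(
    n_beads: int = 800,
    image_size: tuple[int, int] = (400, 400),
    bead_radius_px: float = 2.5,
    psf_sigma: float = 1.0,
    noise_sd: float = 0.01,
    schedule: DeformationSchedule | None = None,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> BeadSeries:
    """Fluorescent-bead time series advected by a deformation schedule.

    Beads are placed uniformly at random, rendered as Gaussian spots
    (sigma combines bead radius and point-spread blur in quadrature), and
    advected forward about the image center each step; Gaussian read noise
    is added per frame.  The analytic per-step displacement fields are
    returned alongside the rendered stack.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    H, W = image_size
    sigma = float(np.hypot(bead_radius_px / 2.0, psf_sigma))
    if n_beads * np.pi * (3 * sigma) ** 2 > 20 * H * W:
        raise ValueError("infeasible bead density for this image size")
    schedule = schedule or DeformationSchedule.uniform(8, 0.10)
    rng = np.random.default_rng(seed)
    margin = 3 * sigma
    pos0 = np.column_stack([
        rng.uniform(margin, W - margin, n_beads),
        rng.uniform(margin, H - margin, n_beads),
    ])
    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])

    positions = [pos0]
    for k in range(schedule.n_steps):
        positions.append(_advect(positions[-1], center,
                                 schedule.step_eps_xx[k],
                                 schedule.step_eps_yy[k],
                                 schedule.nonuniformity, W / 2.0))
    positions = np.stack(positions)

    frames = np.empty((schedule.n_steps + 1, H, W), dtype=np.float32)
    for t in range(schedule.n_steps + 1):
        img = _render_spots((H, W), positions[t], sigma)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, (H, W))
        frames[t] = img
    stack = FrameStack(frames, pixel_size=pixel_size, times=schedule.times)

    fields = []
    for k in range(schedule.n_steps):
        f = _step_displacement((H, W), schedule.step_eps_xx[k],
                               schedule.step_eps_yy[k], schedule.nonuniformity)
        f.source_index, f.target_index = k, k + 1
        fields.append(f)
    return BeadSeries(stack, fields, positions, schedule)


# ---------------------------------------------------------------------------
# Cell label stacks
# ---------------------------------------------------------------------------

def _voronoi_polygons(seeds: np.ndarray, bounds: tuple[float, float, float, float]):
    """Bounded Voronoi cells of the seed points, as shapely polygons.

    Seeds are mirrored across the four sides of the bounding rectangle so
    every original region is finite, then clipped to the rectangle.
    """
    x0, y0, x1, y1 = bounds
    mirrored = [seeds]
    for pts in (
        np.column_stack([2 * x0 - seeds[:, 0], seeds[:, 1]]),
        np.column_stack([2 * x1 - seeds[:, 0], seeds[:, 1]]),
        np.column_stack([seeds[:, 0], 2 * y0 - seeds[:, 1]]),
        np.column_stack([seeds[:, 0], 2 * y1 - seeds[:, 1]]),
    ):
        mirrored.append(pts)
    vor = Voronoi(np.vstack(mirrored))
    rect = shp_box(x0, y0, x1, y1)
    polys = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise RuntimeError("degenerate tessellation")  # pragma: no cover
        poly = Polygon(vor.vertices[region]).intersection(rect)
        polys.append(poly)
    return polys


def _rasterize(poly: Polygon, label: int, canvas: np.ndarray) -> None:
    geoms = poly.geoms if poly.geom_type == "MultiPolygon" else [poly]
    for g in geoms:
        if g.is_empty or g.area < 1:
            continue
        xs, ys = np.asarray(g.exterior.coords).T
        rr, cc = draw_polygon(ys, xs, shape=canvas.shape)
        canvas[rr, cc] = label


@dataclass
class CellLabelSeries:
    """Synthetic tracked segmentation with ground-truth strains and fates."""

    labels: np.ndarray                    # (T, H, W) uint16
    truth_strains: pd.DataFrame           # label, t0, eps_xx_true
    truth_fates: dict[int, str]
    schedule: DeformationSchedule


def gen_cell_labels(
    n_cells: int = 81,
    image_size: tuple[int, int] = (400, 400),
    schedule: DeformationSchedule | None = None,
    cell_noise_sd: float = 0.0,
    division_rate: float = 0.0,
    exit_rate: float = 0.0,
    seed: int = 0,
    gap_px: float = 0.7,
) -> CellLabelSeries:
    """Voronoi tissue advected by a global schedule plus per-cell noise.

    The initial tissue is a jittered-grid Voronoi tessellation sized so
    that, after the full stretch, interior cells still fit inside the
    frame.  Each step every cell deforms with the global affine plus an
    extra axis stretch so its own step strain is eps_xx + eta with
    eta ~ N(0, cell_noise_sd); the per-cell truth is recorded.  Seeded
    divisions split a cell through its centroid into two new labels;
    seeded exits push a cell across the image border before it disappears.
    A small erosion (``gap_px``) leaves membrane-like background gaps
    between neighbouring cells.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    H, W = image_size
    schedule = schedule or DeformationSchedule.from_grip_displacement()
    rng = np.random.default_rng(seed)
    center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])

    # initial tissue extent chosen so stretched cells remain in frame
    cums_x = np.cumprod(1.0 + schedule.step_eps_xx)
    cums_y = np.cumprod(1.0 + schedule.step_eps_yy)
    grow_x = max(1.0, float(cums_x.max()))
    grow_y = max(1.0, float(cums_y.max()))
    hx = (W / 2.0 - 6.0) / grow_x
    hy = (H / 2.0 - 6.0) / grow_y
    bounds = (center[0] - hx, center[1] - hy, center[0] + hx, center[1] + hy)

    # jittered grid of seeds, aspect-matched to the tissue rectangle
    aspect = hx / hy
    ny = max(2, int(round(np.sqrt(n_cells / aspect))))
    nx = int(np.ceil(n_cells / ny))
    gx = np.linspace(bounds[0], bounds[2], nx + 1)
    gy = np.linspace(bounds[1], bounds[3], ny + 1)
    cx = (gx[:-1] + gx[1:]) / 2
    cy = (gy[:-1] + gy[1:]) / 2
    pitch_x, pitch_y = np.diff(gx).mean(), np.diff(gy).mean()
    pts = np.stack(np.meshgrid(cx, cy), axis=-1).reshape(-1, 2)[:n_cells]
    pts = pts + rng.uniform(-0.35, 0.35, pts.shape) * np.array([pitch_x, pitch_y])
    polys = _voronoi_polygons(pts, bounds)

    cells = {i + 1: polys[i] for i in range(n_cells)}   # label -> polygon
    fates = {lab: "complete" for lab in cells}
    next_label = n_cells + 1
    truth_rows = []
    frames = [np.zeros((H, W), dtype=np.uint16)]
    order = sorted(cells)
    for lab in order:
        _rasterize(cells[lab].buffer(-gap_px), lab, frames[0])

    for k in range(schedule.n_steps):
        eps_xx = schedule.step_eps_xx[k]
        eps_yy = schedule.step_eps_yy[k]
        new_cells = {}
        for lab in sorted(cells):
            poly = cells[lab]
            eta = rng.normal(0.0, cell_noise_sd) if cell_noise_sd > 0 else 0.0
            # global affine about the image center
            g = shp_affine(poly, [1 + eps_xx, 0, 0, 1 + eps_yy,
                                  center[0] * (-eps_xx), center[1] * (-eps_yy)])
            # extra axis stretch about the cell centroid -> step strain eps_xx+eta
            if eta != 0.0:
                f = (1 + eps_xx + eta) / (1 + eps_xx)
                cxc = g.centroid.x
                g = shp_affine(g, [f, 0, 0, 1, cxc * (1 - f), 0])
            new_cells[lab] = g
            truth_rows.append({"label": lab, "t0": k,
                               "eps_xx_true": eps_xx + eta})
        cells = new_cells

        # seeded divisions: split through the centroid at a random angle
        for lab in sorted(cells):
            if fates[lab] != "complete":
                continue
            if rng.random() < division_rate:
                poly = cells.pop(lab)
                ang = rng.uniform(0, np.pi)
                cxc, cyc = poly.centroid.x, poly.centroid.y
                d = 4 * max(W, H)
                cut = LineString([
                    (cxc - d * np.cos(ang), cyc - d * np.sin(ang)),
                    (cxc + d * np.cos(ang), cyc + d * np.sin(ang)),
                ])
                halves = [g for g in shp_split(poly, cut).geoms if g.area > 4]
                if len(halves) < 2:       # grazing cut; keep the parent
                    cells[lab] = poly
                    continue
                fates[lab] = "divided"
                for g in halves[:2]:
                    cells[next_label] = g
                    fates[next_label] = "appeared"  # offspring, never complete
                    next_label += 1

        # seeded exits: push the cell across the nearest x border, then drop it
        exiting = []
        for lab in sorted(cells):
            if fates[lab] == "complete" and rng.random() < exit_rate:
                exiting.append(lab)
        frame = np.zeros((H, W), dtype=np.uint16)
        for lab in sorted(cells):
            poly = cells[lab]
            if lab in exiting:
                minx, _, maxx, _ = poly.bounds
                shift = (W - (minx + maxx) / 2.0) if poly.centroid.x >= center[0] \
                    else -((minx + maxx) / 2.0)
                poly = shp_affine(poly, [1, 0, 0, 1, shift, 0])
            _rasterize(poly.buffer(-gap_px), lab, frame)
        frames.append(frame)
        for lab in exiting:
            del cells[lab]
            fates[lab] = "left_frame"

    truth = pd.DataFrame(truth_rows, columns=["label", "t0", "eps_xx_true"])
    return CellLabelSeries(np.stack(frames), truth, fates, schedule)


# ---------------------------------------------------------------------------
# Filaments
# ---------------------------------------------------------------------------

def gen_filaments(
    n: int = 200,
    length_range_px: tuple[float, float] = (20.0, 120.0),
    tortuosity_amp: float = 0.15,
    orientation_kappa: float = 1.0,
    seed: int = 0,
    n_points: int = 60,
    shape: str = "sinusoid",
    field_size: float = 400.0,
) -> list[FilamentTrace]:
    """Synthetic filament centerlines with controlled tortuosity.

    Chord orientations follow an axial von Mises law (kappa = 0 is
    uniform over [-90, 90)); ``shape='sinusoid'`` bends the centerline by
    a full sine period of relative amplitude ``tortuosity_amp`` (0 gives
    perfectly straight filaments); ``shape='semicircle'`` produces arcs
    whose straightness is exactly 2/pi in the continuum limit.
    """
    if n < 1:
        raise ValueError("need at least one filament")
    rng = np.random.default_rng(seed)
    traces = []
    t = np.linspace(0.0, 1.0, n_points)
    for i in range(n):
        chord = rng.uniform(*length_range_px)
        if orientation_kappa > 0:
            theta = 0.5 * rng.vonmises(0.0, 2 * orientation_kappa)
        else:
            theta = rng.uniform(-np.pi / 2, np.pi / 2)
        if shape == "sinusoid":
            bx = t * chord
            by = tortuosity_amp * chord * np.sin(2 * np.pi * t)
        elif shape == "semicircle":
            bx = (chord / 2.0) * (1.0 - np.cos(np.pi * t))
            by = (chord / 2.0) * np.sin(np.pi * t)
        elif shape == "line":
            bx, by = t * chord, np.zeros_like(t)
        else:
            raise ValueError("shape must be sinusoid, semicircle or line")
        c, s = np.cos(theta), np.sin(theta)
        x = bx * c - by * s
        y = bx * s + by * c
        start = rng.uniform(0.0, field_size, 2)
        pts = np.column_stack([x + start[0], y + start[1]])
        traces.append(FilamentTrace(pts, filament_id=i))
    return traces


def stretch_filaments(
    traces: list[FilamentTrace], eps_xx: float, nu: float = DEFAULT_NU
) -> list[FilamentTrace]:
    """Apply an affine uniaxial stretch to filament polylines."""
    out = []
    for tr in traces:
        pts = tr.points.copy()
        pts[:, 0] *= 1.0 + eps_xx
        pts[:, 1] *= 1.0 - nu * eps_xx
        out.append(FilamentTrace(pts, filament_id=tr.filament_id))
    return out


# ---------------------------------------------------------------------------
# Drifting z-stack acquisitions
# ---------------------------------------------------------------------------

@dataclass
class DriftingAcquisition:
    stacks: np.ndarray          # (T, Z, H, W)
    truth: pd.DataFrame         # t, cum_dx, cum_dy, z_focus


def _render_defocused_stack(
    positions: np.ndarray, z_focus: float, z_slices: int,
    shape: tuple[int, int], base_sigma: float, blur_slope: float,
    rng: np.random.Generator | None, noise_sd: float,
) -> np.ndarray:
    out = np.empty((z_slices,) + shape, dtype=np.float32)
    for z in range(z_slices):
        sigma = float(np.hypot(base_sigma, blur_slope * (z - z_focus)))
        img = _render_spots(shape, positions, sigma,
                            amplitude=base_sigma / sigma)
        if rng is not None and noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, shape)
        out[z] = img
    return out


def gen_drifting_acquisition(
    n_timepoints: int = 20,
    z_slices: int = 7,
    focus_drift: float = 0.0,
    xy_drift_per_step: tuple[float, float] = (3.0, -2.0),
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    n_beads: int = 150,
    base_sigma: float = 1.5,
    blur_slope: float = 1.2,
    noise_sd: float = 0.005,
) -> DriftingAcquisition:
    """Drifting, defocusing bead acquisition with ground-truth drifts.

    The in-focus plane sits at z_focus(t) = z0 + focus_drift * t (slices
    per timepoint, clipped to the stack); other slices blur with distance
    from focus.  The scene shifts by the cumulative xy drift each
    timepoint.
    """
    H, W = image_size
    rng = np.random.default_rng(seed)
    margin = 4 * base_sigma
    pos0 = np.column_stack([
        rng.uniform(margin, W - margin, n_beads),
        rng.uniform(margin, H - margin, n_beads),
    ])
    z0 = (z_slices - 1) / 2.0
    drift = np.asarray(xy_drift_per_step, dtype=float)
    stacks, rows = [], []
    for t in range(n_timepoints):
        cum = t * drift
        zf = float(np.clip(z0 + focus_drift * t, 0, z_slices - 1))
        stacks.append(_render_defocused_stack(
            pos0 + cum, zf, z_slices, (H, W), base_sigma, blur_slope,
            rng, noise_sd))
        rows.append({"t": t, "cum_dx": cum[0], "cum_dy": cum[1], "z_focus": zf})
    return DriftingAcquisition(np.stack(stacks), pd.DataFrame(rows))


def simulate_drift_correction(
    n_timepoints: int = 20,
    xy_drift_per_step: tuple[float, float] = (2.5, 1.5),
    z_slices: int = 5,
    focus_drift: float = 0.1,
    seed: int = 0,
    image_size: tuple[int, int] = (256, 256),
    n_beads: int = 150,
    base_sigma: float = 1.5,
    blur_slope: float = 1.2,
    noise_sd: float = 0.005,
    subpixel: bool = True,
) -> pd.DataFrame:
    """Closed-loop drift-correction simulation.

    Each cycle the virtual stage acquires a z-stack at its current
    position, the sharpest slice is referenced against the previous
    cycle's reference, and the compensating move is applied before the
    corrected reference is re-acquired.  Returns per-timepoint residual
    offsets (scene minus stage, pixels) after correction.
    """
    H, W = image_size
    rng = np.random.default_rng(seed)
    margin = 4 * base_sigma
    pos0 = np.column_stack([
        rng.uniform(margin, W - margin, n_beads),
        rng.uniform(margin, H - margin, n_beads),
    ])
    z0 = (z_slices - 1) / 2.0
    drift = np.asarray(xy_drift_per_step, dtype=float)
    stage = np.zeros(2)
    prev_ref = None
    rows = []
    for t in range(n_timepoints):
        true = t * drift
        zf = float(np.clip(z0 + focus_drift * t, 0, z_slices - 1))

        def acquire(offset):
            return _render_defocused_stack(
                pos0 + offset, zf, z_slices, (H, W), base_sigma,
                blur_slope, rng, noise_sd)

        zstack = acquire(true - stage)
        zi = sharpest_z(zstack)
        ref = zstack[zi]
        if prev_ref is not None:
            est = xy_drift(prev_ref, ref, subpixel=subpixel)
            mv = recenter_move(est, pixel_size=1.0)
            stage = stage - np.asarray(mv)
            ref = acquire(true - stage)[zi]
        residual = true - stage
        rows.append({"t": t, "z_index": zi, "residual_dx": residual[0],
                     "residual_dy": residual[1],
                     "residual": float(np.hypot(*residual))})
        prev_ref = ref
    return pd.DataFrame(rows)
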