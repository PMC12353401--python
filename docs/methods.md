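# Methods

This note documents the models, conventions, parameters and design
choices behind `stretchlab`, and what the synthetic-data validation does
and does not demonstrate about real microscope data.

## Coordinates, signs, units

Pixel indices are 0-based; x is the column index and coincides with the
stretch axis, y is the row index.  Elongation along an axis is positive
strain.  Strains are dimensionless fractions (a percentage only ever
appears in report text), strain rates are min⁻¹, on-disk lengths are
pixels with the micrometre-per-pixel size recorded alongside, and angles
are degrees measured from +x.

## Strain algebra

Engineering strain of a length change is (l − l₀)/l₀; true (logarithmic)
strain is ln(l/l₀).  Step strains — between consecutive frames — are
composed into a cumulative strain by converting to true strain, summing,
and converting back: ε_cum = exp(Σ ln(1 + ε_i)) − 1 = Π(1 + ε_i) − 1.
This is exactly path-consistent: splitting a stretch into sub-steps never
changes the composed total, which is why consecutive-pair registration
(small, tractable displacements) can recover arbitrarily large cumulative
strains.  `log1p`/`expm1` keep the composition accurate for small steps.
Any step ≤ −1 is a domain error (the material would be annihilated);
scalar composition raises, while pixelwise composition of *estimated*
fields instead invalidates the offending pixels with a warning, because
isolated nonphysical outliers near the frame edge are an estimator
artifact, not a reason to abort an entire map.

Cumulative pixelwise accumulation is **Eulerian**: each pixel composes the
step strains observed at its own coordinates on translation
pre-registered frames.  This matches what an image-macro pipeline
computes but is an approximation wherever material points traverse strain
gradients; Lagrangian material-point tracking is deliberately out of
scope.  On spatially uniform stretches the two coincide.

### Displacement → strain

At each pixel, a least-squares plane a + b·Δx + c·Δy is fitted to u and
to v over a window (default 3 × 3); the slopes give ε_xx = ∂u/∂x,
ε_yy = ∂v/∂y, ε_xy = ½(∂u/∂y + ∂v/∂x).  The plane fit equals smoothed
central differences on full interior windows and reproduces the gradient
of *any* affine displacement exactly, whatever the validity mask, which
makes affine fields an exact oracle for this operator.  The window
scheme was a free choice (only the 3 × 3 subarray size is conventional);
the plane fit was picked because it degrades gracefully at boundaries.
Boundary policy: by default the window shrinks to its in-image, valid
subset (at least 4 pixels and a non-singular normal matrix, otherwise the
pixel is invalid); a strict mode marks border pixels invalid instead.

### Box statistics

Strain uniformity is summarized over non-overlapping b × b tiles
(default 20 px, giving 400 tiles on a 400 × 400 field).  Partial edge
tiles are dropped with a logged warning rather than padded, keeping the
per-tile sample size constant.  The global figure is the mean ± SD over
tile means; with exact tiling the mean of tile means equals the global
mean.

## Displacement estimation

External B-spline registration engines are deliberately not
re-implemented; their raw pixel-by-pixel displacement exports can be
loaded directly (`width height` header, u block, v block).  The bundled
estimator is classical block matching:

* Gaussian pyramid, coarse to fine (default 3 levels).  The full search
  radius (default 16 px) applies at the coarsest level — an effective
  reach of radius × 2^(levels−1) ≈ 64 px at full resolution — while finer
  levels search ±3 px around the upsampled prior.
* Normalized cross-correlation of block templates (default 32 px every
  8 px); the peak is refined by independent 1D parabola fits in x and y.
  Ties break toward the smaller displacement magnitude.
* Matches with peak correlation below 0.3 are discarded and in-filled
  from the nearest valid node; node values are bilinearly densified and
  Gaussian-smoothed (default σ = 4 px).  Pixel validity reports whether
  the nearest match node was accepted.  If no node anywhere passes the
  threshold the input is rejected as textureless.

Consecutive frames are always registered pairwise; per-step displacements
stay within the search reach even when the cumulative stretch exceeds
100%.  Translation pre-registration uses FFT cross-correlation (exact for
integer circular shifts, upsampled-DFT subpixel refinement otherwise),
accumulating per-pair shifts so every frame aligns to the first;
out-of-frame pixels become NaN and are masked downstream.

## Drift correction

The correction loop models a stage-top acquisition where large substrate
displacements drag the field of view.  Per timepoint: (1) the sharpest
slice of the z search range is selected — variance-of-Laplacian by
default, Tenengrad selectable; the functional was a free choice, made
because both are standard and monotone with defocus blur on bead-like
images; ties resolve to the lowest slice with a warning.  (2) xy drift is
the deviation of the brightest pixel of ifft(F(prev)·conj(F(now))) from
the image center after center-shifting.  The raw conjugate product is the
default; spectral magnitude normalization (true phase correlation) is a
flag.  The estimate is exact for integer circular shifts and antisymmetric
under frame exchange; drifts beyond a quarter frame are flagged since the
fftshift convention is ambiguous beyond half a frame.  (3) The stage move
is the negated drift in micrometres.  The closed-loop simulator
(`simulate_drift_correction`) verifies that per-cycle residuals stay
below 1 px over ≥ 20 cycles under combined xy and focus drift.

## Per-cell strain

Cells arrive as persistent-label images from an external segmenter.  The
per-cell strain definition was the major interpretive choice in this
package: cell step strain along x is the stretch ratio of the mask's
second central moment, √(M_xx(t₁)/M_xx(t₀)) − 1.  For any axis-aligned
affine deformation of the mask this is exact (second moments scale with
the square of the stretch), it needs no landmark correspondence, and
boundary pixelation enters only at second order.  Degenerate moments
(1-px-wide masks) are errors.

Fates: a track is *complete* iff present at every timepoint and never
divided.  A label that disappears is *divided* when ≥ 2 labels new in the
next frame cover ≥ 60% of its last mask (threshold configurable —
invented, there is no conventional value); *left_frame* when its last
mask touched the image border; otherwise *lost*.  Mid-series entrants
(e.g. division offspring) are *appeared*.  Only complete tracks enter the
analysis, mirroring standard practice of excluding dividing and exiting
cells whose shape changes do not reflect the applied stretch.  Note the
coverage test compares consecutive frames without motion compensation, so
a dividing cell that also translates far between frames may be excluded
as *lost* rather than *divided* — the exclusion itself is unaffected.

Tissue strain under a cell is the mean of valid strain-field pixels under
the cell's mask in the *earlier* frame of the interval, consistent with
step-strain semantics (the strain field maps frame t₀ coordinates).

## Concordance

For each cell-step, d = ε_C − ε_T and a movement statistic s.  Two
readings of s exist in the field's usage and both are implemented:
|ε_C + ε_T| (default) and |ε_C| + |ε_T|; results record which was used,
and thresholds estimated under one variant cannot silently classify under
the other.  Thresholds are 1 sample SD of d and of s, estimated from the
data or supplied by the user.  Classification: grey (insignificant
movement, s ≤ σ_s) takes precedence; then yellow (|d| ≤ σ_d), magenta
(d > σ_d), cyan (d < −σ_d).  Categories are exhaustive and mutually
exclusive; records with missing strains are skipped and tallied.

A validation subtlety: on a *noise-free* affine tissue the data-derived
σ_d collapses to the discretization scale, and for any roughly normal
residual about 68% of records land within ±1 SD — by construction, not by
failure.  The zero-noise concordance check therefore classifies against
fixed reference tolerances (σ_d = 0.057, σ_s = 0.081, the magnitudes
reported for real epithelial tissue) rather than against degenerate
data-derived ones.

## Filament metrics

Straightness is tip-to-tip distance over arc length, in (0, 1]; it is
invariant under rigid motion and uniform scaling, equals 1 exactly for
collinear polylines and 2/π for semicircular arcs.  Closed loops return 0
with a warning.  Orientation uses the tip-to-tip chord (matching the
straightness tip convention; PCA major axis available by flag), folded
into [−90°, +90°) — vertical maps to −90°.  The 20-px minimum length
filter is inclusive at the bound and filters on *arc length*, not chord.
Orientation histograms default to 18 bins of 10°; before/after
distributions are compared with a Pearson chi-square homogeneity test on
the 2 × K table (df = K − 1, no continuity correction); zero-expected
bins raise with advice to merge.

## Synthetic generators — what they emulate, what they don't

All generators are deterministic given their seed.  Deformations are
applied about the image center with lateral contraction ratio ν
(default 0.27, the approximate |ε_yy/ε_xx| of a uniaxially stretched
elastomer substrate at mid-protocol); an optional linear strain ramp
across x stands in for grip-thinning nonuniformity phenomenologically —
no substrate hyperelasticity is modelled.

* **Beads** (`gen_bead_series`): uniformly placed Gaussian spots (spot σ
  combines bead radius and PSF in quadrature), forward-advected each
  step, with Gaussian read noise.  Defaults — 400 × 400 px, 800 beads,
  8 steps — match the scale of substrate-validation imagery.  The
  per-step analytic displacement fields satisfy the strain operator
  exactly, giving a machine-precision oracle.
* **Cell tissues** (`gen_cell_labels`): a jittered-grid Voronoi
  tessellation (81 cells by default, the scale of a tracked epithelial
  patch over 8 stretch steps), sized so interior cells remain in frame
  after the full stretch.  Per-cell heterogeneity is *additive in
  strain*: cell step strain = global ε_xx + η, η ~ N(0, σ_c), applied as
  an extra axis stretch about the cell centroid, so the recovered SD is
  directly comparable to σ_c.  Divisions split a polygon through its
  centroid at a random angle; exits translate a cell across the border
  before removal.  A 0.7-px erosion leaves membrane-like gaps.  Real
  segmentations additionally contain boundary errors, label swaps and
  non-affine cell shape change — passing here shows the estimator and
  bookkeeping are correct, not that segmentation noise is harmless.
* **Filaments** (`gen_filaments`): sinusoidal tortuosity of relative
  amplitude A on a straight chord (A = 0 gives straightness exactly 1),
  axial von Mises chord orientations (κ = 0 uniform), semicircle and line
  templates for closed-form checks.
* **Acquisitions** (`gen_drifting_acquisition`): the in-focus bead plane
  blurred by |z − z_focus(t)| × slope with amplitude conservation,
  shifted by cumulative xy drift.

The bundled validations demonstrate recovery under these idealized
conditions — Gaussian optics, conservative intensity, no bleaching, no
out-of-plane motion, affine or mildly heterogeneous deformation.  They
bound algorithmic error, not biological or optical confounds.

## Numerical choices and degenerate inputs

* Engineering→true conversion rejects ε ≤ −1; round trips hold to 1e−12
  over (−0.99, 10].
* Plane-fit normal matrices with |det| ≤ 1e−9 or fewer than 4 masked
  pixels mark the pixel invalid rather than solving an ill-posed system.
* Parabola refinements only apply at interior peaks with strictly
  negative curvature.
* Blank frames (zero variance) yield zero shift/drift with a warning
  instead of an error, so a single failed exposure does not abort a
  series; fully textureless displacement estimation *is* an error, since
  a dense field would be pure invention.
* Box sizes, windows and blocks larger than the image raise immediately.

## Problem sizes used in validation

The bundled tests run the full chain at 256–512 px images, 8 deformation
steps, 36–81 cells, 200–1000 filaments and 20 drift-correction cycles —
sizes chosen to exercise every code path at the same parameter settings
as the emulated experiments while remaining comfortable on a laptop-class
single core.

## Known limitations

* Eulerian accumulation biases cumulative maps where strain gradients and
  displacements are both large (see above).
* The block matcher assumes locally translational motion within a block;
  strong rotation or shear inside one block degrades matches before the
  correlation threshold catches them.
* Division detection has no motion model (see per-cell strain).
* Concordance thresholds assume the 1-SD convention; heavy-tailed strain
  distributions would motivate robust scale estimates instead.
* The drift estimator reports a single global translation; it cannot
  separate stage drift from genuine tissue translation within the field.
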