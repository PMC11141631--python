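# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `nemaflow`.  It is written for users who need to know
exactly what each number means, not just how to compute it.

## Angle and coordinate conventions

All angles are in degrees, measured counter-clockwise from the image
x-axis (columns) with the y-axis pointing up; the array row axis therefore
points along −y, and a direction θ corresponds to the array step
(drow, dcol) = (−sin θ, cos θ).  Nematic (axial) quantities live in
(−90°, 90°] and are closed under θ → θ + 180°; directional quantities
(migration steps, flow vectors) live in (−180°, 180°].  The substrate
director is assumed pre-registered to 0°, i.e. images are rotated before
analysis so the stiff axis is horizontal.

## Orientation extraction (structure tensor)

Gradients are Gaussian derivatives at scale `sigma_gradient` (default
1 px; the choice is not critical and is deliberately small so resolution
is set by the window).  The tensor products are smoothed with an isotropic
Gaussian window `sigma_window` — 10 or 20 px for cell-scale texture at
10× / 20× magnification, 1–2 px for ECM fibrils.  The reported angle is
the eigenvector of the **smaller** eigenvalue (the structure direction,
perpendicular to the dominant gradient); this convention is locked by a
stripe-recovery test, since published descriptions of the reference tool
do not restate it.  Coherency is (λmax − λmin)/(λmax + λmin), set to 0
where the tensor trace vanishes (within 1e−12 of the image maximum);
masked pixels carry no angle.  Histograms over pixel maps exclude a border
of 2·sigma (incomplete gradient support).

Grid sampling takes one vector per complete `grid_size` cell (100 or 50 px
for field-scale statistics, 5 px for defect detection): the
coherency-weighted mean of the doubled angles, masked when the cell's mean
coherency falls below the 25% gate.

The single-cell morphology helper thresholds with Otsu's method and fits
second-moment ellipses; the source experiments state only "thresholded and
segmented", so Otsu is this package's choice.

## Order parameter and spatial disorder

S = |⟨2 cos²(θ − θ̄) − 1⟩| equals the doubled-angle resultant length
|⟨e^{2iθ}⟩|.  "Mean of all angles" is interpreted as the doubled-angle
circular mean: arithmetic means of axial angles are ill-defined at the
±90° wrap, and with this choice S is reference-consistent and matches the
standard 2D nematic order parameter.  The average is unweighted — vectors
are already coherency-gated upstream.  Numerically the resultant is
computed relative to the first angle so a perfectly uniform field returns
exactly 1.0.

Local order applies the same statistic to sliding 4×4 windows of grid
vectors (stride 1, windows fully inside the lattice; border-incomplete
windows are dropped, not padded; windows with fewer than two unmasked
vectors are undefined).  Spatial disorder is the percentage of defined
windows with S < 0.5.  At the default 100 px grid these windows span
roughly 50 × 50 µm regions at typical calibrations.

## Autocorrelation and correlation length

C(d) = 2⟨cos²(θ(r) − θ(r+d))⟩ − 1 is averaged over all unordered pairs of
unmasked grid points **at the same separation distance**; masked vectors
are excluded pairwise, never imputed.  On a square lattice the exact
distance classes are √k for integer squared offsets k (0, 1, √2, 2, √5,
…), so pairs are grouped exactly by integer squared distance — no binning
error, and C at one grid step on a 0°/90° checkerboard is −1 exactly.
C(0) = 1 by construction (self pairs).

ξ is the x-intercept −b/a of an ordinary least-squares line C ≈ a·d + b
through the first 10 distance classes, converted to pixels by the grid
spacing and to µm by the pixel size.  Degenerate cases are clamped to the
maximum sampled distance and flagged: non-negative slope (e.g. a uniform
field with C ≡ 1), a non-positive intercept, or an intercept beyond the
sampled range when the fit used only a truncation of a longer curve.  A
fit that consumes the entire curve is allowed to extrapolate past its last
point — with no samples at larger distances there is no evidence against
the line.

Because the first 10 exact classes span only ~3.6 grid steps, ξ for an
uncorrelated field comes out near 3 grid steps (the intercept of a line
through a delta-at-zero curve), not 1; what matters downstream is that ξ
is exactly reproducible against a brute-force oracle and strictly
monotone in the true field correlation, both of which are enforced by
tests.

## PIV

Displacements are estimated per interrogation window by zero-padded linear
cross-correlation of zero-mean windows, computed by FFT and divided by the
per-lag overlap area.  The overlap normalization matters: raw linear (or
circular) correlation implicitly triangle-weights the lags and biases
every estimate toward zero by a few hundredths of a pixel; with the
normalization the measured bias on speckle textures is below 0.01 px.
The peak is searched within a third of the window, refined by a 3-point
Gaussian fit per axis (parabolic fallback when a lobe is non-positive),
and validated by the ratio of the highest to the second-highest
correlation peak (minimum 1.2).  A single 3×3 median pass smooths the
vector lattice — the reference software's "lowest smoothing setting" has
no published formula, so this stand-in is validated purely through
known-flow recovery.

Multipass chains decreasing windows (default 600/300, 300/150, 150/75 px
window/step), interpolating each pass's displacements onto the next grid
as integer predictors; windows are shift-only (no deformation), justified
because collective cell flows are slow relative to the window sizes.
Invalid vectors are filled from the median of valid neighbours before
prediction.  Output is calibrated to µm/h and the outermost vector ring is
flagged invalid — an automated stand-in for the manual rejection of
frame-boundary artifacts, which is not reproducible by hand.  Frames
corrupted by stage shifts after medium changes are removed by an explicit
`artifact_frames` list rather than by mean-velocity subtraction, which
would be wrong for polarized flows.

ξ_vv reuses the nematic autocorrelation machinery verbatim on flow angles
wrapped to (−90°, 90°]: antiparallel flow is treated as correlated, which
is the documented behaviour of the original analysis.  A signed-vector
variant (C(d) = ⟨v̂·v̂⟩) is provided for comparison but is not the default.

## Tracking and migration

Nuclei are detected by Laplacian-of-Gaussian blobs (σ range derived from
the physical gate), gated to equivalent diameters strictly between 6 and
30 µm, and refined by intensity-weighted centroids.  This is a classical
stand-in for a trained detector; all track-level functions equally accept
externally produced track tables (TrackMate-style exports), so the
detector is swappable.

Linking is greedy mutual nearest neighbour with a maximum displacement
gate, ties broken by distance then index, no gap closing, merging or
splitting.  The reference tracker's "default settings" are unspecified, so
correctness is defined on non-crossing fixtures, where recovery is
complete.

Cell density is counts over field area (cells/mm²).  Replicate time axes
are aligned by smoothing density with a centered 3-point moving average
and shifting so the maximum sits at t_a = 36 h (confluence then lands near
t_a = 0 h); flat or still-rising series are flagged.  The returned offset
should be applied to all companion series (order, disorder, speed, ξ_vv).

Migration steps are consecutive in-track displacements; speed is
displacement over the frame interval, direction is atan2 in the full
circle.  The **normalized directional migration** folds step directions
onto the nematic range (movement toward either end of the director axis
counts as aligned), histograms them in 10° bins — 18 bins across 180° —
and divides the summed frequency of the two bins flanking 0° by the
isotropic expectation 2/18 = 11.111%.  The ratio is 1 for isotropic
migration and 9 at full alignment.  Speed- or ratio-versus-density curves
average per-replicate linear interpolations on a 10 cells/mm² lattice with
equal replicate weight, each replicate contributing only inside its own
density range.

Division axes are consumed as annotated nucleus-pair coordinates (no
mitosis detector), folded to the nematic range and binned at 20°; a
vertical pair lands in the (70°, 90°] bin.

## Defect detection and LIC

The winding number along a closed counter-clockwise loop of grid points is
the sum of consecutive nematic angle differences, each mapped to
(−90°, 90°], divided by 360°.  Detection evaluates square loops of side
`tensor_size` (default 20 grid units) centered on every interior grid
point; centers whose winding rounds to ±1/2 with residual ≤ 0.1 are
candidates (larger residuals are treated as noise and discarded).
Same-sign candidates closer than `min_dist` (default 30 grid units) merge
into one defect at a residual-weighted centroid — every loop enclosing a
core detects it, so candidates form a compact cloud whose centroid sits on
the core.  If opposite-sign detections remain within `min_dist`, the
cleaner winding wins.  The loop geometry is this package's choice (the
referenced detector's loop is undocumented); charge conservation against
the boundary winding and analytic fixtures define correctness.  Fields for
defect detection should be sampled finely (σ = 10 px, grid 5 px).

LIC rendering averages a seeded white-noise texture along director
streamlines, 20 unit steps in each direction with the nematic sign
ambiguity resolved by continuity (each step keeps the orientation vector
on the same side as the previous step).  A second pass may reuse the first
output as its seed texture.  Contrast is enhanced by rank-based histogram
equalization raised to power 1.5, scaled to uint8.

## Watson–Wheeler test

Axial samples are doubled onto the circle (a flag disables this), pooled
and circularly ranked; with uniform scores β = 2πr/N the statistic
W = Σ 2(C_i² + S_i²)/n_i is referred to χ² with 2(k−1) degrees of freedom.
The large-sample approximation is used throughout; groups below 10
observations are rejected rather than approximated, since orientation
fields supply thousands of angles.  Exact rank ties are broken by a tiny
seeded uniform jitter (±1e−6°), and the result records the seed and
whether jitter fired.  Calibration (type-I error 5%, uniform null
p-values) is enforced by simulation tests.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical* structure the analysis assumes,
not the appearance of micrographs:

* `gen_correlated_field` smooths two unit-variance noise fields in the
  doubled-angle plane (periodic boundaries, so the field is stationary)
  and takes half the argument.  This guarantees valid nematic angles and a
  correlation length monotone in the smoothing scale; the ξ ↔ scale map is
  empirical, not analytic.
* `gen_defect_field` is the analytic defect solution
  θ = Σ k_i·atan2(y − y_i, x − x_i) + θ0.
* `gen_filament_image` scatters anti-aliased segments at the local field
  angle plus 3° Gaussian jitter — below the structure-tensor recovery
  tolerance, so texture error does not limit the pipeline tests.
* `gen_displaced_pair` uses exact Fourier shifts for constant flows and
  cubic-spline backward warping for varying flows.
* `gen_growth_tracks` combines deterministic logistic growth to a carrying
  capacity (default 4000 cells/mm², the plateau density of confluent
  myoblast cultures), a persistent random walk whose heading is drawn from
  a von Mises law combining the previous heading (weight `persistence`)
  and the 0° director (weight `bias`; infinite bias short-circuits to
  exactly 0°), linear speed decay with density (to 40% at capacity),
  excluded-volume seeding (15 µm dart throwing) and daughters placed one
  exclusion radius from parents.  Nuclei render as 4 µm-σ Gaussian spots.

Defaults (speed 15 µm/h, persistence 0.5, frame interval 1 h) are
plausible for proliferating myoblasts but are conveniences for testing,
not claims about any particular cell line; the real experiments publish
only summary statistics, not generative parameters.  Consequently, passing
tests demonstrate that the *measurement chain* is correct on data with
known ground truth — they do not validate biological conclusions, and the
generators omit fusion/myotube morphology, mechanical substrate coupling,
crowding during migration (excluded volume holds only at seeding/birth)
and imaging noise.

## Problem sizes in tests

The test and acceptance workloads are sized for quick, deterministic runs:
order-statistics oracles on 12–20 grid fields (20 seeds), ξ recovery on
40×40 fields (20 seeds × 3 scales), PIV on 256² speckle images with 64 px
windows, defect sweeps on 120² lattices (20 random configurations),
tracking on 512² movies of 100–150 cells, and 1000 null simulations for
test calibration.  The full suite runs in well under a minute of compute
on one core.

## Known limitations

* The structure tensor is not bit-compatible with any specific ImageJ
  plugin build; equivalence is functional (stripe and rotation tests).
* Exact distance classes make the first 10 autocorrelation points span
  only ~3.6 grid steps; ξ is an extrapolated intercept and should be
  compared across conditions measured the same way.
* The LoG detector undercounts touching nuclei; at near-confluent
  densities the tracking statistics degrade gracefully but are no longer
  complete.
* No window deformation in PIV: strong shear within a single window
  (>~1/4 window per frame) will bias estimates.
* Defect detection reports static snapshots; there is no tracking of
  defects through time.
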