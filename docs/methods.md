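# Methods

This note describes the models and numerical choices behind `epidose`:
what the dose-reconstruction pipeline computes, what the synthetic
generator emulates (and does not), and where the design was genuinely
open.

## Geometry and ray tracing

The beam frame is defined in CT coordinates (mm): the gantry rotates
about the patient's longitudinal axis; at gantry 0 the source sits above
the isocenter and the beam travels downward to the imager. The imager
grid (default 384 x 512 pixels) projects to 20.1 x 26.8 cm^2 in the
isocenter plane (SAD 100 cm, SDD 150 cm), pixel-centre convention, with
the centre of the grid on the central axis. The collimator angle rotates
the imager axes about the beam axis; edge-search directions rotate with
it.

Radiological depths are line integrals of relative electron density
along each source-to-pixel ray, computed with an exact Siddon-type
voxel traversal (numba-compiled) and split exactly at the plane through
the isocenter perpendicular to the central axis. The split defines

* `w_ij = t_up + t_down` — total radiological thickness of the ray, and
* `d_ij = (t_down − t_up) / 2` — signed midplane offset, so that the
  radiological depth of the isocenter plane equals `w_ij/2 − d_ij`
  identically. Positive `d` means the material sits displaced toward
  the detector.

The half-difference convention is forced by that identity: a literal
difference of the two depths would double the shift that the TMR ratio
is supposed to undo.

HU-to-density conversion is piecewise linear through a calibration
table, clamped outside it. The built-in table (−1000 → 0.0, 0 → 1.0,
1000 → 1.6) is a placeholder with the right general shape; clinical use
requires the scanner's own curve, supplied as a two-column CSV.

## Commissioning model

* `F_CAX(w, l)`: mean signal over the central 20 x 20 pixel block
  divided by the mean planned dose over the same block, on centered
  slabs of thickness `w` ∈ {6, 12, 16, 20, 26} cm and square fields
  `l` ∈ {5, 7.5, 10, 12.5, 15, 17.5, 20} cm. For even-sized grids the
  central block is placed with lower-index bias (rows 182–201, columns
  246–265 on the default grid).
* `f(d, l)`: CAX signal of the centered slab divided by the displaced
  one, `d` from −10 to +10 cm in 2.5 cm steps (9 values including 0) on
  the thickest slab, for `l` ∈ {5, 10, 15, 20} cm. `f(0, l) = 1` by
  construction and the table validates it. `f` is treated as constant
  off-axis.
* Both grids are interpolated with cubic tensor splines through the
  measurement nodes (node queries reproduce the measurements to
  ~1e-12). Queries outside the commissioned ranges raise — the data
  give no basis for extrapolation.
* Edge curves `k(x; l)`: the field edge is the locus where the image
  equals half of (CAX signal + background), background being the mean
  of four 20 x 20 corner blocks. The per-pixel ratio map `F_ij`,
  normalized by `F_CAX`, is averaged over 20 cross-plane subprofiles
  centred on the CAX row, each the 53 in-field pixels nearest that
  row's right-edge crossing (2.76 cm projected at the default pitch).
  Curves are stored per field size `l` ∈ {5, 10, 15} cm from the 12 cm
  slab only: the edge behaviour is insensitive to thickness but not to
  field size, so reconstruction picks the nearest commissioned `l`
  (ties toward the smaller field) and drops the `w` dependence.
  Between samples `k` is linearly interpolated; beyond 2.76 cm it is
  exactly 1, the span containing essentially all of the variability.
  Each curve must end within 1% of 1 — a curve that does not settle
  indicates a detection or normalization failure and is rejected.

## Reconstruction

Homogeneous centered slabs: `D = S / (F_CAX(w, l) k(x; l) k(y; l))`
inside the detected field, zero outside. The general case multiplies by
`TMR(w_ij/2 − d_ij)/TMR(w_ij/2)` (CAX TMR values, bilinear in depth and
field size — off-axis TMR differences are at the 1–2% level and are
neglected) and by `f(d_ij, l)`, and queries `F_CAX` at the per-pixel
`w_ij`. Distances `x`, `y` are from pixel centres to the subpixel
half-maximum crossings of the pixel's row and column; only those two
edges are corrected. The equivalent square of an irregular field is
Sterling's `l = 4A/P`, with the area from the in-field pixel count and
the perimeter from the mask's marching-squares contour smoothed with a
5-point moving average — raw pixel contours overestimate curved
perimeters by ~6% (staircase effect); the smoothing brings squares,
rectangles and disks all within ~1%. Below an equivalent square of
about 5.5 cm the two nearest edges interact and a warning is emitted.

Known blind spot: at field corners both `x` and `y` are small and the
detected per-row/per-column crossings are themselves shifted by the
orthogonal penumbra, so the separable correction over-corrects. On
synthetic round trips the error exceeds 1% only within ~1.5 cm of both
edges simultaneously; gamma at 3%/3 mm absorbs it. Diagonal edges of
irregular apertures are likewise uncorrected — a structural limitation
shared with the correction's definition.

## Gamma evaluation

`γ(r) = min over r' of sqrt(|r−r'|²/dta² + (D_e(r′)−D_r(r))²/(dd·D_max)²)`
with dd = 3% of the **global** reference maximum and dta = 3 mm. The
evaluated map is upsampled 3x by separable bilinear interpolation; the
search visits candidate offsets within 3 x dta in order of increasing
spatial penalty and stops once no remaining pixel can improve, which
makes full-resolution maps cheap while an exhaustive brute-force search
(same upsampling, no radius cut) pins correctness to 1e-6 in tests.
Pass rate is the fraction of in-mask pixels with γ < 1; the acceptance
threshold is >95%.

## Synthetic generator

The generator emulates the physical structure the method relies on,
with closed-form ground truth:

* signal `S = s0 · exp(−μ_eff w_ij) · horn · P_x P_y · (1 + g·d_ij)`
  with μ_eff = 0.05 cm⁻¹, an off-axis horn of +3% at 10 cm, separable
  error-function penumbras of width σ_signal = 0.35 cm, and a
  displacement scatter response `g = 3e-4 · (l/10)` per cm — giving
  `f` deviations of ~0.6% at d = 10 cm for the largest field, the
  magnitude a well-behaved imager shows. Noise is multiplicative
  Gaussian, 0.2% SD, always seeded.
* dose `D = d0 · TMR(w_ij/2 − d_ij) · horn · P_x P_y` with a parametric
  TMR (buildup to 1 at 1.5 cm, exponential slope 0.045 cm⁻¹ at 10 cm
  with a mild field-size dependence) and a **wider** penumbra
  σ_dose = 0.55 cm. The ordering σ_dose > σ_signal is what creates the
  near-edge rise of S/D that the k curves must capture; the implied
  true curve is the ratio of the two normalized edge profiles.
* phantoms: water slabs and two-thickness steps voxelized with faces on
  voxel edges (so digitized thicknesses are exact); an elliptic "head"
  cylinder with a bone shell; a "thorax" with two lung ellipsoids at
  relative electron density 0.25. An optional lateral-disequilibrium
  term reduces the *planned* dose by a set fraction (default test value
  8%) where the ray crosses the isocenter plane in lung — the signal
  model deliberately ignores it, so the reconstruction overestimates
  lung dose, reproducing the method's real failure mode in thorax
  fields.

What the generator does **not** emulate: spectral beam hardening and
detector energy response (their net effect is folded into the empirical
edge curves, which is exactly how the method treats them), ghosting,
imager-arm backscatter, MU nonlinearity, leftover-cine-frame loss, and
scatter transport beyond the displacement factor. Passing round trips
therefore validate the pipeline's internal consistency and its
geometric/interpolation machinery, not the physics of a particular
accelerator — on real equipment every table must be measured anew.

## Problem sizes and tolerances

Tests and the acceptance script run at the full 384 x 512 imager
resolution for commissioning and reconstruction; CT phantoms use 4 mm
(2 mm through slabs) voxels, which keeps a full anthropomorphic field
under a second of ray tracing. Oracle comparisons use 32³ spatially
smoothed random volumes (piecewise-constant white noise would be
dominated by the midpoint rule's own boundary error rather than the
traversal's). Numerical tolerances: commissioning-node reproduction
1e-12 relative; parameter recovery 0.2% (F_CAX), 0.3% (f), 1% (k)
noise-free; round-trip dose 1% away from edges and corners; gamma
oracle 1e-6.
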