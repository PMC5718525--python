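# Methods

This note documents the models behind `gammagel`, the parameters that matter,
the numerical choices, and what the synthetic phantom does and does not
emulate.

## Coordinate conventions

All public coordinates are millimetres in the Leksell stereotactic frame,
axis order (X, Y, Z). Grids follow a voxel-centre convention: `data[i, j, k]`
sits at `origin + index * spacing`, and all mm bounds (subvolume boxes,
extents) are inclusive of both endpoints. Planes are grids with one singleton
axis, so every 3D operation doubles as the 2D film path. Missing data is NaN
and propagates through resampling and every comparison statistic; no
statistic ever imputes a value.

## Synthetic dose model

The generator is deliberately *plumbing*, not a beam model: it produces
fields with the qualitative features the analysis pipeline must handle —
a single maximum per shot, monotone falloff, realistic penumbra widths, and
one-sided falloff from plugging — while remaining analytic, so it can serve
as its own interpolation oracle.

**Shot kernel.** Each shot contributes a separable product of 1D flat-top
profiles, the classic slit-convolved-Gaussian shape
`q(u) = ½[erf((R−u)/√2σ) + erf((R+u)/√2σ)] / q(0)`, with half-maximum at
R = FWHM/2. The in-plane FWHM equals the nominal collimator size
(4/8/14/18 mm); the Z FWHM is 1.3× that, reflecting the elongation of a
multi-source focal spot. The penumbra parameter grows mildly with collimator
size, σ = 1.0 + 0.08·FWHM mm (≈ 1.6 mm for the 8 mm shot, ≈ 2.4 mm for the
18 mm shot), giving 20–80% penumbras in the 2.7–4 mm range typical of
measured focal profiles.

**Plugging.** Tungsten plugs block a subset of the ~200 convergent beams,
lowering dose on the blocked side. The model multiplies each shot's kernel by
an azimuthal wedge transmission about the shot axis. Because the remaining
beams cross-fire through the focus, a plug shadow is diffuse rather than
sharp; the wedge therefore has raised-cosine angular edges (30°) and blends
radially to the azimuthal mean over the first 8 mm from the axis, keeping the
field C¹-smooth everywhere. The shipped plan fixture maps the recorded plug
*counts* (45/21/46 of 201) to wedge widths of 360°·count/201 facing the
organ-at-risk side with 0.2 residual transmission; the actual plug positions
of the emulated study were not recorded, so the wedge geometry is a stand-in,
not a reconstruction.

**Prescription scale.** `generate_calculated_dose` rescales the sampled grid
so that `prescription_isodose × max = prescription_dose` (8 Gy at 50% →
16 Gy), the way a planning system pins absolute dose to the prescription.
Because a coarse export lattice misses the true peak, two independently
normalised samplings of the same plan would disagree by a fraction of a
percent in absolute scale; virtual measurements therefore use
`generate_delivered_dose`, which samples the *same* continuous field on the
measurement lattice at the reference grid's scale. A fine measurement can
then slightly exceed the export grid's nominal maximum — exactly as a
physical detector can. On the raw (unnormalised) field, adding a plug sector
can only ever lower dose; after prescription rescaling, open-sector dose may
rise, as renormalising a plan does in practice.

**Default geometries.** TPS-style export: 2.5 mm isotropic over a 140 mm
cube enclosing the 16 cm phantom's treated region. Gel readout: 0.5 × 0.5 mm
in-plane, 2 mm slices, covering the analysis subvolume with margin. Common
comparison grid: 1 mm isotropic over X 70–115, Y 65–125, Z 90–114 mm
(46 × 61 × 25 voxels).

## Virtual measurements

`simulate_measured_dose` applies, in order: Gaussian blur (FWHM in mm, off by
default), trilinear resampling to the measurement lattice, a multiplicative
*sensitivity factor* (the gel's systematic over-response; the analysis
recovers its reciprocal as the dose scaling factor), and per-voxel
multiplicative Gaussian noise (σ as a fraction of local dose), seeded and
bitwise reproducible. The MR reader samples S(TE) = S0·exp(−TE·R2(D)) on the
echo train with optional additive Gaussian noise per echo (in units of S0).
Gaussian rather than Rician magnitude noise is used because all analysed
voxels are high-SNR; at the last echo of the hottest voxels (R2 ≈ 80 s⁻¹,
S/S0 ≈ 10⁻⁴) the signal floor masks the fit instead.

The film writer inverts the quartic OD–dose calibration per channel (Newton
iteration on the monotone polynomial) and exposes
`pixel = reference · 10^(−OD)` with additive scanner noise in counts. The
synthetic film response is *exactly* the inverse of a monotone quartic — red
spanning 0.60 OD over 0–10 Gy, green 0.30, blue 0.15 — so that the
analysis-side quartic fit is exactly identifiable and the end-to-end film
round trip measures pipeline error, not model-mismatch residual. Pixels are
held as float64 in [1, 65535] in memory and quantised to 16 bits only on
TIFF export; quantisation contributes < 0.01% of the 4 Gy film maximum.

## Fitting choices

**R2 mapping.** The primary fit is weighted least squares of
ln S = ln S0 − TE·R2 with weights S², the variance-stabilised form whose
normal equations match the Gaussian likelihood at high SNR. Two reweighting
iterations (weights from the model prediction instead of the measured
signal) are applied by default: they leave noiseless results bit-identical
and bring noisy estimates within ≪ 0.5% of a per-voxel nonlinear
least-squares fit, at a fraction of its cost. Echoes at or below the signal
floor (default 3× a robust noise estimate from the last echo) are excluded
per voxel; voxels with fewer than two usable echoes are marked invalid
rather than raising. Voxels are fitted independently; no spatial
regularisation.

**Gel calibration.** Ordinary least squares of mean vial R2 on delivered
dose, requiring ≥ 3 vials and a positive slope; residuals and R² are kept
for the linearity diagnostic (a sign-runs check on the residuals should not
reject randomness when the response is truly linear). Conversion inverts the
line; out-of-range doses follow a policy: `clamp` (default for final maps),
`mark-invalid`, or `extrapolate`. The pipeline converts with `extrapolate`
*before* deriving the scaling factor, because the raw gel dose legitimately
exceeds the calibrated span (16 Gy / 0.85 ≈ 18.8 Gy) while the gel response
itself remains linear well beyond 17 Gy.

**Scaling factor.** Ratio of means (robust to zero-mean noise) of calculated
to measured dose over a uniform region — by default a 5 mm half-width cube
centred on the largest shot, which lies inside its 80%-isodose core and
contains enough coarse-grid voxels for a stable ratio. The factor is
scale-equivariant by construction.

**Film calibration.** Per channel, least-squares quartic of dose on OD
(≥ 6 strips; 5 coefficients plus one residual degree of freedom). Dose-on-OD
is fitted directly rather than fitting OD-on-dose and inverting, which is
ill-posed for a quartic; the selected channel maximises the OD change per Gy
over the strip range; a fitted curve that is not monotone over the data span
is flagged and warned about, not silently accepted. Channels beyond the
0–10 Gy red-channel range are a configuration switch, not automatic.

## Gamma index

Global normalisation: ΔD = dose_tol% of the calculated grid's maximum
(16 Gy for the gel study, 4 Gy for film); local normalisation is a flag. The
calculated grid is the reference and the measured grid is evaluated, with
the opposite orientation available. The minimisation samples the reference
by trilinear interpolation on a lattice of step `interp_step` (default
DTA/10, never coarser than DTA/5) out to `search_radius` (default 3×DTA).
Offsets are visited in order of increasing distance and a voxel leaves the
search as soon as the pure distance term exceeds its current best γ² — an
exact pruning, since the dose term is non-negative: the result is identical
to exhaustively scanning the same lattice, which the test suite verifies
against an independent brute-force implementation to 10⁻⁶. Voxels whose
minimum lies on the search-sphere boundary are capped at the boundary value
(radius/DTA) and flagged saturated. No low-dose cutoff is applied by default
(periphery voxels legitimately fail strict criteria and belong in the
statistics); a cutoff is available as an option.

## Comparison statistics

- **DVH**: cumulative volume (% of the analysis region's valid voxels) at or
  above each dose level (% of normalisation); per-structure DVHs are out of
  scope — the comparison is region-based.
- **DDDVH**: per dose bin, (n_measured − n_calculated)/N_total over the
  common voxel set (default bin width 1% of normalisation); bins sum to zero
  exactly and negate under swapping the inputs.
- **D4 diagram**: voxels binned by *calculated* dose (default 5% of maximum
  per bin); per bin, mean ± SD of 100·(measured − calculated)/calculated.
  The local-dose denominator is the default — it reproduces the
  characteristic inflation of percent differences below ~20% dose — with a
  global-denominator variant available. Zero-dose voxels are excluded from
  the ratio and counted.
- **Profiles and contours**: trilinear line samples at a fixed mm step;
  marching-squares isodose polylines in mm coordinates.

## Verification pipeline and problem sizes

`run_pipeline` chains simulate → echoes → R2 fit → calibration → scaling →
resampling → comparison deterministically from one seed, and writes a report
bundle (CSV tables, contour JSON, machine-readable summary). The default
study sizes keep a full run around a minute on one CPU: a 57³ export grid at
2.5 mm, a 131 × 161 × 19 gel lattice (≈ 400 k voxels × 8 echoes), and a
70 150-voxel common grid; the film branch uses a 0.5 mm plane and five
averaged scans. The noiseless identity configuration (1 mm calculated grid)
verifies that the whole chain returns its input — 100% gamma pass at
0.5%/0.5 mm — before any noise study is interpreted.

## Limitations

The dose kernel is not a beam model: no output factors, no attenuation or
scatter, no 201-source geometry, no tissue heterogeneity; only qualitative
field shape is meaningful. Plug wedge azimuths are invented (counts, not
positions, were recorded). The gel model omits post-irradiation drift,
temperature and dose-rate effects and edge artifacts near vial walls; the
film model omits lateral scanner response, orientation/polarisation effects
and triple-channel dosimetry. Passing the synthetic suite demonstrates the
*analysis* chain is correct and self-consistent under the stated noise
models — it does not validate any physical dosimeter against a real
treatment unit.
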