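# Methods

This note documents the models, numerical choices and known limitations of
`minltv`: an analytical cone-beam CT reconstruction chain plus a
mutual-information non-local total-variation (MI-NLTV) denoiser aimed at
low tube-current (low-mAs) acquisitions.

## Geometry and conventions

Right-handed axes (x, y, z) in mm, rotation axis along z, isocenter at the
origin. Gantry angle 0° puts the source at (0, −sad, 0); the flat detector
is perpendicular to the central ray at distance `sdd` from the source, with
u along +x at angle 0 and v always along +z. Volumes are arrays indexed
`[z, y, x]` with voxel centres at `origin + index·spacing`. Projection
values live in the post-log line-integral domain (dimensionless); the
simulator performs the `−ln(counts/I0)` conversion, so reconstruction
consumes line integrals directly. Volumes carry an explicit unit tag
(`mu_mm^-1` or `HU`, with `HU = 1000·(μ−μ_water)/μ_water`,
μ_water = 0.02 mm⁻¹ by default); the denoiser requires the μ domain
because its spatial weighting factor is ill-behaved for negative HU.

## Reconstruction

1. **Cosine pre-weighting** `sdd/√(sdd²+u²+v²)` compensates the intensity
   drop of oblique cone rays (u, v physical detector coordinates).
2. **Parker weighting** for scan arcs < 360°, applied before filtering
   (standard ordering; a flag moves it after). We use the generalized
   over-scan form with half-over-scan `δ = (arc−π)/2`: ramp-up
   `sin²(π/4·β/(δ−γ))`, plateau 1, ramp-down `sin²(π/4·(arc−β)/(δ+γ))`,
   where γ = atan(u/sdd) is the fan angle. Redundant ray pairs
   (β, γ) and (β+π+2γ, −γ) get weights summing to 1, so no extra 1/2
   redundancy factor is applied for short scans. Arcs below 180° + full
   fan are rejected.
3. **Ramp filtering** of each detector row: zero-pad to 2× the next power
   of two, multiply the DFT by
   `H(f) = f_N·(2/π)·|sin(πf/2f_N)| · ½(1+cos(πf/f_N))`
   (Shepp–Logan apodized ramp × Hann window), inverse DFT, crop. The
   frequency axis is defined on isocenter-scaled detector coordinates
   `û = u·sad/sdd`, which makes the filtered values backproject directly
   to attenuation in mm⁻¹ without per-view magnification factors. H(0)=0
   and H(f_N)=0 by construction. Edge padding is available to suppress
   truncation ringing for laterally extended objects.
4. **Backprojection.**
   *Pixel-driven (PDB):* each voxel centre is perspective-projected onto
   each detector, the filtered value bilinearly interpolated, weighted by
   the FDK distance factor `(sad/U)²` (U = source distance along the
   central-ray direction) and summed with `Δβ`, times ½ for full scans
   (every ray measured twice).
   *Ray-driven (RDB):* every detector pixel casts a Siddon ray to the
   focal spot; voxel j accumulates `Σ l_jk·P_k` and `Σ l_jk` and their
   ratio is the reconstruction. Because this ratio is a length-weighted
   *average* over views, the filtered projections are pre-scaled by
   `arc/2` (full scan) or `arc` (Parker-weighted short scan) to restore
   absolute μ units; the average of `(sad/U)²` over a full circle is 1 to
   second order, so no per-ray distance factor is needed. Voxels whose
   summed intersection length stays below 1 nm are reported in a coverage
   mask and left at zero.

The Siddon tracer walks parametric plane crossings exactly; corner
degeneracies are resolved by merging crossings at equal parameters and
dropping segments below 10⁻¹² mm. Accumulation order is fixed (views,
rows, columns), so outputs are bitwise reproducible. On a noise-free
uniform cylinder (60–72 views, 128-column detector) both backprojectors
land within ~1.5% of the true μ in the interior.

## MI-NLTV denoiser

Processing is 2-D, slice by slice. For pixel j of a slice:

* A **pooled joint histogram** (default 128×128 bins) is built between the
  stationary 5×5 patch (radius a=2) and the moving patches at every
  non-null displacement of a 21×21 search window: each stationary pixel is
  paired with the correspondingly displaced pixel, giving
  `(2a+1)²·((2s+1)²−1)` pairs. Intensities are binned with the
  slice-global min/max so the top bin corresponds to the slice maximum.
  Pooling all displacements into one histogram (rather than averaging
  per-displacement MI values) is the default because it yields one
  well-sampled distribution per voxel at 440× lower cost; the
  per-displacement average is available behind `aggregate="per_patch"`.
* The **statistical measure** is `M = MI/H(A)` with
  `MI = H(A)+H(B)−H(A,B)` in bits, clamped to [0,1]; a featureless
  (zero-entropy) stationary patch gets M=0 and therefore falls into the
  smoothing state. Note one property of the pooled estimator: M is high
  only where displaced patches relate to the stationary patch through a
  *consistent* intensity mapping across the search set; mixing matched and
  anti-matched displacements (e.g. period-2 stripes under a ±2 window)
  cancels, which is the intended robustness to incidental matches.
* The **weight** is `w_j = exp(−(max(V_j,0)/τ)^ρ·M_j)` with ρ=10 and τ the
  90th percentile of the whole volume's intensity distribution (computed
  once per volume; negatives clamped only inside this factor). The
  exponent is the *product* of the spatial factor and M: high intensity
  and/or high structural similarity → small w → preservation, which
  matches the intended behaviour (dense inserts and repeating bars are
  kept; homogeneous noise is smoothed). A `weight_composition="quotient"`
  switch retains the alternative reading for experimentation.
* The **objective** is `R(V) = Σ_j w_j·√(dr² + dc² + ε²)` with backward
  differences (first row/column differences zero, reflective boundary) and
  ε defaulting to 10⁻⁸ of the slice intensity range to smooth the
  non-differentiability at zero gradient. The analytic gradient is the
  exact three-term derivative of this discrete objective (own term plus
  coupling through the right and lower neighbours); it matches central
  differences to better than 10⁻⁴ relative — the single most important
  correctness gate of the implementation.
* **Descent:** `V ← V − λ·∇R/|∇R|` with `|∇R|` the root-sum-square over
  the slice and `λ = γ·√(Σ V_j²)·s`. The step scale s defaults to
  `0.5/√N_pixels`, i.e. λ = 0.5·γ·RMS(V): with a unit-normalized gradient
  direction, scaling by the root-sum-square *intensity* alone would move
  the image by its own norm in one step, while dividing by N would make
  the update vanish as slices grow; λ ∝ RMS intensity is the
  slice-size-invariant middle ground. The 0.5 factor was calibrated once
  on the synthetic phantom study as the balance point between
  uniform-region noise suppression and bar-pattern (3 lp/cm) retention,
  in the spirit of parameters "empirically determined to balance image
  quality"; it is a config knob (`step_scale`). γ starts at 1.0 and is
  multiplied by r_red = 0.8 whenever R increases; the offending step is
  kept by default (`reject_on_increase=True` rejects it instead). 20
  iterations by default. Weight maps are computed once per slice from the
  input image (`recompute_weights_every` enables refresh). The descent is
  fully deterministic.

The conventional-NLTV baseline replaces M with the mean Gaussian
patch-distance similarity `exp(−‖patch₀−patch_d‖²/((2a+1)²h²))` over the
same displacement set; h defaults to 10% of the slice intensity range, a
conventional NLM bandwidth choice (the baseline's own reference gives no
value). Everything downstream is shared, so MI-vs-NLM comparisons isolate
the similarity measure.

## Synthetic data

`phantom.make_catphan_like` voxelizes (by centre-sampling) a
water-equivalent cylinder with three non-overlapping axial modules:
seven density inserts (Delrin, Teflon, air, PMP, LDPE, polystyrene, air)
on a ring, using textbook HU values scaled by μ_water — documentation-level
approximations of the named materials, not measured data; a plain
uniformity module; and 1/2/3 lp/cm bar groups at twice the water
attenuation. `simulate_projections` forward-projects with the same Siddon
kernel and draws `counts ~ Poisson(I0·e^{−p})` (optional additive Gaussian
electronic noise), floors counts at one photon, and returns
`−ln(counts/I0)`. I0 is the proxy for the mAs setting; the default study
uses I0 = 2·10⁴ for the low-dose scan and a 16× larger I0 for the
benchmark scan, mirroring a 0.1 → 1.6 mAs ratio.

The default desk-scale study — 60 views over 360°, 128×128 detector at
1.6×1.0 mm pitch, sad/sdd = 1000/1536 mm, a 96×96×16 grid at 1 mm voxels —
was chosen so the whole six-way comparison runs in minutes on one CPU.
Metrics follow phantom-study practice: CNR `|m_fg−m_bg|/σ_bg` per axial
slice then averaged; SNU `(max−min)/1000·100` over five uniform-module ROI
means in HU; RMSE/Pearson correlation against the benchmark over an
in-body mask; NPS via first-order (plane) detrending of square ROIs,
`NPS = ΔxΔy/(NxNy)·|DFT|²` ensemble-averaged, with radial profile, peak
and intensity-weighted mean frequency; bar modulation as the Fourier
amplitude of the mean profile at the bar frequency. CNR/SNU formula
variants (pooled σ, pooled slices) are flags.

## What the synthetic study does and does not show

The simulation reproduces the *mechanisms*: Poisson-dominated low-dose
noise, streaks from angular undersampling and high-contrast inserts, and
cone-angle effects. It omits scatter, beam hardening (monoenergetic
model), detector lag/glare, bowties and anatomical texture. Consequently,
passing tests demonstrate the direction and internal consistency of the
method (MI-NLTV improves every insert's CNR, cuts uniform-region noise
several-fold, preserves most of the 3 lp/cm modulation, lowers the NPS
peak), not the magnitudes reported for any physical scanner. One known
difference: on this synthetic study the NPS intensity-weighted mean
frequency *rises* after denoising (the TV flow removes mid-frequency noise
faster than the finest-scale residue), whereas measurements on real
scanner noise, whose spectrum is strongly low-pass, report a downward
shift. The NPS peak, which drops by an order of magnitude here, is the
robust summary.

## Numerical details and edge cases

* Joint histograms are sparse (≤ 11,000 pairs vs 16,384 bins), so the fast
  kernel visits and resets only touched bins; flat slices put all pairs in
  bin (0,0) and are valid.
* A flat slice has zero TV gradient everywhere and is returned unchanged;
  an all-zero volume makes τ undefined and raises.
* Degenerate rays (zero length, non-finite endpoints) and truncated or
  mismatched projection files raise with the offending quantities named.
* Detector offsets are supported everywhere (centered detector assumed by
  default for the small-FOV protocol; config-overridable).
* The descent carries a NaN guard that aborts with the slice and iteration
  index.
* Full determinism: same config and seed give bitwise-identical artifacts;
  the run manifest records the config hash, seed and package version.

## Limitations

3-D block patches, projection-domain denoising, scatter correction,
distance-driven/separable-footprint projectors, task-based transfer
function and detectability-index estimation are out of scope. The RDB is
~2–4× slower than the PDB at equal grid sizes, as expected from tracing
one ray per detector pixel.
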