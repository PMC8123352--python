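# Methods

This note documents the models, numerical choices and known limitations of
`qelast`.  It is the place to look when a default needs changing or a
result needs interpreting.

## Material model and sign conventions

The specimen is treated as isotropic, nearly incompressible and
linear-elastic: two parameters, Young's modulus E (Pa) and Poisson's ratio
ν ∈ [0, 0.5), with shear modulus G = E/(2(1+ν)).  Under uniaxial
compression with stress-free lateral surfaces, E = σ₀/ε₀ where σ₀ and ε₀
are the *compressive-positive* axial stress and strain.  Raw
displacement-gradient fields keep their natural signs (εzz < 0 in
compression); the modulus stage flips the sign once (ε₀ = −εzz).  Mild
strain hardening of gelatin-like solids is modelled through an exponential
apparent modulus E_NL = E·exp(3γε₀²); the hardening parameter defaults to
γ = 0 for the linear synthetic phantoms and γ = 10 is the literature value
for gelatin.  All lengths, times and pressures are SI; pixel indices are
0-based with rows = axial depth z (downwards from the transducer face) and
columns = lateral x.

The printed form of the 2D→3D Poisson conversion uses the index order
εzz/εxx; with compression along z the transverse-to-axial ratio is
ν′ = −εxx/εzz, which is what the code computes before converting with
ν = ν′/(1−ν′).

## Displacement tracking

Frames are Gaussian-blurred (σ = 1 px; the flow estimators assume smooth
intensity) and tracked against an automatically redefined reference: flow
is estimated reference→k, scored by the masked 2D Pearson correlation of
the reference against the flow-warped target, and when the score drops
below ρ_min = 0.9 the current frame becomes the new reference.  "Adding
the accumulated displacement to all further fields" is implemented as
proper warp composition u(x) = u_acc(x) + u_new(x + u_acc(x)) with bilinear
sampling; naive Eulerian addition is wrong for large motion and survives
only as a debug mode.  A correlation below 0.5 while the reference is
already the immediately preceding frame aborts the run: switching cannot
rescue a sequence whose consecutive frames do not correlate.  (An absolute
abort floor rather than ρ_min itself is used so that ρ_min = 1 — switch
every frame — still runs to completion.)

Flow backends are pluggable (`qelast.flow.register_backend`).  The default
`hybrid` backend composes a pyramidal iterative Lucas–Kanade estimate
(robust beyond 30 px of motion but locally noisy) with two TV-L1
refinements of the residual (sub-0.1 px accurate but unreliable beyond
~20 px on speckle when used alone).  This mirrors the
matching-plus-variational design of large-displacement flow methods
without reimplementing one.  Pure `ilk` and `tvl1` backends remain
selectable.  Frames are jointly normalized to [0, 1] before estimation
because variational data terms are intensity-scale dependent.  Measured on
simulator ground truth at 256² px, the hybrid backend tracks a full 3 mm
compression with a p95 endpoint error of ~0.2 px.

## Strain

The 2D Savitzky–Golay first-derivative kernel of half-width M has entries
h(x) = 3x/((2M+1)²M(M+1)·GS) in every row (GS = grid step): a least-squares
plane fit per window, averaged across the perpendicular axis.  It
differentiates fields linear along the derivative axis *exactly* (this
property fixes the normalization, including that GS divides), returns zero
for rigid translations, and cancels arbitrary perpendicular variation.
Only the valid part of the convolution is kept — an M-pixel border is
masked.  Default M = 5; at the full 0.045 mm pixel pitch this is a ±0.23 mm
window, at the fast preset's 0.098 mm pitch ±0.49 mm.  Derivatives are
taken in physical units so strains are dimensionless.

Total (frame-0→k) strain feeds the modulus; the incremental mode
(differences of cumulative fields, exact on the common material grid) is
available for diagnostic pairings.

## Stress

Love's solution for a uniformly loaded rectangle on an elastic half-space
is evaluated on the image plane (y = 0, through the transducer's long
axis) with p = F/A₁.  The four arccos arguments of the solid angle Ω are
clamped to [−1, 1]; depth is floored at 1 nm so nominal surface pixels are
evaluable; corner distances follow the pairing fixed by requiring
machine-precision agreement with an adaptive-quadrature integration of the
Boussinesq point-load kernel 3pz³/(2πR⁵) — the module's primary
correctness oracle (relative agreement ~1e−15; the shipped test demands
<0.5%).  The finite specimen on a rigid base is approximated by a mirrored
base-plate-sized compressor carrying the same pressure p = F/A₁, scaled by
A₁/A₂ — the bottom compressor therefore carries the full reaction force.
Because the field is homogeneous of degree one in p, the pipeline computes
the unit-pressure shape once and rescales it per frame by that frame's
interpolated force.

## Performance descriptors and gating

For each (k−1, k) pairing three correlations are combined:
ρ_i (preprocessed frames, both warped to the reference configuration),
ρ_s (consecutive cumulative εzz maps) and ρ_e (consecutive modulus maps);
p_S = ρ_i·ρ_s gates the strain stage and p_E = ρ_i·ρ_s·ρ_e the
elastography stage, both at p_min = 0.9.  The first tracked frame has no
predecessor maps and is not gated in.

Two deliberate choices differ from the obvious construction, both forced
by measurement:

* ρ_s uses *cumulative* strain maps.  Consecutive incremental maps contain
  the middle displacement field's noise with opposite signs and therefore
  anticorrelate whenever the per-frame strain increment is small — the
  descriptor would reject perfect sequences.
* ρ_e is the **uncentered** normalized cross-correlation of winsorized
  (1–99 percentile) modulus maps rather than Pearson.  A correctly
  recovered homogeneous elastogram is structureless, so mean-subtracted
  correlation degenerates to the correlation of residual noise and
  *decreases* as the estimator improves (observed directly: improving the
  flow backend cut the strain error from 17% to 10% RMS and dropped
  Pearson-based p_E from ~0.97 to ~0.86).  The uncentered form retains the
  quantitative level of the map, which is the thing an elastogram is for.
  Winsorization is needed because pixelwise ratio estimates carry heavy
  tails that otherwise dominate the correlation sums.

Image rows within `bottom_exclusion_m` (default 3 mm, the compression
travel) of the base are excluded from all maps: the plate interface rises
through that band during the sequence, so it images material that leaves
the specimen and cannot be tracked — the same band is unusable in real
recordings.

## Modulus, Poisson and ROI reporting

Per-frame maps live on the frame-0 grid (the cumulative fields are
Lagrangian), so the multi-frame combination over accepted frames is a
plain masked pixelwise mean with a per-pixel count; no extra warping is
needed.  Division by strain is floored at |ε₀| ≥ 1e−4 (masked, never
infinite).  The Poisson map aggregates the *unclipped* in-plane ratio ν′
across frames and converts/clips once at the end: the generating value
(ν = 0.495, i.e. ν′ = 0.331) lies near the physical ceiling of 0.5, so
clipping each frame before averaging truncates only the upper noise tail
and biases the map low by several hundredths.  ROI summaries report the
median as the headline statistic (plus mean, std and pixel count);
homogeneous specimens use one central region, inclusion specimens a circle
1 mm inside the inclusion plus two flanking body rectangles.

## Synthetic phantoms

The simulator emulates the study conditions: a 25 mm specimen imaged over
25 × 25 mm at 0.045 mm/px (556², or 256² with ~2-of-8 temporal subsampling
in the fast preset), compressed 3 mm at 1 mm/s, 43 fps, with a 38 × 8 mm
transducer on a 45 × 25 mm base.  Homogeneous phantoms default to the
mechanical-reference medians (hard 18.9 kPa, soft 6.92 kPa); the inclusion
phantom embeds a stiff 8 mm cylinder at the image centre.  Speckle is
rendered as Poisson-distributed point scatterers with log-normal
amplitudes deposited bilinearly and blurred by a Gaussian PSF (σ = 1.2 px);
frames carry independent additive Gaussian noise of 1% of the dynamic
range (exported B-mode CINE is post-processed, so residual noise is low).

The forward deformation treats each image column as springs in series
under an axial stress profile σ(x,z) = p·φ(x,z).  By default φ is the
same two-compressor Love shape the reconstruction models
(`stress_model="love"`); p is calibrated so a body column integrates to
the applied compression, and F = p·A₁.  This makes parameter recovery
well-posed — the remaining error is attributable to tracking and
differentiation — and it is what lets the plane-stress baseline be shown
to be worse on the same data (under a uniform-stress forward model the
plane-stress reconstruction would be exact by construction and the
comparison meaningless).  The idealized uniform-stress mode
(`stress_model="uniform"`) is kept for closed-form column-spring checks:
uniform strain d/H for homogeneous specimens, 2:1 strain in two-layer
stacks, per-column strain ratio E_body/E_inc through the inclusion.
Strain fields are laterally smoothed over ~1 mm so inclusion edges do not
produce displacement kinks sharper than real gelatin interfaces.  Frames
are rendered in transducer-attached coordinates (the B-mode origin rides
on the moving face): the contact surface stays at row 0 and deep material
moves up by as much as the applied compression.  Lateral motion integrates
the in-plane expansion −ν′εzz outward from the centre line with
ν′ = ν/(1+ν).

What the simulator does **not** emulate: RF-domain speckle physics
(scatterer phase, decorrelation under deformation), attenuation and
shadowing, out-of-plane motion, viscoelastic creep of the force, and
transducer–surface friction.  Passing tests on these phantoms therefore
demonstrate the correctness of the *algorithmic chain*, not robustness to
every artifact of real recordings.

## Mechanical reference estimators

Both estimators detect contact as the first sample at ≥0.1 N, re-zero
displacement and force there, and fit the post-contact region by ordinary
least squares through the contact point.  The bonded-block compression
relation is read as E = 3σ/((λ⁻²−λ)·(1+2S²)) with λ = (H−δ)/H < 1 in
compression; points beyond 15% strain are excluded (the sidewalls could
touch the plate).  The BASh relation is read as the standard
dF/dδ = (2/√π)·φ_c·√A·M₃′ with φ_c = 1.016 for the rectangular transducer
and E = M₃′(1−ν²).  Both resolutions are validated by exact round trips on
curves generated from the same relations and by <1% bias under 1% force
noise across 1000 replicates.  The bonded/free surface ratio S of the
25×25×45 mm blocks is exposed as a parameter (default 0.25) since it
depends on the mounting.

## Problem sizes and defaults

The shipped tests and the acceptance script use the fast preset (256² px,
~32 frames per sequence); a three-specimen suite runs in ~2.5 min on one
CPU.  The full-resolution default (556², 130 frames) is approximately 20×
slower and produces the same ROI statistics within the seed-to-seed
scatter.  Key defaults: ρ_min = 0.9, p_min = 0.9, M = 5, blur σ = 1 px,
strain floor 1e−4, ν assumption 0.495, γ = 0 (synthetic) / 10 (gelatin),
density 1000 kg/m³.

## Known limitations

* Love's solution assumes a homogeneous half-space; with a stiff inclusion
  the true stress concentrates and the reconstruction inherits a bias the
  model cannot see (contrast-transfer correction is future work).
* The uniformly *loaded* footprint approximates the uniformly *displaced*
  rigid transducer; the error is largest near the contact surface.
* The trustability gate needs the per-stage correlations of good frames to
  sit above p_min; very short or very low-resolution sequences (under
  ~10 frames or 128² px) score structurally lower and may need a lower
  p_min even when their recovered moduli are fine.
* Strain noise is speckle-correlated and systematic across frames, so
  averaging more frames does not remove the residual mottle of the
  modulus map; the spatial CoV at the fast preset is ~10–14%.
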