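# Methods

## Mechanical model

The capsule wall is modelled as a thin laminated plate in classical
laminate theory (CLT) with hygroscopic load resultants. At a given
circumferential station the stack, inner to outer, is: transverse fiber
cells (fiber axis at 90° to the capsule's longitudinal axis),
longitudinal fiber cells (0°), and parenchymatous mesocarp
(quasi-isotropic). Each layer contributes a plane-stress reduced
stiffness Q̄ rotated into laminate axes; the parenchyma additionally
carries an isotropic free drying strain ε < 0. Solving
[[A,B],[B,D]](ε⁰,κ) = (Nʰ,Mʰ) for the unconstrained plate yields the
free mid-plane strains and curvatures; κ_x is the longitudinal bending
curvature κ_L.

Assumptions:

- **End states only.** The model relates a fully wet to a fully dry
  state; no moisture-diffusion kinetics.
- **Small-strain, linear plate.** No geometric nonlinearity and no
  doubly-curved shell coupling: longitudinal and transverse bending are
  the two curvature components of a single flat-plate solve, reported
  independently.
- **Parenchyma is the only actuator.** The fiber layers' own
  hygroscopic strain is set to zero; this isolates the mechanism by
  which parenchyma shrinkage drives bending while fibers resist it
  along their axis. The solve is exactly linear in ε, so the
  *normalized* curvature profile is independent of the shrinkage
  magnitude — only ratios of stiffness and thickness matter.
- **Sign convention.** z runs from the inner (endocarp) surface
  outward; curvature is positive when the outer (mesocarp) face becomes
  concave, so drying gives κ_L > 0. Internally the standard CLT
  system is solved and the curvature vector negated; the reference
  plane (default: geometric midplane) changes the (ε⁰, κ) bookkeeping
  but not the physical curvature, which is covered by a test.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| E along fibers : across : parenchyma | 20 : 5 : 0.1 | relative | typical anisotropy of fiber tissue vs parenchymatous foam; only ratios enter the normalized profile |
| ν₁₂ | 0.3 | – | generic soft-biocomposite value; the minor ratio follows as ν₂₁ = ν₁₂·E₂/E₁ |
| G₁₂ | E₂/(2(1+ν₁₂)) | relative | isotropic-like estimate; no shear data exist for these tissues |
| ε (parenchyma) | −0.7 | – | isotropic in-plane analogue of the observed through-thickness collapse to ~30% of wet thickness; pure scale factor for normalized output |
| wall thickness h | 1.0 | arbitrary | held constant along the circumference; only fractions X_M, X_L, X_T vary |

A sensitivity test confirms the normalized profile and its peak
position are insensitive to ν and ε at the qualitative level.
Zero-thickness layers are dropped from a station's stack (rather than
kept at ε-thickness) to keep the ABD matrix well conditioned; an
all-zero station is an error.

## Measurement procedures

**Segment curvature.** Each digitized dried-segment trace is fitted
with a circle: the algebraic Kåsa solution (linear least squares)
initializes a geometric orthogonal-distance refinement
(Levenberg–Marquardt on the center, radius as the mean distance). The
fit is exact on noise-free arcs and deterministic for a fixed point
order. Collinear point sets (relative flatness below 1e-9) are flagged
straight and mapped to κ = 0 rather than an error — the split-region
segment genuinely barely bends. Curvature is reported unsigned via
κ = 1/R with the straight flag.

**Positions.** Segment n of widths d₁…d_N sits at
l_n = Σ₁ⁿdᵢ / Σ₁ᴺdᵢ; for comparison with model predictions each
segment's curvature is plotted at its midpoint l_n − d_n/(2Σd). The
canonical station grid is the midpoint grid s_i = (i+½)/n, so an
equal-width dissection with n segments has its midpoints exactly on
the stations and the noiseless round trip (profile → arcs → circle
fit → comparison) is exact; with unequal widths the comparison falls
back to linear interpolation in s.

**Shrinkage.** ratio = 100·mean(dry)/mean(wet) over paired same-locus
thickness samples, with the reciprocal fold change also reported; a
binary-mask route measures per-ray thickness by foreground pixel counts
along rays normal to a roughly axis-aligned layer band (≥ 20 rays).

**Microfibril angle.** Per cell, the three highest-retardance pixels in
the ROI are sampled (brightest birefringence = strongest crystalline
cellulose signal; ties broken by grid order for determinism), the
azimuth-minus-cell-axis differences folded to [−90°, 90°), and the
absolute axial circular mean taken. Cohorts aggregate per-cell values
with angle-doubled circular mean and sd; fewer than five cells is
flagged, not an error. Pixels below a retardance noise floor (default
5% of the map's 95th percentile) are excluded; a cell with fewer than
three bright pixels raises a dark-cell error, which is what the
parenchyma produces. The absolute-mean folding inflates estimates near
0° truth (half-normal bias ≈ 0.9° at noise sd 2°, quantified in a
test); measured fiber MFAs of 8–12° sit far from that boundary.

## Synthetic material

The generators produce every pipeline input with known truth; all are
deterministic under a seed recorded in the run log.

**Canonical graded profile.** PCHIP (monotone shape-preserving)
interpolation of (X_M, X_L, X_T) through six anatomical knots,
renormalized to sum to 1 per station, sampled at 20 midpoint stations,
with multiplicative station jitter (CV 3%, renormalized). The knot
values are *fixture calibration, not measured data*: they were chosen
once so the generated architecture reproduces the qualitative wall
anatomy — a longitudinal-fiber monolayer at the split region
(X_L ≈ 0.9 at s=0), longitudinal fibers vanishing to a
transverse+parenchyma zone at the vascular bundle (X_L ≈ 0.02 near
s ≈ 0.775), mostly longitudinal fibers again at the far side — together
with a strong negative X_M–X_L correlation (R² ≈ 0.96) and a clearly
weaker X_M–X_T coupling (R² ≈ 0.62). The sum-to-one constraint plus the
shared vascular-bundle maximum of X_M and X_T put a floor on the M–T
correlation: under this architecture R²(M,T) cannot be pushed much
below ~0.6 without breaking the split-monolayer or vascular-bundle
anchors, so the M–T coupling should be read qualitatively ("much weaker
than M–L"), not as a calibrated value. Multiplicative rather than
additive jitter is used because a fixed absolute noise on the ~0.02
vascular-bundle X_L would be ~50% relative error and would destabilize
the curvature peak; a few-percent CV is the realistic scale for
thickness readings. Robustness was verified over hundreds of seeds:
R²(M,L) ≥ 0.948 and the curvature peak always at 72.5–77.5% of the
circumference.

**Segment arcs.** Equal-width segments realize a curvature profile as
circular arcs (straight lines at κ = 0) of the curvature interpolated
at each segment midpoint, under a random rigid pose per segment, with
optional Gaussian point noise (default 0 — digitization noise is opt-in
for Monte-Carlo tests).

**Azimuth fixtures.** Rectangular fiber-cell masks at varied cell-axis
angles; inside a cell, azimuth = cell axis + true MFA + von Mises noise
(sd 2° by default), retardance 80–135 nm; the background is nearly dark
(0–2 nm), mimicking parenchyma. Truth defaults: 8° (transverse cells),
12° (longitudinal cells).

**Wet/dry pairs.** Lognormal wet thicknesses around 300 µm (σ = 0.15),
dry = wet × ratio × (1 + noise), default ratio 0.30, CV 2%, n = 20.

What the generators do *not* emulate: real micrograph segmentation
error, perspective/lens distortion of photographed segments, spatially
correlated thickness errors, within-cell MFA gradients, and the optics
of the polarized-light microscope itself. Passing tests therefore
demonstrate the correctness and stability of the *procedures* under
controlled noise, not the accuracy of any particular real-specimen
measurement.

## Numerical choices

- ABD conditioning is checked (cond > 1e12 raises a singular-laminate
  error naming the stack); layer invariants guarantee positive-definite
  A and D otherwise.
- Peak location ties break toward the smallest s; an all-zero curvature
  profile raises a no-movement flag rather than returning a position.
- Zero-variance series in correlation statistics return NaN with an
  `undefined` flag; profile comparison returns NaN Pearson r for a
  constant profile.
- Round-trip file I/O is stable to 1e-12 (tables are written at 12
  significant digits).

## Problem sizes

Defaults mirror the study design at desk scale: 20 circumferential
stations, 20-segment synthetic dissections (8–9-segment dissections are
exercised in tests), 5-cell MFA cohorts with 3 measurements per cell,
20 wet/dry thickness samples. The heaviest routine checks are
Monte-Carlo suites of ~1000 replicates (circle-fit recovery, MFA
cohort bias), which run in seconds.

## Known limitations

- The plate solve ignores the capsule's initial curvature and any
  shell-membrane coupling; predictions are for flattened longitudinal
  strips, matching the dissection geometry.
- Absolute curvature magnitudes depend on the unknown ε and absolute
  moduli; only normalized profiles are claimed.
- The MFA estimator is a transparent azimuth-difference stand-in for
  proprietary instrument software; it is validated by parameter
  recovery on synthetic maps, not against instrument output.
- Mask-based thickness assumes a roughly axis-aligned layer band; it
  does not trace curved layer midlines.
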