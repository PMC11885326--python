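# Methods

This note documents the models behind `neoaorta`, the choices made where
the design was genuinely open, and what the synthetic stand-ins do and do
not establish about real post-ASO anatomies.

## Synthetic geometry

The aorta is a tube lofted along a planar "candy-cane" centerline: a
straight ascending limb, a circular apex arc, and a straight descending
limb (limbs 8 cm, all geometry in cm internally).  Cross-sections are
circular; their diameter interpolates the four clinical levels — annulus,
sinus of Valsalva, sino-tubular junction (STJ), mid-ascending aorta — with
a shape-preserving PCHIP profile (so the sinus bulges smoothly and equal
level diameters degenerate to an exact constant-radius tube), and stays
constant distal of the mid-ascending level.  A small seeded radial jitter
(5e-4 fractional) gives each subject surface-roughness individuality
without perturbing any measurement beyond ~0.1%.

**Arch angle.**  The angle is *measured* exactly as defined clinically:
take the highest centerline point A, displace the tangent at A by one
diameter toward the lumen, and intersect; the angle BAC between the two
first crossings is reported.  The *generator* controls this angle through
the inclination of the two limbs (half-angle each side of vertical),
solved by 1-D root finding so the measured angle equals the request; the
apex rounding arc has radius 0.62 × the apex diameter, which keeps the
inner wall of even the most acute ("gothic", ~68°) arches from folding.
Open choices resolved here: "one diameter" always means the *local*
diameter at the reference station; the offset line is displaced within the
best-fit centerline plane toward the centroid; multiple crossings take the
one nearest the apex on each side.

**Planes and regions.**  Plane 0 sits one local diameter distal of the
annulus; plane 1 one diameter proximal of the brachiocephalic ostium;
plane 2 just before that ostium (0.05 diameters); plane 3 just after the
left subclavian; plane 4 two diameters further.  Wall regions are
arclength bands: the root from one STJ diameter proximal of the STJ to the
STJ, the other four ±0.5 local diameter around planes 1–4; triangles in
overlapping bands go to the nearest band center, keeping regions disjoint.
Branch ostia are landmark points only (no branch tubes): the 0-D module
owns all branch flow, and the post-processing regions exclude branch
lumens anyway.

**Level measurement** slices the triangle mesh perpendicular to the
centerline and reports the equivalent-circle diameter 2√(A/π), except the
mid-ascending level, which averages the minimum and maximum caliper
diameters of the section (rotating-calipers on the convex hull).  Hinge-
point conventions are not reproducible on synthetic tubes and are out of
scope.

## Cohort and normalization

Body surface area uses the Haycock formula
`0.024265 · W^0.5378 · H^0.3964` (W kg, H cm).  Z-scores are
`(d − mean(BSA)) / sd(BSA)` per level against a reference model.  The
published pediatric reference coefficients are not reprinted anywhere we
can ship, so the bundled reference is a synthetic affine-in-BSA model
(documented as non-clinical); any table of (level, bsa, mean_mm, sd_mm)
loads from CSV with linear interpolation.  Class boundaries follow the
printed inequalities exactly: Z = 4 is severe, Z = 2 is normal.

The cohort generator samples age uniformly on 8–18 y with age-increasing
weight/height envelopes, cardiac output uniformly on 3.8–6 L/min, and
pressure targets on 100–130 / 60–80 mmHg.  Diameters are produced by
sampling per-level Z-scores inside group bands (severe max-Z 4–6.5 at the
sinus; mild 2.3–3.7; normal ≤ 1.8) and inverting the reference at the
subject's BSA — so every subject classifies into its intended group *by
construction*, which is the property the label-fidelity tests assert.
Arch angles draw uniformly from the printed group ranges (68.5–77.2°,
71.1–85.2°, 87.4–99.0°).  No cardiac-output-from-age formula is published
in a reusable form, so CO is sampled directly inside its stated range.

## 0-D hemodynamics

Blood is Newtonian with μ = 0.04 P and ρ = 1.06 g/cm³ (ν ≈ 0.0377 cm²/s;
the implied Reynolds numbers for the cohort envelope stay below 1700,
i.e. laminar/transitional).  The bundled inflow waveform is an analytic
pulse — a systolic half-sine of duration T/3 plus a small (8%) reverse
lobe at valve closure — with period 0.8 s, rescaled by a single factor to
any cardiac output; measured waveforms load from CSV.

The 3-D domain is replaced by an ideal junction: inlet flow splits among
all outlets by modified Murray fractions d²/Σd² at every instant, so mass
is conserved to machine precision.  Each outlet evolves the standard
3-element Windkessel with distal reference pressure 0:

    P_i = Q_i Rp_i + P_c,i        C_i dP_c,i/dt = Q_i − P_c,i / Rd_i

integrated with the exact exponential update of the one-state capacitor
equation (unconditionally stable at dt = 1 ms; halving dt moves pressures
by < 0.01%).  Capacitors start at their cycle-mean steady state, whole
cycles are integrated until systolic and diastolic root pressure drift
≤ 1% versus the previous cycle (minimum eight cycles), and only the final
cycle is reported.  Root pressure is the Murray-fraction-weighted mean of
outlet proximal pressures.

**Tuning** uses the standard two-knob decoupling: total resistance scales
by the target/achieved mean-pressure ratio, total capacitance by the
achieved/target pulse-pressure ratio (factors clipped to [0.3, 3] per
step), then totals redistribute with R_i ∝ 1/fraction, C_i ∝ fraction and
a fixed Rp:Rd = 0.09 (a conventional large-artery characteristic-impedance
share; configurable).  On the synthetic cohort the tuner reaches its 1%
stopping tolerance in ~5 iterations; mean achieved-vs-target error ≈ 1%.

## Constructed velocity field

The field replaces the finite-element solution; it is the component that
makes the analysis desk-scale.  The axial profile is a generalized power
law `u = U(s,t)·(m+2)/m·(1 − r̃^m)` along the local tangent, renormalized
so every cross-section integrates to Q(t) (flux consistency within 1% at
all planes and frames).  The bluntness exponent m(s) is 2 (exact
Poiseuille) on branchless tubes — which is what makes the closed-form
WSS/vorticity oracles exact — and on full anatomies rises from 2 at the
STJ to 4 at the pre-bifurcation station before relaxing to 2 two diameters
past the last branch.  This entrance-flow sharpening of the wall gradient
is the mechanism that reproduces the normal-anatomy WSS pattern (root
minimum, distal-ascending maximum, decline into the descending aorta);
with it, regional TAWSS ∝ (m+2)·μU/R captures both the diameter cube law
and the along-arch pattern.

The recirculation bubble is superposed strictly between the
distal-ascending and arch planes: an axial deficit shaped
`r̃⁴(1−r̃²)·(1+cos Δφ)/2`, concentrated near the outer-curvature wall,
whose amplitude is calibrated by root finding so the peak reverse velocity
equals `strength` × the local mean forward velocity; the forward profile
is simultaneously rescaled so the deficit is flux-neutral.  A tangential
swirl `∝ r̃(1−r̃²)` (amplitude 1.2 × strength by default) extends 1.5
diameters into the arch; the extra near-wall azimuthal shear it carries is
what lifts the arch region to the TAWSS maximum in severe phenotypes,
while the deficit depresses the distal-ascending region — together
reproducing the severe-dilation signature.  Default strengths are 0.6
(severe), 0.15 (mild), 0 (normal); with these, the volumetric reverse-flow
fraction at peak systole is ≈ 0.05–0.07 for severe subjects and exactly 0
for normal ones, against a presence threshold of 0.02.  Each subject's
bubble gets a small seeded azimuthal/axial placement jitter.

Womersley (oscillatory) profiles are deliberately omitted: every reported
metric is a cycle average, and a quasi-steady profile family keeps all
oracles closed-form.

## Metrics

- **WSS**: one-sided second-order difference anchored at no-slip,
  `μ(4u(ε/2) − u(ε))/ε`, with offsets measured from the analytic lumen
  boundary (compensating the sub-percent gap between faceted-mesh triangle
  centroids and the true wall); exact for parabolic profiles.  Default
  ε = R/20.  TAWSS averages over frames (uniform weights) then over
  triangle areas.
- **Vorticity**: full 3-D curl by central differences (stencil step = ¼
  grid pitch, decoupled from the pitch so near-wall cells survive
  masking), |∇×u| averaged over the masked section, then over the cycle.
  A streamwise-only switch projects onto the plane normal instead.
- **Recirculation fraction**: deterministic station × radius × azimuth
  lattice (area-uniform radii, volume weights) between planes 2 and 3;
  fraction of points with negative tangent-projected velocity at peak
  systole (the frame of maximum inlet flow).  The 0.02 presence threshold
  is an operational cutoff — the original observation is visual — and is
  configurable.
- **Pattern**: argmax region of the five TAWSS values; ties break toward
  the more distal region and are logged.

## Numerical tolerances asserted by the test suite

Poiseuille WSS equivalence ≤ 2%; TAWSS cube-law scaling ≤ 5%; solid-body
vorticity = 2Ω within 1%; Poiseuille slice vorticity = 8U/3R within 3%;
steady Windkessel P = Q(Rp+Rd) within 0.1%; arch angle vs the circle-chord
closed form within 1° for arc-to-offset ratios 2–50; time-step halving
moves all reported metrics ≤ 3%; a factor-two spatial refinement moves
TAWSS/vorticity ≤ 10%; cycle-to-cycle pressure drift ≤ 1% after eight
cycles; tuned pressures within ~1% of targets (well inside the 5.1%
acceptance bound).

Default problem sizes — 400 centerline points, 48 ring vertices, 40×40
plane grids, 16 frames per cycle for TAWSS and 8 for vorticity — were
chosen as the coarsest discretization that keeps the refinement checks
comfortably inside those tolerances; a full 5+5+5 cohort runs in about
half a minute on one CPU.

## What the synthetic stand-ins do not show

The velocity field is constructed, not solved: it enforces flux
consistency, no-slip, and the phenotype features the metrics measure
(near-wall shear, slice rotation, reverse flow), but contains no pressure
field, no Dean/secondary-flow physics beyond the imposed swirl, and no
turbulence.  Passing tests therefore validate the *measurement apparatus*
and the 0-D boundary model — not the hemodynamic realism of any individual
flow feature.  Likewise the bundled normative reference is synthetic:
dilation classes are internally consistent but not clinically meaningful.
Absolute vorticity levels are not comparable to any published values; only
their along-aorta patterns are.
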