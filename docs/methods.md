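# Methods

This note documents the models implemented in `stemsurvey`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not demonstrate.

## DBH from tangent-arc geometry

### Model and assumptions

One caliper observation is a pair of contact angles (α₁, α₂). The stem
cross-section is modelled as **two circular arcs meeting at the vertex
contact point**: arc *i* is the circle tangent to the vertex-tip line
(offset `h` from the beam axis) at the beam middle (distance `s` from the
hinge) and tangent to arm *i*'s inner face (offset `w` from the arm axis).
Solving the tangency gives

    sᵢ = s − (h·cos θᵢ + w)/sin θᵢ,    rᵢ = sᵢ·tan(θᵢ/2),    DBH = r₁ + r₂,

equivalently `rᵢ = (s·sin θᵢ − h·cos θᵢ − w)/(1 + cos θᵢ)`, which reduces to
the closed branch `s − w` at θ = 90° and is continuous there. The test
suite enforces this derivation against an independent brute-force
construction (root-finding on the raw tangency conditions with numerically
minimised point-to-line distances), to < 10⁻⁸ cm over α ∈ [30°, 150°].

Assumptions: tangential contact on smooth bark (no local concavity at the
three contact points); each side of the stem locally circular; the vertex
contact exactly at the beam middle. Bark roughness and non-convex
cross-sections are not modelled.

### Valid angle domain

The frame cannot produce a positive tangent offset below a minimum angle
θ_min (≈ 22.5° for the default geometry), solved once per `DeviceGeometry`
from `s·sin θ = h·cos θ + w`. Angles outside (θ_min, 180°) — and any input
yielding sᵢ ≤ 0 or rᵢ ≤ 0 — raise an out-of-range-stem error. The
contact-angle inverse (used by the simulator) additionally caps the domain
at 170°, a generous mechanical limit for how far an arm can open; with the
default frame this still represents radii up to ~2.3 m.

### Device constants and calibration

`s = 15 cm`, `w = 2.5 cm`, `h = 3.5 cm` are fixed mechanical values of the
frame (half sensor-axis spacing, half member width, and `w` plus the vertex
width). The ADC conversion `α = (360/U_n)·(U_c − V_z·U_n/V_r)` is linear in
the output count with the zero offset rescaled by the supply ratio, so
supply drift between initialisation and measurement cancels; it operates on
raw counts, and volt-to-count scaling is the calibration's concern.

### Exact vs. series evaluation

`exact` mode (default) uses library trigonometry. `series` mode reproduces
the firmware's fixed-point arithmetic: 4-term truncated Maclaurin series
for sin and cos, and tan(θ/2) as the ratio of the half-angle series. The
truncation error per arc stays below 1 mm of DBH contribution over
α ∈ [30°, 120°] (worst case 0.59 mm at 120°); for a symmetric stem with
*both* arcs at the 120° extreme the errors add to ~1.2 mm. Above ~120° the
series degrades quickly and exact mode should be used.

## DS-TWR ranging

The distance estimator is
`Dis = c·(t_round1·t_round2 − t_reply1·t_reply2)/(t_round1 + t_round2 + t_reply1 + t_reply2)`
with `c = 2.99702547×10¹⁰ cm/s` (light in air; configurable). With ideal
clocks this is algebraically exact for any reply asymmetry, since
`(2t_p+ρ₁)(2t_p+ρ₂) − ρ₁ρ₂ = 2t_p(2t_p+ρ₁+ρ₂)`. Clock drift is modelled as
each node's clock running at rate (1 + e), e in ppm, with timestamps being
local-clock readings of true event times — the standard model. Under
drift, the double-sided error is second-order while the single-sided
estimate `c·(t_round1 − t_reply1)/2` carries a first-order term
(rate difference × reply delay); the tests verify strict dominance over a
±50 ppm grid. One genuine edge: when both clocks share the same rate, every
timestamp scales identically and the two estimators coincide exactly, so
dominance is non-strict on that diagonal. A related consequence is that the
*measured* reply can slightly exceed the *measured* round near zero flight
time; exchange validation therefore allows a 1000 ppm skew margin rather
than enforcing round ≥ reply on local-clock readings.

Antenna-delay calibration and received-power range-bias curves are out of
scope; the NLOS effect enters only as the simulator's additive delay.

## Localization

Anchor frame: A = (0,0), B = (dis_AB, 0) on the x-axis, C and D from the
two-circle intersection `X = (dis_AB² + dis_A·² − dis_B·²)/(2·dis_AB)`,
`Y = +√(dis_A·² − X²)`. The **positive root** places the plot interior on
the +y side, which presumes anchors labelled counterclockwise A→B→C→D; the
surveyed C–D distance, unused by the construction, is checked against the
frame and a warning is issued beyond 5 cm — the signature of a mislabelled
(clockwise) survey or a non-convex layout. Degenerate layouts (triangle
inequality violations, collinear triples) raise errors rather than
returning complex or unstable coordinates.

Trilateration solves the three radical-axis equations of one triple by
least squares. The third equation is the sum of the first two, so the
system is rank-2 consistent and the residual is ~0 *for any positive
ranges* — uniformly inflated NLOS ranges move the radical centre but never
make the system inconsistent, which is what makes the subsequent fusion
meaningful. Least squares is chosen over picking two equations for
numerical symmetry; both are equivalent given the proven consistency.

Fusion weights are the reciprocals of each triple's total projected range.
The fused point is a convex combination of the four trilateration points.
Under noise, observations whose range falls below the altitude difference
(negative projection radicand) are rejected, and the simulator's protocol
redraws them.

The field protocol measures everything twice: DBH in two directions
(major/minor) and position twice; both are averaged (positions
component-wise).

## Accuracy statistics

BIAS, relBIAS, RMSE, relRMSE and MAPE follow the standard paired
definitions (relative metrics in percent of the reference). Correlation is
**Pearson's** product-moment coefficient. Per-plot tables add a pooled
"Total" row computed over all trees, so the total RMSE is the quadratic
mean of equal-size per-plot RMSEs, not their arithmetic mean. Ed is the
per-tree Euclidean position error; its summary reports mean/max/min/std
(std with n−1 degrees of freedom).

## Synthetic-plot simulator

### What it emulates

Square 10 × 10 m plots on a planar terrain ramp (slope 3–33°, configurable
aspect), 15–37 trees per plot with truncated-normal DBH inside a 51–341 mm
envelope — the descriptive range of the kind of mixed stands the method
targets. Stems are a mix of circular, two-arc (the estimator's own
eccentricity model, minor/major width ratio drawn from 0.7–1.0) and
elliptical cross-sections; the ellipse lies *outside* the two-arc model
class and exists to stress-test it. Tree positions are uniform with
non-overlap (bounded rejection sampling). True DBH follows the caliper
reference convention — the mean of major and minor widths — giving 2r,
r₁+r₂ and a+b for the three shapes.

The forward contact model inverts the arc-radius relation by bisection
(unique root; the radius is strictly increasing in the angle). Elliptical
contact angles are solved from the ellipse support function with the
ellipse axis-aligned to the measurement direction; oblique orientations are
not modelled.

### Noise model and defaults

- `range_gauss_sd = 10 cm`: Gaussian jitter on each UWB slope range.
- `nlos_delay_mean = 10 cm`: exponential nonnegative delay added per range
  (obstructions only lengthen paths, so ranges are biased high).
- `altitude_sd = 2 cm`: Gaussian altimeter noise (sensor resolution 1 cm).
- `angle_sd = 0.1°`: Gaussian angle-sensor noise (resolution 0.088°).

The hardware's noise magnitudes are not published beyond resolutions, so
these scales are assumptions chosen to put the simulated position errors in
the same tens-of-centimetres regime as field experience with sub-100 m UWB
ranging; they are explicit `NoiseModel` parameters, not constants. All
randomness flows from one seed through numpy Generators; fixed seeds
reproduce observation sets bit-for-bit.

### What passing tests show — and do not

Zero-noise recovery (DBH to < 10⁻⁶ cm for circular and two-arc stems,
positions to < 10⁻⁶ cm) demonstrates the estimators are structurally exact
inverses of the forward models — no algebraic or geometric bias. The
elliptical stems show the model-class limit: averaging the two measurement
directions leaves a residual of order 1 mm for realistic eccentricities.
Noisy-recovery statistics (DBH RMSE ≈ 0.5 mm, mean Ed ≈ 10–12 cm under the
defaults) characterise error *propagation* through the pipeline under this
noise model only. They do not validate the noise model itself against real
forests: real NLOS delay is environment-dependent and non-exponential, real
bark contact adds DBH error far exceeding the angle-sensor jitter, and
anchor surveys in the field carry their own errors (the simulator's anchor
survey is exact). Field DBH errors of several millimetres are therefore
entirely compatible with the sub-millimetre simulation figures.

### Problem sizes

The bundled experiments use a ten-plot campaign of 225 trees (15–37 per
plot) with two observations per tree per instrument — a full-size plot
campaign for this method; the statistics stabilise well below these counts
and the whole suite runs in seconds.

## Known limitations

- Four anchors, one 10 × 10 m cell; no multi-cell mosaicking or >4-anchor
  generalisation.
- No NLOS identification/mitigation beyond the inverse-range weighting.
- Stem model is convex and two-arc; bark texture, buttressing and DBH
  above ~50 cm (outside the frame's comfortable range) are not addressed.
- The QR codec handles payload strings only; image rendering/scanning is
  hardware territory.
- GeoJSON output is in the local plot frame (metres), not georeferenced.
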