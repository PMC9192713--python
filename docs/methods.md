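# Methods

`cortmag` re-implements, on fully synthetic data, an analysis chain that
links local V1 cortical magnification to contrast sensitivity around the
visual field.  This note documents the models, the choices made where the
procedure was genuinely open, and what the synthetic data do and do not
emulate.

## Coordinate conventions

Visual-field polar angle is measured counter-clockwise with 0° at the right
horizontal meridian and 90° at the upper vertical meridian; x is positive
rightward and y positive upward.  The left hemisphere carries the right
visual hemifield (angles in [-90°, 90°]) and the right hemisphere the left
hemifield; the vertical meridian is represented on both, and
vertical-meridian wedge areas are always assembled from the two 15°
hemifield halves, never double counted.

## Synthetic cortex

Areal cortical magnification is modelled as

    M(ecc, θ) = M0 · (A / (ecc + e2))² · (1 + α·cos 2θ − γ·sin θ)

the standard inverse-linear eccentricity fall-off (defaults A = 17.3 mm,
e2 = 0.75°, which give ~1400 mm² of V1 per hemisphere within 8°) times the
minimal angular modulation producing independent horizontal–vertical (α)
and vertical-meridian (γ) asymmetries.  `MagnificationModel.from_asymmetries`
inverts the closed-form ±15° wedge integrals so that planted HVA/VMA index
values (difference over mean, ×100) are exact analytic properties of the
model: the wedge mean of cos 2θ over ±15° is sin 30°/(π/6) and of sin θ
over the upper wedge is 2·sin 15°/(π/6).

A hemisphere mesh is a log-eccentricity × uniform-angle grid mapped to a 2-D
cortical sheet whose Jacobian equals M(ecc, θ) exactly: the radial
coordinate is the integral of the linear magnification and the tangential
coordinate is m(ecc)·ecc times the integral of the angular modulation.
Because the radial coordinate depends only on eccentricity, the areal
distortion of the map is exact in the continuum; triangulated vertex areas
(one third of incident triangle areas) converge to it with resolution.  The
default resolution is 96 rings × 145 spokes over 0.2°–12°, at which a ±15°,
1–8° wedge measured by the full distance-map procedure is within ~1% of the
closed-form integral.  Pial and white surfaces are emulated as per-vertex
area scalings of the midgray mesh (global factors 1.2 / 0.85 plus a smooth
anticorrelated gyral/sulcal-like modulation), since the analysis consumes
only vertex-area maps per depth.  Mesh construction is deterministic.

## pRF model and fitting

The forward model is a circular 2-D Gaussian (x, y, σ) multiplied pointwise
by the binary bar aperture (a 3.1°-wide bar sweeping a 12.4°-radius disc in
eight 24-step, 1-s-per-step sweeps; diagonal sweeps blank in their second
half; 192 frames total), summed over the field and convolved with a
difference-of-two-gammas HRF (five parameters; canonical defaults: delays 6
and 16 s, unit dispersions, peak:undershoot 6; unit-peak normalized).  The
sweep order and start angles are fixed in config — fits are invariant to
sweep order given the full design matrix — and only the contrast aperture
enters the model, not the carrier textures.

Fitting is coarse-to-fine: an exhaustive grid (eccentricities 0 plus 8
log-spaced values to 11°, 16 angles, 6 log-spaced σ from 0.25–6°) with the
optimal non-negative gain and free offset per candidate in closed form,
followed by Nelder-Mead refinement of (x, y, log σ) from the best grid
point.  The initial simplex uses fixed degree-scale steps (0.8° in x/y,
0.4 in log σ) so refinement cannot stall when a start coordinate is exactly
zero, and a short restart from the optimum polishes premature convergence;
tie-breaks on the grid go to the first minimum in iteration order.  R² is
computed against the mean-removed series, clipped to [0, 1]; vertices with
R² ≤ 0.10 are excluded from all downstream analyses.  Negative-gain
solutions are rejected because the model assumes aperture-driven positive
responses.  On noiseless simulated data the estimator recovers (x, y, σ) to
better than 10⁻³ degrees.

Synthetic BOLD is the forward prediction per vertex (σ from an
eccentricity-scaled size map, 0.25° + 0.16·ecc, typical of V1) plus i.i.d.
Gaussian noise; no drift or physiological noise is simulated, so no
detrending beyond mean removal is applied anywhere.

## Wedge-ROI surface areas

Meridian line-ROIs are automated: included vertices within 2° of the
meridian, thinned to one vertex per log-eccentricity bin.  Cortical
distance is multi-source Dijkstra along mesh edges — deterministic,
dependency-light, and accurate to one edge length, which is below the
pooling variability; an exact polyhedral-geodesic backend could be swapped
in behind the same contract.  The 1–8° range is split into 10 log-spaced
bands; per band, the cortical distance of the 15° iso-angle line is the
mean distance of included vertices whose pRF angles fall within ±8° of the
15° boundary (the pool is the angular band [7°, 23°]; whether the "±8°"
pool should instead be symmetric in distance is ambiguous, and the angular
reading is implemented).  If a band's pool is empty it is widened once by
+4°; a still-empty band is dropped from the union rather than silently
interpolated, which would bias areas.  Vertices with excluded fits never
enter pools or masks.  Band membership uses each vertex's pRF eccentricity
(ground truth in synthetic tests).  The wedge mask is the union of the
per-band sub-wedges; its area is the sum of member vertex areas at the
chosen depth.  V1 size uses 0–8° while wedges use 1–8° (the central degree
is excluded from wedges); both are config.

A note on bias: estimating the boundary as the *mean* pooled distance
slightly over-reaches where the angular area density rises away from the
meridian (the vertical meridian under a planted HVA) and under-reaches
where it falls (the horizontal meridian), so strongly anisotropic planted
indices are compressed by roughly one index point in the continuum limit,
plus a discretization term that vanishes with resolution.  At the default
resolution planted 60/25 indices are recovered to within a point.

## Psychophysics simulation

Observers are Weibull 2AFC psychometric functions: P(correct | c) =
0.5 + (0.5 − lapse)·(1 − exp(−(c/scale)^k)), slope k = 3.5 and lapse 0.01
by default (typical contrast psychometric slopes).  The threshold parameter
c* is defined at the 3-down-1-up convergence accuracy p = 0.5^(1/3) ≈ 79.4%,
so staircase estimates are directly comparable to the planted value.

The staircase steps contrast in log10 units: down after three consecutive
correct responses, up after any error; steps halve at reversals and double
after three same-direction steps, with the classical delay of the first
doubling after a reversal that was preceded by a doubled step (the exact
step-placement recipe of the original adaptive procedure is not fully
specified in this setting; reversal-count stepping with these adaptation
rules is the conventional reading).  Defaults: initial level 0.5 Michelson,
initial step 0.3, step bounds [0.01, 0.6], contrast clamped to
(0.001, 1].  A session is five blocks of 50 trials per location, the four
location staircases randomly interleaved within each block.  The threshold
read-out is the mean log contrast over the last six reversals (final level
if fewer) — the estimator itself is a convention, exposed in config — and
sensitivity is the reciprocal of the across-block mean threshold.
Simulated staircases settle at 79.0–79.4% accuracy and recover planted
thresholds to within ~2%.

## Synthetic cohorts

`make_cohort` plants the population structure the statistics assume.  V1
sizes are log-normal with the SD set (via the Blom approximation for the
expected extreme ratio) so the max/min across the cohort is ~2-fold around
a 2900 mm² both-hemisphere mean; total cortex (~2×10⁵ mm²) varies much
less and is only weakly coupled to V1 size.  Per-observer asymmetry
indices are drawn around the group values (defaults 60/25% for surface
area, 50/20% for sensitivity, between-observer SD 15 points — comparable
to the spread seen in individual-differences work) and realized as
location weights 1 ± index/200, which reproduce the group indices exactly
in expectation.  Wedge areas are the observer's V1 share times these
weights times log-normal noise.

Sensitivity couples to local surface area through a power law in log
space: the exponent is chosen so the planted surface-area asymmetries map
onto the planted sensitivity asymmetries under full coupling, and the
`coupling` parameter blends this area-driven component with an independent
behavioral trait carrying its own planted asymmetries (coupling = 1:
sensitivity a deterministic monotone function of area, pooled Spearman
ρ = 1 at zero noise; coupling = 0: independent).  The default coupling of
0.8 with 5% multiplicative noise yields pooled ρ ≈ 0.9–0.98; the noise
level of individual sensitivity estimates is not pinned by any published
value, so it is a parameter rather than an assertion.  Psychometric
thresholds are the reciprocals of the planted sensitivities.

Randomness uses one root seed with per-component child streams (cohort,
behavior, surface measurement, BOLD, nulls), so every stage is
independently reproducible, and a `noise_sd = 0` cohort is the exact
noiseless twin of a noisy cohort with the same seed.

## Statistics

HVA = 100·(H − V)/mean(H, V) with H the mean (sensitivity) or sum (area)
of the two horizontal-meridian measurements and V of the two vertical;
VMA likewise for lower minus upper.  The brain-behavior association is a
pooled one-tailed Spearman ρ over all observer × location pairs (average
ranks for ties).  Two shuffle nulls isolate its sources: one permutes
which observer's sensitivity quadruple is paired with which observer's
area quadruple (location ties preserved — removes between-observer
structure), the other permutes location labels within observers (observer
ties preserved — removes location structure).  This pairing-permutation
reading is the only one under which the two nulls isolate observer vs
location variance; it is exposed as a strategy option, and assignments can
be drawn with replacement instead (the default draws a uniform permutation
per iteration).  Each null runs 10,000 iterations by default; x0.95 is the
95th percentile by linear interpolation, and the observed ρ is called
significant when it exceeds x0.95.  Group-level meridian comparisons use
two-sided paired t-tests with Cohen's d on the differences; equal inputs
return t = 0 and constant non-zero differences are flagged as undefined.
Centering by observer (row means) or location (column means) decomposes
the pooled correlation into its meridian and individual-differences
components; V1 size is optionally normalized by total cortical area.

## Problem sizes and runtime

Defaults are desk scale: 29 observers, 96 × 145 meshes, 200-vertex pRF
recovery diagnostics at 18 × 25 mesh resolution with refinement, 10,000
null iterations.  A full default pipeline runs in under two minutes on one
CPU.  The replicate-based checks in the test suite use 50 pipeline
replicates for asymmetry recovery, 100 staircases × 200 trials for
convergence, 500 noiseless vertices for pRF recovery, and 200 replicates
at 1,000 null iterations for the type-I rate — sizes chosen to keep the
suite fast while leaving Monte-Carlo error well inside the asserted
tolerances.

## What the synthetic data do not emulate

No anatomical folding, MRI physics, physiological or temporally structured
noise, eye movements, aborted trials, or manual ROI editing.  Passing
tests show the *analysis chain* is correct and recovers planted structure
under its own generative assumptions; they cannot show that real cortices
satisfy those assumptions (e.g. the inverse-linear magnification form, the
independence of angular and radial factors, or i.i.d. BOLD noise).  The
interchange reader accepts external per-observer tables of sensitivities
and wedge areas in the documented tidy CSV schema, so the same statistics
can be run on real measurements.
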