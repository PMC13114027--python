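# Methods

## The measurement chain

`cochmap` models the chain from two CT calipers to a per-ear mismatch
statistic and its association with speech outcomes.

**Duct length.** The basal turn of the cochlea is treated as an ellipse
with semi-axes A/2 (diameter through the round window) and B/2
(perpendicular width). Its perimeter is computed with Ramanujan's second
approximation (relative error < 0.05 % at anatomical eccentricities,
verified against numeric arc-length quadrature in the tests) and scaled
by a single factor `eca_scale = 1.417` to the full lateral-wall cochlear
duct length (CDL). The scale is calibrated so the population-mean
calipers (A = 8.7 mm, B = 6.5 mm) give the population-mean CDL of
34.0 mm; it is a config field so any published elliptic-approximation
variant can be substituted. The cochlear height H is carried for
descriptive summaries but enters no computation.

**Angle ↔ arc length.** Electrode positions are reported as insertion
angles from a zero reference at the round-window centre. The cumulative
arc length along the spiral is modelled in closed form as

    L(θ) = L_total · (1 − e^{−bθ}) / (1 − e^{−bΘ}),   θ in radians,

an exponential-decay density: the spiral radius shrinks toward the apex,
so equal angular steps cover shorter arcs. Θ = 900° (2.5 turns) bounds
the map. Two decay calibrations are used: `b_lateral = 0.1025 rad⁻¹`
places a 74.8 % insertion at ≈ 511°, and `b_oc = 0.140 rad⁻¹` (on the
organ-of-Corti spiral, whose length defaults to 0.90 × CDL) places a
511° apical contact at a Greenwood place frequency of ≈ 285 Hz. Both
constants are *calibration*, not anatomy: they stand in for the internal
maps of clinical planning software, which are not published, and are
exposed in `GeometryConfig`. The map is strictly increasing and concave
with exact endpoints, and the inverse is closed-form (round-trips to
1e−9° are asserted by property tests).

**Tonotopy.** Greenwood's function `f(x) = F(10^{ax} − k)` with the
standard human constants F = 165.4 Hz, a = 2.1, k = 0.88. The convention
here is x = relative distance from the **apex** (x = 0 apex, x = 1 base),
so f is increasing in x; an insertion angle is converted to x by taking
the organ-of-Corti arc fraction from the base and complementing it.

**Electrode array and filter bank.** A straight lateral-wall array with
12 equally spaced contacts spanning 23.1 mm (28 mm overall), numbered
apex-first C1…C12; both values are manufacturer-typical defaults and
config fields. The default filter bank spreads 70–8500 Hz over 12
channels with exactly geometric band edges; channel centres are
geometric means of adjacent edges and are apex-aligned (C1 = lowest
band, centre 85.5 Hz; C6 = 631.6 Hz; C12 = 6959 Hz). Pure log spacing is
implemented because that is the stated behaviour of the clinical
default; a custom centre table can be passed as a `FrequencyMap`.

**Mismatch.** Per contact, the absolute semitone deviation
`|12 log₂(f_place/f_center)|`. A degree-4 polynomial is fitted to the
deviations versus angle by least squares (numpy's scaled-domain
`Polynomial.fit`, coefficients converted back to the plain degree basis
for reporting) and evaluated at C6's own angular position — C6 is
"mid-frequency" per ear, not a fixed angle. The statistic is clamped at
zero (flagged) if the smoother dips negative. Absolute deviation is
taken *before* fitting; a `signed_fit` switch fits the signed deviation
and takes the absolute value afterwards — for realistic one-sided
(all-shallow) profiles the two agree. Ears with fewer than five
intracochlear contacts cannot support a quartic and fall back to the raw
C6 deviation with a `fallback` flag; geometrically this requires a
degraded state (dropped contacts), since a basal truncation shallow
enough to leave < 5 contacts also leaves C6 extracochlear, which raises
instead.

With the default maps and realistic insertions every contact is shallow
(place frequency above centre frequency), the deviation is largest at
the apical contact, and the C6 statistic is monotonically non-increasing
in insertion depth — the sign structure that links deeper insertion to
less mismatch.

## Inference

Partial correlation is computed by residualizing both variables on
`[1, covariates]` (ordinary least squares) and correlating the
residuals; this is algebraically equivalent to the
inverse-correlation-matrix form (cross-checked against pingouin in the
tests) and keeps per-covariate diagnostics available. Significance uses
`t = r√(df/(1−r²))` with `df = n − 2 − k` and the exact Student-t tail.
The df convention reproduces the headline transform r = −0.52, n = 35,
k = 2 → p = 0.0019 ≈ 0.002. The two-sample t-test defaults to Student's
pooled-variance form (Welch behind a flag). Family-wise error over the
4 measures × 3 timepoints outcome grid is controlled by Bonferroni:
0.05/12 = 0.00417, printed as 0.0042. Missing scores are removed
listwise per timepoint, so per-cell n follows the attrition counts.

A null simulation (mutually independent x, y and two covariates,
n = 35, 10 000 replicates) confirms the nominal 5 % type-I rate within
±0.01.

## The synthetic cohort

The generator emulates the *summary structure* of a 44-patient
retrospective unilateral-CI cohort; defaults:

| quantity | value | note |
|---|---|---|
| n, sex | 44; 15 M / 29 F | analysis subset 15 M / 20 F |
| age | N(66.6, 16.8) yr, truncated [21, 89] | |
| preop PTA | N(97.2, 20.2) dB HL, truncated [40, 130] | 0.5/1/2 kHz average |
| CDL | male N(34.6, 0.9), female N(33.6, 1.5) mm | mixture ≈ 34.0 ± 1.4 |
| calipers | back-solved from CDL, B/A ≈ 0.747 ± 0.01 | estimator-consistent |
| insertion | length ≈ N(25.4, 1.15) mm, derived coverage ≈ 74.8 ± 4.6 % | see below |
| exclusions | 6 extracochlear + 3 second-CI, exact | assigned among females |
| attrition | 35 → 33 → 27 complete, exact, nested | per timepoint |
| effects | target partial r per measure × timepoint | configurable table |

**Insertion depth is drawn as a length, not a coverage.** Every virtual
ear receives the same array inserted to the same mark, so what varies
between ears is the inserted *length* (surgical variability); coverage
= 100·L/CDL then inherits a negative correlation with CDL, which is the
mechanism behind the observed negative AID–CDL correlation. (Drawing
coverage directly, independently of CDL, would make the angular depth a
deterministic function of coverage alone and decorrelate it from CDL.)
The length distribution's mean and SD are derived from the configured
coverage mean/SD by moment matching at the population CDL distribution.
Draws are truncated below at the contact span (so full insertions keep
C12 intracochlear) and above at 89 % coverage, the value that maps to
≈ 720° at mean CDL — no deeper insertions were observed in the emulated
setting. The truncation trims ~9 % of the lower tail, shifting mean
coverage up by well under one point. The six partial-insertion ears
have their length reduced by a uniform 10–30 % shortfall, capped just
below the contact span so at least one basal contact is genuinely
extracochlear.

**Scores.** Each measure × timepoint score is
`μ + s·(γ_age z_age + γ_pta z_pta + γ_mm z_mm + ε)`, with standardized
covariates, ε ~ N(0, σ²), σ = 1, scale s = 12 points per latent SD, and
γ_age = γ_pta = −0.2 (modest negative confounding; the emulated study
treats them as confounders without printing coefficients). The mismatch
coefficient is solved from the target partial correlation:
`γ_mm = r σ/√(1 − r²)`, which makes the population partial correlation
exactly r because the mismatch is independent of the covariates by
construction. Score means rise with time and with linguistic redundancy
(monosyllable < consonant < word < sentence); sentence scores pass
through a soft ceiling (excursions above 80 % compressed by half), which
puts roughly half of 6-month and two-thirds of 12-month sentence scores
above 80 % — a realistic ceiling for sentence materials. Scores are
clipped to [0, 100]; with the default means and scale, clipping is rare
enough not to measurably attenuate the configured effects.

Parameter recovery: across 500 replicate cohorts the mean estimated
consonant/3-month partial correlation is within ±0.05 of the configured
−0.52, and the empirical spread matches the large-sample approximation
(1 − r²)/√(n − 3) within 25 %.

**What the generator does not emulate:** etiology- or device-specific
effects, within-patient longitudinal correlation of scores (timepoints
share only the structural effects, not residual noise), measurement
error in the calipers, non-linear mismatch–score relationships, and any
absolute-semitone ground truth (no published mean mismatch exists to
calibrate against; the semitone scale is fixed by the geometry alone).
Passing tests therefore validate the *pipeline* — not the clinical
magnitude of mismatch effects in real ears.

## Numerical choices

* Angles in radians internally, degrees at every interface; lengths mm;
  frequencies Hz.
* Spiral and Greenwood inverses are closed-form; round-trip tolerances
  of 1e−9 are asserted, not assumed.
* The quartic is fitted on a rescaled angle domain (numpy's [−1, 1]
  window) purely for conditioning; coefficients are reported in the
  plain degree basis.
* Exclusion and attrition counts are exact by construction; which
  patients they hit is random under the seed. All randomness flows from
  one seed through per-stage `SeedSequence` substreams, so reports are
  byte-identical across reruns.
* Replicate sizes used in stochastic tests (e.g. 500 cohorts for
  recovery, 10 000 null replicates for type-I error) were chosen so
  Monte-Carlo error is several times smaller than the asserted
  tolerance.
* Degenerate inputs fail loudly: over-long insertions, extracochlear C6,
  collinear covariates (the offending column is named), zero-variance
  vectors, unknown exclusion codes (offending rows listed).

## Known limitations

* The elliptic scale factor and both spiral decay rates are calibrated
  stand-ins for unpublished software internals; absolute angles and
  place frequencies away from the calibration anchors carry model error.
* The organ-of-Corti length ratio (0.90) is a fixed default, not fitted.
* Contact spacing is assumed equal; real arrays taper slightly.
* "Inserted length" is interpreted as the arc position of the apical
  contact plus the contact span — whether a clinical report means full
  array length or active span for partial insertions is ambiguous, and
  partial-insertion ears are excluded from analysis anyway.
* The mid-array summary contact is fixed at C6; for extreme geometries
  its place can drift outside 1–2 kHz (the profile records whether it
  does).
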