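# Methods

This note documents the models behind `wpqa`: what is simulated, which
parameters matter, which numerical choices were made where the design was
genuinely open, and what the synthetic cohorts can and cannot say about real
QA data.

## Coordinate and unit conventions

Phantom frame with the origin at the center of the water-phantom entrance
window at isocenter.  Axis A is the longitudinal axis (depth in water), B
vertical, C lateral; the beam enters along +A, perpendicular to the phantom
surface.  All lengths are mm, doses Gy, gradients mGy/mm, deviations percent
of the whole-field maximum dose D_max.  Dose grids are isotropic (1 or 2 mm,
2 mm default) with voxel centers at `origin + (i + 0.5) * spacing`.

## Synthetic dose engine

The depth-dose curve per beam energy is an analytic stand-in chosen for
physical plausibility, not for fidelity to any measured beam database: the
sum of an asymmetric Gaussian peak and a gently rising entrance plateau cut
off distally by a complementary error function on the same length scale as
the distal fall-off.  Parameters per ion (defaults in `ION_DEFAULTS`):

| parameter | proton | helium | carbon | meaning |
|---|---|---|---|---|
| entrance_to_peak_ratio | 0.30 | 0.28 | 0.25 | plateau dose / peak dose |
| peak_width (mm) | 8 | 6 | 5 | proximal half-width of the peak |
| distal_falloff (mm) | 4.0 | 2.5 | 1.8 | 80 %→20 % distal distance |
| idd_peak (Gy·mm²) | 1.6e-6 | 6e-6 | 2.5e-5 | integral depth dose per particle at the peak |

The peak sits one distal-falloff proximal to the nominal range, so the
distal 80 % level lands near the nominal range.  `idd_peak` values are
order-of-magnitude stopping-power estimates; absolute dose scale is absorbed
by the optimizer weights, so only their ratios matter.  Supported ranges are
2–300 mm water-equivalent.

A field's dose is the superposition over spots of
`N_spot x IDD(depth) x G2D(lateral offset; FWHM)` with a normalized 2D
Gaussian lateral profile — exactly linear in every spot's particle number,
translation-equivariant, with no nuclear halo, lateral scattering growth
with depth, or RBE weighting (all out of scope).  Minimum spot FWHM is 8 mm
(protons) and 6 mm (helium, carbon).

**SOBP optimizer.**  Bragg peaks are placed across the target depth interval
at a layer step of `min(2.5 mm, peak_width / 2)` (a 5 cm target then uses
roughly 20–30 layers); spots form a square lateral grid at FWHM/2 spacing
covering the target circle plus a 1.5 x FWHM margin.  Per-layer weights are
solved by non-negative least squares against the prescription on a 1 mm
central-axis sampling of the target — deterministic, no iteration-order or
random-seed dependence.  A simple multiplicative fixed-point iteration was
tried first and rejected: with heavily overlapping proximal peak shoulders
it fails to converge and leaves several-percent distal ripple.  The NNLS
solution keeps the central axis flat to within about ±2 % of the
prescription and the target-volume mean within 1 %.

**Range shifter.**  Modeled purely as a water-equivalent range shift applied
to every layer; optional linear FWHM broadening with thickness exists but is
off by default (scattering physics out of scope).

## Chamber stack and measurement model

The stack holds 24 chambers in 6 rows of 4, rows 12 mm apart along depth,
chambers 12 mm apart laterally, rows cycling over three height levels
(−10, 0, +10 mm) so no two chambers overlap (exact PinPoint-stack
coordinates are not published; these are documented plausible stand-ins).
Each chamber has a 30 mm³ sensitive volume modeled as a box
(2.9 x 2.9 x 5 mm) — a deliberate simplification of the cylindrical
volume — integrated by 3x3x3 Gauss–Legendre quadrature of the trilinearly
interpolated dose.  Planned doses are trilinear interpolations at the
effective points; the effective-point offset defaults to 0 (the grid is
taken to live at the effective point already).

A simulated reading is

```
measured_i = volume_avg(dose at displaced position_i)
             x (1 + calibration_bias) x (1 + noise_i) + background_offset
```

with one shared positioning draw per session (the stack is positioned
once), independent multiplicative per-chamber noise (readings scale with
dose), and a single additive background offset per session whose default in
the mechanistic generator is slightly negative (−0.5 mGy), reflecting the
way background subtraction biases low-signal multichannel readouts.  kQ
(1.026) and the air-density correction are carried as metadata and treated
as exactly compensated; they enter only through the gross human-error modes
(wrong calibration factor: +5 % default; wrong positioning: a 5 mm B/C
offset; wrong air gap: a 3 mm depth shift).  With all error terms zero and a
point-like sensitive volume the simulation returns the interpolated planned
doses exactly — the zero-error fixed point used throughout the tests.

## Verification rules

Gradients are central differences over the six ±1-voxel neighbors of the
voxel enclosing the chamber position, reported as the Euclidean norm of the
three components (the per-component maximum is available via configuration;
which scalar the clinical system uses is not specified, and the norm is the
conventional choice).  A chamber is deactivated when its gradient in mGy/mm
exceeds `fraction x D_max` with D_max in mGy — i.e. the default 0.05
threshold reads "5 % of D_max per mm".  Boundary equality keeps a chamber
active, and a chamber whose gradient stencil leaves the grid is deactivated
with gradient +inf rather than erroring the whole field.

Deviations use the *whole-grid* D_max, not the maximum over the chamber
subset.  The SD is the sample SD (n−1), zero for a single active chamber;
zero active chambers raise an explicit "no evaluable chambers" error.
Pass/fail applies |mean| ≤ 5, min ≥ −7, max ≤ +7 with inclusive boundaries
(benefit of the doubt on exact equality).  The repeat policy is: pass →
accept; first failure → repeat; persistent failure → accept with
justification only when at most k (default 2) chambers exceed ±7 % and all
of them sit above the 0.75 gradient quantile of the field, else adapt the
plan.  The count "a few chambers" is not quantified in clinical practice;
k is configuration, not a truth claim.

## Adapted-plan and integrity rules

The ATP check requires: same ion species (short-circuits), fraction dose
equal to 1e-6 Gy, same field count, couch/gantry angles within 10° on the
circle (shortest arc), same modifier set within 100 mm, at most 20 new
energy levels relative to the original (the one intentionally asymmetric
rule), total particle number within 20 % — measured as a symmetric relative
difference so the rule reads identically from either side — and optimization
metadata equal within 10 % relative ("comparable field contributions" is
qualitative in practice; this formalization is a design choice).  A
per-field particle-number bound is not implemented because no bound is
stated anywhere; only the total is checked.  The integrity check compares
the transfer-sensitive tags (approval status, plan label, review timestamp,
patient identifiers, field names, spot count, particle-number tuples,
modifiers and positions, isocenter positions) exactly, reporting missing
tags as `tag (absent)`.

## Cohort statistics

Sample SD (n−1) throughout.  α = 0.01.  Shapiro–Wilk normality is computed
and reported but never gates the one-sample t-test (robustness for large
symmetric samples); the strongly asymmetric per-field minima/maxima use the
Wilcoxon signed-rank test instead.  Two-group comparisons gate pooled vs
Welch t by Levene's test at the same α; more than two groups use one-way
ANOVA with Tukey HSD pairwise only when the ANOVA is significant.  No
multiple-testing correction beyond Tukey is applied — a deliberate mirror of
standard QA-report practice.  Report rendering rounds deviations to 0.1 %
and pass rates to the integer.

Time accounting adds fixed overheads — TPS preparation 15 min and analysis
10 min per verification, phantom setup 30 min and pre-irradiation 5 min per
session — to the summed per-field beam times.

## Synthetic cohorts

**Parametric generator.**  Each field draws its category labels
independently per axis (room 59/41 Hx/Ga, ion 51.7/47.2/1.1 % p/C/He, TPS
77/23 Syngo/RayStation, range shifter 25 %, eight indications dominated by
head at 68 %, yearly proportions from the cohort's yearly counts — whose
printed sum, 22838, differs from the stated total of 23014; the proportions
are renormalized and all reported totals here are internally consistent).
The field-mean deviation is Normal(−0.5, 0.9) % of D_max by default, or
per-level of one designated axis after `calibrate_from_summary`.
Per-chamber residuals are a two-component normal mixture — core SD 1.6 %,
wide component SD 6 % with weight 0.028 — *centered within each field*, so
the recorded field mean equals the drawn field-level mean exactly; the
mixture is tuned so roughly 0.7 % of active-chamber deviations fall outside
±7 %.  The number of active chambers is Normal(21, 2) rounded and clipped to
[1, 24]; irradiation times are log-normal with mean 204 s and SD 117 s
(log-normal keeps positivity); stack positions and target volumes are drawn
from wide plausible ranges (depth 20–250 mm, volumes 10–10000 cm³,
log-normal).  3 % of fields receive a repeat measurement whose residuals
correlate 0.8 with the original; 0.5 % are flagged as human-error sessions
and excluded by the standard pipeline.  Pass flags are always *recomputed*
from the tolerance rules, never sampled.

Because the residual mixture is iid across chambers, the implied field-level
fail rate (~13 %) is higher than the ~9 % a real cohort shows at the same
chamber-level tail rate — in real data the outliers cluster within a few
highly modulated fields.  Matching both rates simultaneously would require
field-level tail clustering; the simpler iid model was kept because the
cohort-level mean/SD recovery and the tail calibration, not the pass rate,
are the quantities the generator is specified to reproduce.

**Mechanistic generator.**  Desk-scale (default 20 fields, 2 mm grids,
200 x 120 x 120 mm phantom): per field an SOBP target (depth center
70–120 mm, length 30–50 mm, diameter 40–60 mm, 2 Gy) is optimized, the
grid computed, the stack centered on the target, and a sampled error model
(positioning SD 0.3 mm, noise SD 0.6 %, background −0.5 mGy, calibration
bias Normal(−0.4 %, 0.6 %)) applied before the full verification pipeline
runs.  Those defaults yield per-field mean deviations scattering slightly
negative within about ±1 % of D_max.  Problem sizes throughout (20-field
cohorts, 2 mm grids, 9³–11³ oracle grids, 2500-replicate null calibrations)
are chosen as the smallest sizes at which the checked properties are
statistically meaningful.

## What the synthetic data does not show

The generators reproduce the *statistical shape* of a QA cohort
(per-category moments, activation counts, tail frequency, times), not the
physics of any clinical beamline: no TPS dose algorithm, no fragmentation
tails, no spot-position or monitor-calibration drifts, no inter-field
correlation within patients, and the per-chamber joint distribution is one
admissible choice among many, since only summary moments are publicly
printed.  Passing tests therefore validate the pipeline's rules and
statistics, not dose-calculation accuracy on real fields.
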