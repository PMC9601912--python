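# Methods

## The test and its geometry

The reference template is an Archimedean spiral: radius affine in the
unwrapped polar angle, r(θ) = r_in + (r_out − r_in)·(θ − θ₀)/Θ with
θ₀ = 90° (screen top) and sweep Θ = 720° (two counterclockwise turns,
drawn inward-out).  Consecutive turns are therefore a constant
(r_out − r_in)/2 apart.  Angles are measured in a y-up frame; because
screen y grows downward, screen coordinates are x = cx + r·cosθ,
y = cy − r·sinθ.  The default template is centered on a 1280 × 800 px
screen with inner radius 20 px and outer radius
min(width, height)/2 − 50 px = 350 px.  The source app publishes the start
angle, the sweep, and the screen resolution but not the radii; 20/350 px
keeps the drawn figure filling the screen height with a comfortable margin,
and both values are constructor parameters.

## Angle assignment

Each trace sample is matched to the template point at the same unwrapped
polar angle about the spiral center.  The angle accumulates wrapped atan2
increments (each step mapped to (−180°, 180°]), pinned so the first sample
is exactly θ₀.  Two clamps keep the correspondence single-valued:
backtracking (negative increments) is clamped to the running maximum, and
angles past θ₀ + Θ are clamped to the sweep end, so doodling after
completion cannot inflate the score.  A sample exactly at the center has no
angle and is an error, as is a trace covering less than 10° of sweep.
The alternative of matching by arc length or by sample index was rejected:
only the polar-angle reading makes "the angle of the first point is 90°"
exact, and it is the only correspondence under which the template itself is
a fixed point of the scoring (SD = 0).

## Spiral Deviation

The area between the drawn and reference curves matched by angle is the
polar area element integral ½∮|r_d(θ)² − r_ref(θ)²| dθ, evaluated by the
trapezoid rule over the per-sample angles (duplicate angles from clamped
backtracking contribute zero width).  Absolute rather than signed radial
differences are integrated: signed differences would let inward and outward
excursions cancel, which contradicts the notion of a deviation.  For points
matched at equal angle the radial and Euclidean point-to-point distances
coincide, so "distance between matched points" and "area between the
curves" agree.  SD = area / (screen width · height) × 10,000.

Numerics: the trapezoid rule is exact for radius perturbations affine in θ
and is second-order for smooth paths — doubling the sample count cuts the
error roughly fourfold (the tests assert at least a halving).  At 500
samples over the full sweep a smooth path is scored to well under 0.5%.

## Total Time and Pen Pressure

TT = (t_last − t_first)/1000 s — exact arithmetic, translation invariant.

PP = Σᵢ area(pᵢ)·max(0, pᵢ − f_typ).  f_typ defaults to 1.45 N, the
midpoint of the 1.4–1.5 N typical handwriting band, so typical writing
scores ~0.  The pixel footprint model is area(p) = 1 + round(k·max(0,
p − f_typ)) px with k = 100 px/N: the rendered line thickens with force,
but no law for the footprint is published, so a minimal linear model is
used and both parameters are configurable.  PP is nondecreasing in every
sample's pressure and exactly 0 when no sample exceeds f_typ.

## Simulator

A subject is a set of drawing parameters; a trace is generated at a fixed
sample rate (default 120 Hz, comfortably above Nyquist for 6 Hz tremor —
enforced) with the angle advancing at constant angular speed ω, so
TT = 720/ω exactly.  The drawn radius is

r(θ(t)) = r_ref(θ(t)) + a·sin(2π f t + φ) + w(t)

with sinusoidal tremor (f uniform in the parkinsonian 5–6 Hz band, phase φ
random per subject) and w(t) a stationary Ornstein–Uhlenbeck wobble
(exact discretization; correlation time 0.5 s) that gives every subject,
healthy included, a smooth nonzero deviation.  Pressure is
base + max(0, excess + OU noise).  Tremor frequency is recovered from a
trace as the dominant periodogram peak of the radial residual
(r_drawn − r_ref) in a 3–10 Hz search band; the band excludes the
low-frequency wobble while bracketing the tremor band.  Recovery is within
±0.25 Hz for amplitudes ≥ 2 px at 120 Hz sampling.

### Cohort profiles and calibration

The default cohort mirrors the published study design: 12 patients
(4 F: 2 per age band 40–50/50–60; 8 M: 4 per band) and 12 controls
(6 F and 6 M, 3 per band).  Per-subject parameters are drawn from clipped
normal distributions.  Defaults:

| parameter | healthy | patient |
|---|---|---|
| total time (s) | 12.7 ± 5.15 | 20.1 ± 7.1 |
| wobble SD (px) | 1.65 ± 0.30 | 1.65 ± 0.30 |
| tremor amplitude (px) | 0 | 1.0 ± 0.5 |
| tremor frequency (Hz) | — | U(5, 6) |
| pressure base (N) | 1.0 | 1.45 |
| pressure excess (N) | 0 | 0.40 ± 0.11 |

These values were **calibrated** (wobble analytically, then refined
against simulated group means; pressure excess likewise) so that default
cohorts land near the published group statistics: healthy SD ≈ 30 and
patient SD ≈ 33 "% pixels", TT 12.7 vs 20.1 s, patient PP ≈ 4.8 × 10⁴
N·px.  This is calibration of the generator to the study's reported
conditions, not validation: the raw per-subject data behind those
summaries was never published, so agreement in distribution cannot be
checked.  Two deliberate idealizations: the patient tremor amplitude is
small (≈1 px) because resting tremor largely abates during voluntary
movement — which is also why the published spiral-deviation gap is small
and non-significant — and healthy peak force stays below f_typ so healthy
PP is exactly 0, where the published healthy mean is a tiny unexplained
0.0191 N·px.  Consequently, passing tests show the pipeline reproduces the
*pattern* (TT and PP separate groups; SD does not) and the scale of the
published summaries, not their exact values, and say nothing about e.g.
pen-slip artifacts, pauses, or lifted-pen gaps in real traces, which the
simulator does not model.

All randomness flows from a master seed through `numpy` `SeedSequence`
spawning, so a cohort is bit-reproducible (identical CSV bytes) from its
seed.

## Inferential layer

Group summaries use the sample (n−1) standard deviation and SEM = sd/√n.
Both t-tests are computed from summaries alone: pooled
(se² = s_p²(1/n₁ + 1/n₂), df = n₁ + n₂ − 2) and Welch
(se² = s₁²/n₁ + s₂²/n₂, Satterthwaite df), each with two-sided p from the
central t distribution and 95% CI = Δ ± t₀.₉₇₅,df·se.  The two variants
coincide whenever n₁ = n₂ and s₁ = s₂.  Degenerate inputs: zero se with
nonzero mean difference reports t = ±∞ with p = 0; zero/zero is an error at
the operation level and an "undefined" row in table reports.  Levene's test
is mean-centered (the classical definition and the default of the
statistics package whose output layout the reports mirror); it is a
one-way ANOVA on |x − group mean| and genuinely requires raw values, so
the summaries-only path reports it as unavailable rather than
approximating it.

### Reference-table reproduction and tolerance policy

The bundled reference tables are printed at 4–5 decimals.  A recomputed
cell is compared with the printed one at: 1 unit in the last printed digit
(1.5× for float slack), **plus** first-order propagation of the printed
inputs' own rounding through the formulas (e.g. the t of the healthy
age-band PP comparison is uncertain by ±0.019 because the group means are
printed to only 4 decimals while their difference is 0.0007), **plus** a
1e-5 relative floor covering transcription precision of large magnitudes
(one printed mean difference of ≈4.8 × 10⁴ disagrees with the printed
means' difference by 3 × 10⁻⁴ in the source itself).  Under this policy
all 206 comparable cells match.  Four printed cells contradict their own
row (a dropped minus sign on a mean difference, twice; a dropped leading
digit in a CI bound; a CI bound copied from the preceding table); they are
flagged as misprints with explanatory notes and excluded, never compared.

## Problem sizes

Defaults throughout are the study's own sizes (12 vs 12 cohorts, ~1,500–
2,400 samples per trace at 120 Hz).  Stochastic checks use 20 seeded
traces for tremor recovery and 21 replicate cohorts for the significance
pattern; at n = 12 per group single-cohort significance is itself a coin
with known bias (the TT effect size gives ≈0.8 power at α = 0.05), so the
tests assert majorities over replicates rather than a single cohort's
p-values.

## Known limitations

* The simulator draws at constant angular speed and constant-rate sampling;
  real drawings pause, lift, and vary speed within a trace.
* The pixel-footprint law of the pen and the tiny nonzero healthy PP of the
  source study are unknown; both are modeled by declared convention.
* Levene F/Sig values of the reference tables cannot be validated, only
  displayed.
* The scorer assumes the trace is a single continuous attempt at the
  spiral; it does not segment multiple attempts.
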