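# Methods

## Targeting geometry

A trial is a segment `entry + t·direction·depth`, `t ∈ [0, 1]`, scored
against a spherical target (centre, radius R, all in mm). The measures:

- **Closest approach `d`** uses the *clamped* segment, not the infinite
  line: a drain that stops short of the ventricle did not reach it, so the
  tip-to-centre distance is the clinically meaningful error. The infinite-
  line distance `d_line` is exposed separately because the chord identity
  `R² = (E/2)² + d_line²` holds for the line, not the clamped distance.
- **Engagement `E`** solves the line–sphere quadratic and intersects the
  chord interval with the segment, so partial entries and interior endpoints
  are handled exactly.
- **Distance metric `D = R − √(R² − d²)`** is represented component-wise
  (`real_part`, `imag_part`, derived `magnitude`, `outside` flag) rather
  than as a native complex number, keeping the miss flag explicit and the
  value serialization-safe. For `d > R` we continue the square root on the
  principal branch, `D = R − i√(d² − R²)`, choosing the negative imaginary
  sign as a documented constant (all tests use `|imag_part|`). This gives
  `|D| = d` for every `d ≥ R`, continuity at the wall, and monotone `|D|`.
  An alternative convention sometimes quoted for the just-outside case,
  `D = iR`, is *not* adopted: it contradicts the analytic continuation of
  the defining formula and would make `|D|` discontinuous in the miss
  distance; the continuation keeps the metric well-posed.
- **Angulation** projects both directions onto the sagittal and coronal
  planes and reports the unsigned angle in [0, 180]°. The anatomical frame
  defaults to RAS (x right, y anterior, z superior; sagittal normal x,
  coronal normal y) and is configurable. A direction orthogonal to a plane
  has no in-plane heading and raises a degenerate-projection error rather
  than returning an arbitrary angle.
- Degenerate inputs (zero/non-unit direction, depth ≤ 0, R ≤ 0, negative d)
  are hard errors; nothing is silently normalised.

## Rubric emulation

The consultant's 1–6 index of accuracy is emulated in two ways.

`extract_features` + `assign_ia` implement the verbal clauses with explicit
thresholds: inside ⇔ `d < R`; near-wall ⇔ inside and `R − d ≤ 0.2R`;
good angle ⇔ max(sagittal, coronal) ≤ 10°; slightly outside ⇔
`R ≤ d ≤ 1.5R`; wide miss beyond. The three numbers (0.2, 10°, 0.5) are
calibration knobs exposed in configuration — the verbal rubric carries no
numbers, so these defaults are stand-ins to be re-fit against real expert
rankings. Two clause readings were genuinely open and are resolved as:
an inside-near-wall trial with a good angle scores 2, not 1 (wall proximity
dominates); and for wide misses the good angle takes the lower score (5),
parallel to the slightly-outside 3/4 pattern.

`ia_from_normalized_D` is the complementary angle-blind view: a
non-decreasing step map from `|D|/R` (plus the miss flag) onto {1,…,6} with
breakpoints 0.8 (inside), 1.5 and 2.5 (outside). Band 4 is unreachable
without angle information, by construction. The map is versioned as the
package's stand-in for the unspecified monotone rank–metric relationship
and is meant to be replaced by a calibration when expert labels exist.

## Same/different session scoring

Per-participant summaries count errors and average *correct-trial* RTs per
truth class (subjective reports of correct-report times are the tabled
quantity); a class with no correct trials carries an explicit missing value,
never zero. The population index of difficulty of a stimulus pair is the
number of participants who misjudged it. RT-vs-difficulty lines are fitted
by least squares on per-pair mean correct RTs (per-stimulus aggregation;
raw-trial regression is available as an option), separately for same-truth
and different-truth stimuli; the same/different gap is the difference of
population mean correct RTs. The speed–accuracy association is a Spearman
rank correlation (small cohorts, ordinal error counts) of error count
against pooled mean correct RT, with the least-squares slope reported
alongside.

Conditioning on correct trials biases the gap estimator slightly upward
(errors remove more slow, hard-pair trials from the "different" class,
whose correct-response probability is lowered by the "same" bias); at the
reference conditions the bias is ≈ 0.07 s against a bootstrap CI half-width
of ≈ 0.12 s, so the generating penalty stays within the interval.

## Performance indices and correlation

Both tasks are fused the same way: accuracy component in [0, 1] divided by
mean completion time. For EVD targeting, accuracy is
`mean(1 − min(|D|/D_max, 1))` with `D_max = 3R` by default — a documented
sensitivity knob capping unbounded misses. For the spatial task, accuracy is
`1 − errors/trials` and time is the pooled mean correct RT. Accuracy per
unit time is the simplest composite consistent with scoring a task phase by
its speed and error rate; both raw components are always emitted so
alternative composites (or single-margin "objective scores") can be formed
without re-scoring. The cohort association is Spearman by default with a
seeded 2000-resample bootstrap percentile CI — asymptotic intervals are not
trusted at n ≈ 25–53. Both margins (EVD index vs spatial accuracy alone and
vs mean RT alone) are reported next to the composite.

## Synthetic cohort generator

One scalar latent ability `θ_i ~ N(0, 1)` per trainee drives both tasks;
that single-factor structure is the analysis's working construct, and
multi-factor abilities are out of scope. Reference conditions: 25 trainees,
10 targeting trials each, 48 same/different trials over 24 base pairs (each
pair has a "same" and a "different" version, seen once each, so classes are
balanced and each stimulus contributes at most one record per participant).

Targeting: target centres are placed uniformly in a ±20 mm workspace with
R = 10 mm; the entry point sits 80 mm away (a typical burr-hole-to-ventricle
lever arm) in a random direction. The aim point scatters isotropically
around the centre with sd `6·exp(−coupling·θ)` mm, the insertion axis gets
2° of angular execution jitter, and the catheter is advanced exactly to the
aim point. Task time is log-normal, median 30 s, log-sd 0.3, with log-median
slope `−coupling·0.2·θ`. The `coupling ∈ [0, 1]` knob gates **every**
ability→targeting pathway (aim scatter *and* time), so `coupling = 0` is a
true ablation in which targeting is statistically independent of ability —
the property the uncoupled null check relies on.

Same/different: base-pair difficulties span a linear grid on [−2, 2]. The
perceptual comparison fails with probability
`logistic(difficulty − θ − 1.0)`; on failure the participant guesses,
choosing "same" with probability `0.5 + bias_same` (default 0.7) — a
lapse-plus-biased-guess model that yields the observed asymmetry between
"said same to different pairs" and the reverse. RT is
`3.0 + 0.5·difficulty + 2.0·1[truth = same] + 0.12·θ + N(0, 1)` seconds,
truncated below at 0.25 s (truncation, not rejection, so the trial count is
exact). The 2 s same-penalty is the exhaustive-search account: a "different"
verdict can fire on the first discrepancy, a "same" verdict only after the
search is exhausted.

The caution slope (0.12 s per ability unit) was calibrated once, by a
design-phase power analysis, to balance two requirements the cohort
structure must satisfy simultaneously: careful (high-θ) responders must be
slow enough that the population error-vs-RT correlation is reliably
negative, yet not so slow that the RT denominator cancels the accuracy
signal in the spatial composite (both components rise with θ). At 0.12 the
speed–accuracy statistic is negative in ≈ 96% of seeded 25-trainee cohorts
while the composite still tracks ability.

All randomness flows from a single `numpy.random.default_rng(seed)`, so a
(config, seed) pair reproduces the cohort bit-for-bit across platforms.

### What the generator does and does not emulate

It reproduces the *statistical couplings* the analysis assumes — shared
latent ability, difficulty-dependent errors and RTs, the "same" response
bias, the same/different RT gap, heavier-tailed task times — with balanced
designs and stationary behaviour. It does not model learning across trials,
fatigue, anatomical variation beyond a random sphere pose, non-spherical
ventricles, multi-factor abilities, or strategic speed–accuracy shifts
within a session. Passing parameter-recovery tests therefore demonstrates
that the *pipeline* recovers known structure from data of the assumed form,
not that real trainee cohorts have that structure.

## Problem sizes and statistical checks

Simulation-based checks use: 200 seeded 25-trainee cohorts for the
speed–accuracy sign rate; 100 paired seeds per coupling value
{0, 0.3, 0.6, 0.9} for monotonicity of the mean recovered correlation
(paired seeds share abilities and noise draws across couplings, shrinking
the comparison's variance by an order of magnitude); and 100 seeded
53-trainee cohorts (the full-cohort size) for the detectability study,
where a coupled cohort's bootstrap CI excludes zero in ≥ 90% of runs and an
uncoupled one covers zero at ≈ the nominal rate. At the 25-trainee default
the coupled composite correlation (≈ 0.6) is *not* reliably detected by a
95% bootstrap CI (≈ 75% of runs) — a power limitation worth knowing before
running a real 25-person cohort.

## File formats

Every CSV begins with `# schema: <name> v<version>`; readers reject unknown
names/versions. The simulator log is UTF-8, tab-delimited, one event per
line: ISO-8601 millisecond timestamp, participant id, trial id, event
label, JSON payload; timestamps are non-decreasing within a session.
Malformed log lines become per-line diagnostics, never silent drops; a file
with no parseable trial lines is an error, an empty file a warning. Floats
are written at 6 significant digits, with a full-precision option for
lossless round trips. Config precedence is CLI flag > config file > default,
and each run logs a config hash and the seed.

## Known limitations

- The rubric thresholds and the |D|/R step map are uncalibrated stand-ins;
  ranks they produce are internally consistent but not validated against a
  real expert.
- The composite index weights accuracy and speed by simple division;
  cohorts that trade them differently (e.g. uniformly cautious trainees)
  would need the reported raw components instead.
- The gap estimator conditions on correct responses and inherits the small
  selection bias quantified above.
- Spherical targets only; mesh-based ventricle geometry is out of scope.
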