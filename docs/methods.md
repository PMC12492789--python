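# Methods

## Processing model

The package operates on *activity counts*: dimensionless non-negative
integers per second and axis, linearly related to movement intensity, as
produced by standard count-generation software from 30 Hz accelerations.
Count generation itself is out of scope; `todacc` starts at the per-second
count stream and assumes a strict, gap-free 1-s grid in naive local time.
Device-off periods are represented as explicit zero rows (the convention
produced by idle-sleep-mode zero imputation), never as missing rows, which
keeps every downstream epoch grid regular.

### Epochs and vector magnitude

Epoch sums are taken over half-open windows `[t, t + L)` with `L ∈ {5, 15,
60}` s, anchored at local midnight so that epochs nest inside minutes and
calendar days.  Partial epochs at either end of a (truncated) stream are
dropped; over the retained whole epochs, axis totals are conserved exactly.
The vector magnitude is computed from the epoch-level axis sums,
`VM = √(x_sum² + y_sum² + z_sum²)`, not by summing per-second magnitudes.
The order of operations matters (the norm is not additive); computing VM
from epoch sums is the standard count-processing convention and makes VM
well defined at any epoch length.

### Protocol truncation

Recordings are truncated to the parent-logged wear window with a symmetric
margin (default 60 min, reflecting log uncertainty).  The retained interval
is closed on both ends; the choice between closed and half-open is
immaterial at the day scale but is fixed so that boundary behaviour is
testable.

### Non-wear detection

Non-wear is inferred on the minute-level VM series (built by reintegration
at 60 s): maximal runs of zero-VM minutes of at least `min_window_min`
(default 20) are non-wear, and an interior non-zero run of at most
`spike_tolerance_min` (default 2) minutes does not break an interval
provided each side shows at least `spike_flank_min` (default 30) zero
minutes.  The 20-min window is conservative for children, for whom more
than ~17.5 min of genuinely motionless wear is implausible.  The spike
tolerance is inclusive (a run of exactly 2 minutes is tolerated) and
exposed as a parameter.  Three conventions the minute-based rule does not
itself determine are fixed as follows:

* a flank truncated by the series boundary counts as satisfied when it is
  all zeros; leading/trailing spikes join nothing and always remain wear;
* "zero minute" means VM exactly 0 (counts are integers; no tolerance);
* the minute-level decision is projected to 5-s/15-s epochs by epoch-start
  membership — an epoch is non-wear iff its start lies inside a detected
  interval.

With `spike_tolerance_min = 0` the rule degenerates to plain run-length
thresholding, which the tests exploit as an oracle check.

### Classification

SB iff `value ≤ sb_max`, LPA iff `sb_max < value ≤ lpa_max`, MVPA above,
with the published integer thresholds (Trost VA 25/419 at 15 s; Costa VA
5/164 and Costa VM 96/361 at 5 s).  The same inequalities are applied to
the real-valued VM; on integers they reproduce the printed bands exactly,
and where an epoch VM falls exactly on a threshold it goes to the lower
band, consistent with the integer convention.  Each cut-point set is only
ever applied at its calibration epoch length; a mismatch is an error rather
than a silent re-aggregation, because changing the epoch length changes the
intensity distribution (long epochs average short vigorous bursts and
stillness into the middle band — an effect the acceptance suite
demonstrates directly).  Non-wear epochs belong to no intensity class, so
daily SB + LPA + MVPA equals daily wear time exactly.  An SB bout is a
maximal run of consecutive SB epochs; it is broken by activity *and* by
non-wear, the conservative choice for the under-one-hour rule.

### Validity, standardization, adherence

A day is valid with ≥ 6 h wear; a subject is included with ≥ 4 valid days;
only valid days enter subject means ("measurement days" is read as valid
days — invalid days of included subjects are excluded, the convention of
the inclusion criteria themselves).  Adjusted minutes are
`raw / subject_mean_wear × cohort_mean_wear`, with the cohort mean taken
unweighted over included subjects; the adjustment is scale-free and for
every subject the adjusted levels sum to the cohort mean wear time exactly
(asserted to 1e-9 relative).  Guideline adherence uses adjusted TPA by
default (`use_adjusted_adherence` switches to raw for sensitivity), with
≥ 180 min/day ("at least") and a strict < 60 min longest SB bout
("below one hour").

### Method comparison

For one balanced within-subject factor, estimated marginal means reduce to
simple per-method means and their pairwise contrasts to paired contrasts;
the ANOVA and the contrasts are therefore implemented directly from the
sums-of-squares and paired-difference formulas rather than through a
general mixed-model fitter (external routines serve as cross-checks in the
tests, not as the implementation).  Contrast direction is fixed as
`pair = (a, b)` meaning `mean(a) − mean(b)`.  p-values and 95% confidence
intervals are Bonferroni-corrected over the three pairs.  No sphericity
correction is applied; a Greenhouse–Geisser epsilon is computed from the
double-centred covariance and reported as a diagnostic only.  Perfectly
additive matrices (zero residual) are rejected as degenerate rather than
reported with an infinite F; identical methods yield F = 0, p = 1.
Adherence proportions are compared with an exact McNemar test (binomial
test on discordant pairs; p = 1 when no pairs are discordant) — a
reasonable default for paired binary outcomes, and configurable in the
sense that the discordant counts are returned for any alternative
treatment.

## Synthetic cohort generator

The generator emulates the structure the pipeline assumes, with known
per-second ground truth:

* **Wear pattern** — `n_days` whole calendar days; device worn from
  `wear_start_clock` to `wear_end_clock` (default 08:00–19:00) with ±30 min
  uniform jitter per end per day; a 90-min device-off nap with probability
  0.5 per day, starting uniformly between 12:00 and 14:00.  This yields
  ~10.3 h mean daily wear, typical of parent-administered toddler
  protocols.  Nights and naps are NONWEAR with all-zero counts.
* **Bout structure** — within wear, a semi-Markov chain over SB/LPA/MVPA:
  geometric dwell times (discretised exponential, the simplest semi-Markov
  form) with default means 45/30/15 s — MVPA shortest, since toddlers
  accumulate it in brief bursts — and a zero-diagonal embedded transition
  matrix (so one bout is exactly one dwell draw) whose stationary mix puts
  roughly 54/37/8% of wear time in SB/LPA/MVPA.  Initial states are drawn
  from the embedded chain's stationary distribution.
* **Counts** — per second and axis, zero-inflated negative binomial with
  marginal mean `loc` held fixed across zero-inflation levels.  Vertical
  locations put 15-s VA sums near 10/200/800 for SB/LPA/MVPA (inside the
  Trost bands); horizontal locations put 5-s VM sums near 30/200/600
  (inside the Costa VM bands).  SB is the most zero-inflated, MVPA the
  least.
* **Ambiguity** — the draw is shrunk toward its location,
  `count = rint((1−a)·loc + a·D)` with `a ∈ [0, 1]`: `a = 0` gives a
  deterministic band-centre stream (classification at the matching epoch
  recovers the truth exactly for epoch-aligned bouts), `a = 1` the full
  distribution; intermediate values scale the overlap across thresholds.
  Default 0.5.
* **Determinism** — one `numpy` generator per subject, seeded from the
  cohort seed; identical config and seed give byte-identical recordings.

`SimConfig.n_subjects` defaults to 653, a large-cohort setting; tests and
the acceptance script use scaled-down cohorts (50–150 subjects, 2–7 days)
chosen so the suites exercise the full chain at cohort scale while staying
cheap to re-run.

### What the generator does *not* emulate

Interpreting test results against real data needs these caveats:

* **No between-subject heterogeneity** in activity composition: all
  subjects share one bout process, so between-subject SDs are small and
  guideline adherence is nearly degenerate (all subjects pass or fail
  together).  Recovery and comparison tests are informative; simulated
  adherence *percentages* are not cohort-realistic.
* **No external motion** (stroller, carrying), no circadian intensity
  gradient, no seasonal or demographic covariates, no raw 30 Hz
  accelerations (counts are generated directly), and no missing or
  corrupted files.
* Bout-length distributions are illustrative: no published toddler cohort
  provides per-state dwell statistics to calibrate against.

## Numerical and design choices

* Epoch, day and truncation boundaries are all half-open except the
  truncation interval (closed, see above); ties at classification
  thresholds go to the lower band.
* Validity, wear and minute arithmetic is exact (counts are integers,
  minutes are multiples of `epoch/60`); floating tolerances appear only
  where division does (the wear-time adjustment, 1e-9 relative).
* Subjects enter the method comparison only if valid under **all**
  cut-point sets (complete cases); per-method wear time can differ slightly
  at the epoch level because the non-wear mask is projected onto different
  epoch grids.
* Degenerate statistical inputs fail loudly (constant or additive
  matrices) or are flagged (zero-variance contrasts) instead of returning
  NaNs.

## Limitations

The Choi rule is validated in adults; no toddler-validated non-wear
algorithm exists, and the 20-min window choice materially affects SB/LPA
estimates.  Cut-point classification itself misattributes external motion
to MVPA.  The comparison machinery assumes complete balanced data by
design and does not handle missing cells.
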