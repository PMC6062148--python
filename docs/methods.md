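# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `flyrhythm`, and what its synthetic-data tests do and do not show
about real recordings.

## Time base and conventions

Activity is beam-cross counts on a uniform grid.  Bins are half-open
intervals labelled by their start time; all per-bin attributions (ZT,
light/dark phase) use the bin start.  Zeitgeber time is hours after
lights-on (ZT0 = lights-on; ZT12 = lights-off in LD 12:12).  Under
constant darkness the same projection is applied with a fixed 24.0-h cycle
from the last lights-on and reported as circadian time (CT).  We do not
re-reference CT to each fly's fitted period τ: phase tables are then
directly comparable across flies of one genotype, at the cost of a slow
drift of ≈(τ−24) h per DD day for flies far from 24 h.  Collection is at
5-min bins; rhythm and phase analyses run on 30-min rebinned data (sums of
six bins; a trailing partial bin is truncated with a warning, never
padded).  Sleep is scored before rebinning, because the 5-min inactivity
rule is undefined at coarser resolution.

## Vital status

Activity tables report flies alive at the end of a run without stating a
rule.  We operationalize death as a terminal run of all-zero bins spanning
at least 24 h (configurable) and reaching the end of the recording; the
death time is the end of the last non-zero bin.  A long mid-recording gap
followed by activity is not death.  Dead flies are excluded from all
cohort statistics; rhythm analysis refuses them outright so the exclusion
cannot be forgotten.

## Synthetic activity model

Counts per 5-min bin are independent Poisson draws with rate

    λ(t) = baseline + morning_amplitude·gM(t) + evening_amplitude·gE(t).

Each bout template g peaks at its centre — lights-on for the morning bout,
lights-off + phase_offset for the evening bout — and decays as the
trailing half of a raised cosine of half-width 1.5 h.  The build-up before
the peak is a linear ramp of duration `anticipation_ramp_hours` rising
from 0 to the full amplitude at the peak, so λ is continuous there.  This
split is deliberate: the ramp is the clock-driven anticipatory component,
while the post-transition half-cosine is the light-driven (startle-like)
component.  A fly simulated with ramp = 0 therefore carries *no*
anticipatory signal at all, which is what gives the anticipation and
Morning Index metrics a meaningful negative control; a symmetric bump
centred on the transition would leak pre-transition activity even for
"non-anticipating" flies and make those metrics untestable.

Under DD both template centres shift by (τ − 24) h per cycle, making the
signal exactly τ-periodic.  Arrhythmic flies keep the same time-averaged
rate but flat, so they remain alive under the death rule.  A `death_day`
zeroes the rate from that day onward.  Cohorts use sub-seed `seed + i` for
fly i, so a cohort can be extended without disturbing existing flies; the
arrhythmic subset has exactly `round(n·fraction)` members chosen by a
seeded permutation.

Defaults (chosen once as typical of healthy laboratory cohorts): baseline
1.0 counts per 5-min bin, morning amplitude 4, evening amplitude 6,
τ = 24 h, ramp 3 h, phase offset 0, schedule LD 12:12 for 3 days then 7 DD
days.  What the generator does **not** emulate: the midday siesta is flat
baseline rather than actively suppressed sleep, there is no light-masking
or relative coordination, no temperature cycles, and mortality is an
abrupt stop rather than declining activity.  Tests passing on these
cohorts show the analysis chain is correct under its stated model, not
that it is robust to every pathology of real DAM data (dead channels,
monitor glitches, weak rhythms near the detection floor).

## Rhythmicity and period

Both arms run on the 30-min series of DD days 2–7 (the first DD day is
excluded as an entrainment transient; window configurable).

**Chi-square periodogram.**  For candidate period P (hours, 18–30 in 0.1-h
steps), the first K = ⌊n/P_bins⌋ complete cycles are folded; sample i goes
to column ⌊i mod P_bins⌋.  With column means M_h, column counts n_h, grand
mean M̄ and total variance σ̂² = (1/n)Σ(x_i − M̄)²,

    Qp = Σ_h n_h (M_h − M̄)² / σ̂²,

which equals n·(between-column variance)/(total variance) for integer
P_bins and is approximately χ² with (number of columns − 1) degrees of
freedom under the null.  Fractional periods leave a sparsely filled wrap
column whose mean is far too noisy for the χ² approximation; columns with
fewer than max(2, ⌈K/2⌉) samples are excluded from the sum (integer
periods are unaffected).  Candidates allowing fewer than two complete
folds are skipped with a warning.

Because 121 candidate periods are scanned, comparing each Qp to its
per-candidate α quantile would call roughly a third of *flat noise* series
"significant" somewhere on the grid (measured: 0.39 familywise at
α = 0.01 over 300 flat Poisson replicates).  The significance line and
the reported peak p-value are therefore Bonferroni-corrected for the
number of candidates evaluated, so "significant at α" is familywise.
Genuine rhythms at the default amplitudes sit at Qp ≈ 200–250 against a
corrected line of ≈ 90 and are unaffected.  The best period is the argmax
of (Qp − significance line), refined by 3-point parabolic interpolation
(ties broken toward 24 h).

**Autocorrelation.**  r(k) = Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)², lags up to
36 h.  The rhythmicity statistic RS is the peak coefficient in the
18–30 h window divided by the white-noise 95% level 2/√n; RS ≥ 1 supports
rhythmicity.  Constant (zero-variance) series raise a degenerate-input
error at the primitive level and are classified arrhythmic by the
high-level classifier.

**Call.**  Rhythmic iff the (familywise) periodogram peak is significant
at α = 0.01 AND RS ≥ 1; τ is reported for rhythmic flies only.  Both
thresholds are exposed in the pipeline config.  On simulated cohorts with
a 70% arrhythmic fraction this rule recovers the rhythmic fraction to
within one or two flies and both per-class recalls are ≈ 1.

## Phase metrics

All LD metrics use the average-day profile: the mean count per 30-min ZT
bin over the (default three) LD days.

* **Morning Index**: MI = (A_late − A_early)/(A_late + A_early) with
  A_late the mean over ZT21–24 and A_early over ZT18–21 (windows
  configurable); 0 when both are 0.  Bounded in [−1, 1] and antisymmetric
  under swapping the two blocks.
* **Anticipation**: the 3 h before a transition is split into 1-h thirds
  a1, a2, a3 (a3 adjacent); anticipation iff a3 > a2 ≥ a1 and a3 > 0.
  Note the chance rate of this ordering on featureless noise is 1/6, so
  specificity against non-anticipating flies is bounded near 5/6; the
  metric is informative at cohort level (fraction anticipating), not as a
  per-fly certainty.
* **Evening onset**: the evening peak is the profile argmax in ZT6–13
  (ties → latest).  Walking backward from the peak, the bout extends while
  each earlier bin ≤ its successor, tolerating at most one zero bin
  (compared across, not to, the zero); a bout cannot open on a zero bin.
  The onset is accepted only when the bout directly follows a rest: a run
  of ≥ 2 consecutive bins below 25% of the profile maximum ending at the
  bin before the onset, searched from ZT2.  Requiring adjacency (rather
  than "a rest exists somewhere earlier") rejects spurious late onsets
  produced when profile noise breaks the monotone walk mid-bout, and it
  reproduces the reduced N that onset tables show relative to cohort
  size.  Search window, threshold and rest length are free parameters of
  what is fundamentally a manual scoring rule; all are config-exposed.
* **DD phase**: on a chosen DD day (default the fourth), a centred moving
  average of width 3 bins (odd; edges truncated) smooths the 48 half-hour
  bins; the phase is the CT of the maximum smoothed bin (ties →
  earliest).  All-zero days yield no phase.

## Sleep

Sleep is 5 min of consecutive inactivity, hence every zero 5-min bin
contributes 5 sleep minutes; runs are not required to exceed one bin.
Minutes are attributed to light vs dark by bin-start ZT.  Sleep plus
active-bin time always tile the 1440-min day.

## Expression statistics

The matrix is probes × samples, log2 scale, NaN for missing ("NA" on
disk), two sample groups.

* **Filtering**: probes with missing fraction strictly above 0.5 are
  dropped (exactly half missing is kept); order preserved.
* **Quantile normalization**: each column's sorted values are replaced by
  the across-column mean of sorted values at each rank; ties receive the
  mean of the tied ranks' reference values.  Columns with missing entries
  are normalized through the ranks of their available values against a
  reference interpolated to the available count.  The result has
  identical sorted values in every complete column and the map is
  idempotent.
* **SAM (two-class, unpaired)**: d = (x̄₁ − x̄₂)/(s + s₀) with pooled
  standard error s = √(a(SS₁+SS₂)), a = (1/n₁+1/n₂)/(n₁+n₂−2), computed
  over available values (≥ 2 per group required, else flagged).  s₀ is the
  percentile of the s distribution (0–100 grid, step 5) minimizing the
  coefficient of variation of window-wise MADs of d across s-quantile
  windows (100 windows when ≥ 1000 probes, else 10).  The null is all
  distinct column relabellings when fewer than `n_permutations` exist
  (C(8,4) = 70 for a 4+4 design), otherwise a seeded sample without
  replacement.  Cut points scan outward from the centre of the sorted d's:
  the up cut is the first order statistic above the centre whose deviation
  from the mean permuted order statistic reaches δ (symmetrically down),
  so an excursion in the opposite tail can never define a cut.  FDR = π₀ ·
  (median permuted count beyond the cuts) / (number called), capped at 1,
  with π₀ estimated from the fraction of observed d inside the central 50%
  of the permuted d distribution.  δ may be given directly or found as the
  smallest grid deviation whose estimated FDR meets a target.
  *Known limitation*: because the cuts adapt to the observed order
  statistics, the estimator is downward-biased when δ lies inside the null
  noise floor — on a pure-null 1000-probe 4+4 matrix tuned to ≈ 50 calls
  it reports ≈ 0.7–0.85 where the realized false-discovery proportion is
  1.0.  At realistic operating points (spiked matrices, target FDR 10%)
  estimate and realized FDP agree closely (0.084 vs 0.083 in the test
  conditions) and sensitivity for 2-fold effects at noise SD 0.5 is ≈ 1.
* **Enrichment**: exact hypergeometric upper tail P(X ≥ k) for an overlap
  of k between n called genes and K annotated targets in a universe of N
  filtered probes (delegated to scipy; verified against exhaustive
  enumeration for all N ≤ 12).
* **Small formulas**: RQ = 2^−ΔΔCt (replicates averaged before the
  formula); staining intensity 100·(signal−background)/background;
  luciferase activity (Firefly/Renilla)/control ratio.  All validate
  positivity of their denominators.

## Reporting

Cohort summaries follow the conventional table layout: percentages are
over alive flies and rounded half-up to 2 decimals (matching printed
tables), τ statistics are over rhythmic flies only, onset and DD-phase
statistics are over the flies for which the metric is defined, and
SEM = SD(n−1)/√n.  Pipeline outputs carry a header comment with package
version, seed and config hash; every threshold in effect is logged.

## Problem sizes used in verification

The self-checks and the acceptance script use desk-scale cohorts chosen to
give stable statistics: 50 flies per period-recovery condition
(τ ∈ {23, 24, 24.85, 25.5} h), 100 flies for the arrhythmic-fraction
recovery, 30 flies per phase-contrast cohort, and expression matrices of
1000–2000 probes with 4 samples per group.
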