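# flyrhythm

Analysis of *Drosophila* circadian locomotor behaviour from Drosophila
Activity Monitor (DAM) recordings, together with the expression statistics
that typically accompany a fly chronobiology study (microarray SAM
analysis, target-set enrichment, qPCR relative quantification).

It is aimed at chronobiologists who record beam-cross counts from flies
kept in light–dark (LD) cycles followed by constant darkness (DD) and need
reproducible, scriptable versions of the usual desk analyses:

* **Rhythmicity and free-running period.** Activity is analysed in 30-min
  bins.  For each fly a chi-square periodogram folds the DD activity at
  candidate periods P ∈ [18, 30] h (0.1-h grid); the statistic
  Qp = Σ_h n_h (M_h − M̄)² / σ̂² is compared to its χ²(P−1) null with a
  family-wise (Bonferroni) significance line across the grid.  In
  parallel, the autocorrelation rhythmicity statistic
  RS = peak r(τ) / (2/√n) must reach 1.  A fly is rhythmic when both arms
  agree; its period τ is the (parabolically refined) periodogram peak.
* **Phase metrics.** From the 3-day LD average profile: the Morning Index
  MI = (A_ZT21–24 − A_ZT18–21)/(A_ZT21–24 + A_ZT18–21), fly-by-fly
  morning/evening anticipation (monotone rise over the three 1-h thirds
  before a light transition), the evening activity onset after the midday
  siesta, and the DD phase (smoothed activity peak of a chosen DD day, CT).
* **Sleep.** The standard fly rule — 5 min of consecutive inactivity — on
  the raw 5-min bins, split into light-phase and dark-phase minutes.
* **Expression arm.** Probe filtering (≤ 50% missing), quantile
  normalization, two-class SAM (d = (x̄₁−x̄₂)/(s+s₀) with permutation null
  and π₀-adjusted median FDR), log2 fold changes, hypergeometric
  target-overlap enrichment P(X ≥ k), 2^−ΔΔCt relative quantification,
  staining-intensity and dual-luciferase normalizations.
* **Synthetic data.** A generator produces cohorts with known ground truth
  (crepuscular Poisson activity with anticipation ramps, τ near 24 h, an
  arrhythmic fraction, in-recording death) plus expression matrices and Ct
  tables with spiked-in effects, so the entire chain is testable without
  any recordings.

## Worked example

Simulate a small control cohort (3 LD days, 7 DD days) and run the full
behaviour pipeline:

```python
import yaml
from flyrhythm.report import run_behavior_pipeline

cfg = {
    "schedule": {"lights_on": "08:00", "photoperiod_hours": 12,
                 "n_ld_days": 3, "n_dd_days": 7},
    "simulate": [{"genotype": "ctrl", "n_flies": 20,
                  "arrhythmic_fraction": 0.2}],
}
per_fly, summary = run_behavior_pipeline(cfg, "out", seed=1)
print(summary[["genotype", "n_alive", "n_rhythmic", "pct_rhythmic",
               "tau_mean", "mi_mean", "e_onset_mean"]].to_string(index=False))
```

prints

```
genotype  n_alive  n_rhythmic  pct_rhythmic  tau_mean  mi_mean  e_onset_mean
    ctrl       20          16          80.0 23.964657 0.386394           8.1
```

16 of 20 flies are called rhythmic (the 4 simulated arrhythmic flies are
rejected), the mean free-running period recovers the simulated 24 h within
a few hundredths of an hour, the Morning Index is positive (the cohort was
simulated with a 3-h anticipation ramp), and the mean evening onset sits in
the late light phase, about four hours before lights-off, where the
evening activity bout begins.  The same pipeline is available from a
shell via the `flyrhythm` command:

```sh
flyrhythm simulate          --config cfg.yaml --seed 1 --out sim/
flyrhythm analyze-behavior  --config cfg.yaml --seed 1 --out results/
flyrhythm analyze-expression --config expr.yaml --seed 1 --out results/
flyrhythm summarize         --per-fly results/per_fly.csv --out summary.csv
```

For the expression arm, `run_expression_pipeline` runs
filter → quantile-normalize → SAM → target overlap → hypergeometric
enrichment and writes `sam.csv` and `enrichment.json`.

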