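"""Synthetic cohorts, expression matrices and Ct tables with known truth.

The generators emulate the study conditions every analysis stage is tested
against: crepuscular fly activity with morning and evening bouts, linear
anticipation ramps before the light transitions, a free-running period
near 24 h expressed in DD, an arrhythmic fraction, in-recording death,
two-group expression matrices with a known differentially expressed
subset and missing-at-random entries, and qPCR Ct tables with a known
fold change.  Every generator is a pure function of its seed.

Activity model
--------------
Counts per 5-min bin are independent Poisson draws with rate

    lambda(t) = baseline + morning_amplitude * gM(t) + evening_amplitude * gE(t)

where each bout template g peaks at its centre (lights-on for the morning
bout, lights-off + phase_offset for the evening bout) and decays as the
trailing half of a raised cosine of half-width 1.5 h.  The build-up
*before* the peak is a linear anticipation ramp of the configured
duration: with ramp = 0 the bout starts as a startle-like step at the
transition and carries no anticipatory signal at all, so anticipation
metrics separate clock-driven ramps from light-driven startles.  Under DD
the template centres advance or delay by (tau - 24) h per cycle.
Arrhythmic flies keep the same time-averaged rate but flat (they stay
"alive" for death detection); a death day truncates activity to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime

import numpy as np
import pandas as pd

from .dam_io import ActivitySeries, LightSchedule

HALF_WIDTH_H = 1.5  # half-width of the activity bout template, hours


@dataclass
class FlyParams:
    """Ground-truth parameters of one simulated fly.

    Rates are expected counts per 5-min bin; ``phase_offset_hours`` shifts
    the evening bout relative to lights-off (positive = delayed);
    ``death_day`` (0-based day index) truncates activity to zero from the
    start of that day onward.
    """

    tau_hours: float = 24.0
    phase_offset_hours: float = 0.0
    morning_amplitude: float = 4.0
    evening_amplitude: float = 6.0
    baseline_rate: float = 1.0
    anticipation_ramp_hours: float = 3.0
    arrhythmic: bool = False
    death_day: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 16.0 <= self.tau_hours <= 32.0:
            raise ValueError("tau_hours must lie in [16, 32]")
        if min(self.morning_amplitude, self.evening_amplitude,
               self.baseline_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.anticipation_ramp_hours <= 6.0:
            raise ValueError("anticipation_ramp_hours must lie in [0, 6]")


@dataclass
class ExpressionSimParams:
    """Two-group expression simulation (log2 scale)."""

    n_probes: int = 2000
    n_per_group: int = 4
    de_fraction: float = 0.05
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    na_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.na_fraction < 1.0:
            raise ValueError("na_fraction must lie in [0, 1)")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 samples per group")


def _bout_template(t_h: np.ndarray, centre_h: float, ramp_h: float) -> np.ndarray:
    """Unit-peak bout: linear ramp up to the centre, half-cosine decay after."""
    g = np.zeros_like(t_h)
    d = t_h - centre_h
    if ramp_h > 0:
        on_ramp = (d >= -ramp_h) & (d < 0)
        g[on_ramp] = 1.0 + d[on_ramp] / ramp_h
    decay = (d >= 0) & (d <= HALF_WIDTH_H)
    g[decay] = 0.5 * (1.0 + np.cos(np.pi * d[decay] / HALF_WIDTH_H))
    return g


def rate_function(params: FlyParams, schedule: LightSchedule,
                  bin_minutes: int = 5) -> np.ndarray:
    """Expected counts per bin over the whole recording (the noiseless truth)."""
    bins_per_day = int(round(24 * 60 / bin_minutes))
    n_bins = schedule.n_days * bins_per_day
    t = (np.arange(n_bins) + 0.5) * bin_minutes / 60.0  # hours since ZT0 day 0
    lam = np.full(n_bins, params.baseline_rate, dtype=float)
    for day in range(schedule.n_days + 1):  # +1: tails may spill backwards
        if day < schedule.n_ld_days:
            drift = 0.0
        else:
            drift = (params.tau_hours - 24.0) * (day - schedule.n_ld_days + 1)
        c_m = 24.0 * day + drift
        c_e = 24.0 * day + schedule.photoperiod_hours + params.phase_offset_hours + drift
        lam += params.morning_amplitude * _bout_template(
            t, c_m, params.anticipation_ramp_hours)
        lam += params.evening_amplitude * _bout_template(
            t, c_e, params.anticipation_ramp_hours)
    if params.arrhythmic:
        lam = np.full(n_bins, lam.mean())
    if params.death_day is not None:
        lam[params.death_day * bins_per_day:] = 0.0
    return lam


def simulate_fly(params: FlyParams, schedule: LightSchedule,
                 fly_id: str = "sim", genotype: str = "synthetic",
                 start_date: datetime | None = None) -> ActivitySeries:
    """Draw one fly's 5-min count series from the Poisson activity model."""
    lam = rate_function(params, schedule, bin_minutes=5)
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(lam)
    if start_date is None:
        start_date = datetime(2016, 1, 4)
    start = datetime.combine(start_date.date(), schedule.lights_on_clock)
    return ActivitySeries(fly_id=fly_id, genotype=genotype, start_time=start,
                          bin_minutes=5, counts=counts)


def simulate_cohort(
    n: int,
    params_template: FlyParams,
    arrhythmic_fraction: float,
    schedule: LightSchedule,
    seed: int,
    genotype: str = "synthetic",
) -> tuple[list[ActivitySeries], pd.DataFrame]:
    """Simulate ``n`` flies with independent sub-seeds (fly i uses seed+i).

    Exactly ``round(n * arrhythmic_fraction)`` flies are arrhythmic; which
    ones is decided by a seeded permutation.  Returns the series together
    with a ground-truth table (fly_id, arrhythmic, tau_hours, seed).
    """
    if not 0.0 <= arrhythmic_fraction <= 1.0:
        raise ValueError("arrhythmic_fraction must lie in [0, 1]")
    n_arr = round(n * arrhythmic_fraction)
    rng = np.random.default_rng(seed)
    arr_idx = set(rng.permutation(n)[:n_arr].tolist()) if n else set()
    series, rows = [], []
    for i in range(n):
        p = replace(params_template, seed=seed + i, arrhythmic=i in arr_idx)
        s = simulate_fly(p, schedule, fly_id=f"{genotype}_{i:03d}",
                         genotype=genotype)
        series.append(s)
        rows.append({"fly_id": s.fly_id, "arrhythmic": p.arrhythmic,
                     "tau_hours": p.tau_hours, "seed": p.seed})
    truth = pd.DataFrame(rows, columns=["fly_id", "arrhythmic", "tau_hours", "seed"])
    return series, truth


def simulate_expression_matrix(params: ExpressionSimParams):
    """Two-group log2 expression matrix with a spiked-in DE subset.

    The first ``round(n_probes * de_fraction)`` probes carry a group effect
    of ``log2_effect`` (treated minus control), half up- and half
    down-regulated; ``na_fraction`` of entries are masked missing at
    random.  Returns ``(ExpressionMatrix, truth)`` where truth maps probe
    id to its signed effect.
    """
    from .expression import ExpressionMatrix

    rng = np.random.default_rng(params.seed)
    m, k = params.n_probes, params.n_per_group
    probe_ids = [f"probe_{i:05d}" for i in range(m)]
    baseline = rng.normal(8.0, 2.0, size=m)
    effect = np.zeros(m)
    n_de = round(m * params.de_fraction)
    effect[: n_de - n_de // 2] = params.log2_effect
    effect[n_de - n_de // 2: n_de] = -params.log2_effect
    values = np.empty((m, 2 * k))
    values[:, :k] = baseline[:, None] + effect[:, None]  # treated
    values[:, k:] = baseline[:, None]                    # control
    values += rng.normal(0.0, params.noise_sd, size=values.shape)
    if params.na_fraction > 0:
        values[rng.random(values.shape) < params.na_fraction] = np.nan
    labels = ["treated"] * k + ["control"] * k
    cols = [f"{g}_{j + 1}" for j, g in enumerate(labels)]
    mat = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=cols),
        group_labels=labels,
    )
    truth = pd.Series(effect[:n_de], index=probe_ids[:n_de], name="log2_effect")
    return mat, truth


def simulate_qpcr_ct(
    true_fold_change: float,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    reference_ct: float = 20.0,
    target_calibrator_ct: float = 25.0,
) -> pd.DataFrame:
    """Ct table (target/reference x sample/calibrator x replicate).

    Built so the noiseless ddCt equals ``-log2(true_fold_change)``; per-well
    Gaussian noise of ``ct_noise_sd`` cycles is then added.
    """
    if true_fold_change <= 0:
        raise ValueError("true_fold_change must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    means = {
        ("target", "sample"): target_calibrator_ct - np.log2(true_fold_change),
        ("target", "calibrator"): target_calibrator_ct,
        ("reference", "sample"): reference_ct,
        ("reference", "calibrator"): reference_ct,
    }
    for (gene, condition), mu in means.items():
        for rep in range(1, n_replicates + 1):
            ct = mu + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0)
            rows.append({"gene": gene, "condition": condition,
                         "replicate": rep, "ct": ct})
    return pd.DataFrame(rows)
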