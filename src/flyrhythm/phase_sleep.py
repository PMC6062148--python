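"""Phase metrics and sleep scoring from DAM activity.

Covers the average-day profile, the Morning Index (a bounded contrast of
pre-dawn activity build-up), fly-by-fly morning/evening anticipation at
the light transitions, the evening activity onset after the midday
siesta, the DD phase (peak activity on a chosen free-running day, on
smoothed data), and sleep by the fly 5-minute inactivity rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .dam_io import ActivitySeries, LightSchedule, is_light_phase, rebin, to_zeitgeber

PROFILE_BIN_HOURS = 0.5
PROFILE_BINS = 48


@dataclass
class DayProfile:
    """Mean activity per 30-min ZT bin, averaged over requested days."""

    values: np.ndarray
    n_days_averaged: int
    bin_hours: float = PROFILE_BIN_HOURS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (PROFILE_BINS,):
            raise ValueError(f"profile must have exactly {PROFILE_BINS} bins")
        if (self.values < 0).any():
            raise ValueError("profile values must be non-negative")

    def zt(self, i: int) -> float:
        return i * self.bin_hours


@dataclass
class PhaseSleepMetrics:
    morning_index: float
    morning_anticipation: bool
    evening_anticipation: bool
    evening_onset_zt: float | None
    dd_phase_ct: float | None
    sleep_total_min: float
    sleep_day_min: float
    sleep_night_min: float


def average_day_profile(
    series: ActivitySeries,
    days: Iterable[int],
    schedule: LightSchedule,
) -> DayProfile:
    """Average 24-h activity profile over the given 0-based recording days.

    The series is analysed in 30-min bins (rebinned if finer); the value
    at ZT bin b is the mean over the requested days of the count in that
    bin.
    """
    work = series if series.bin_minutes == 30 else rebin(series, 30)
    days = sorted(set(int(d) for d in days))
    if not days:
        raise ValueError("at least one day required")
    bpd = work.bins_per_day
    acc = np.zeros(PROFILE_BINS)
    for d in days:
        if d < 0 or (d + 1) * bpd > len(work):
            raise ValueError(f"day {d} outside the recording")
        for i in range(d * bpd, (d + 1) * bpd):
            zt = to_zeitgeber(work.bin_start(i), schedule)
            b = int(zt / PROFILE_BIN_HOURS) % PROFILE_BINS
            acc[b] += work.counts[i]
    return DayProfile(values=acc / len(days), n_days_averaged=len(days))


def morning_index(
    profile: DayProfile,
    early_window: tuple[float, float] = (18.0, 21.0),
    late_window: tuple[float, float] = (21.0, 24.0),
) -> float:
    """Bounded pre-dawn build-up contrast in [-1, 1].

    MI = (A_late - A_early) / (A_late + A_early) with A_late the mean
    activity over ZT21-24 (the 3 h before lights-on) and A_early the mean
    over ZT18-21; 0 by convention when both are zero.
    """
    zts = np.arange(PROFILE_BINS) * profile.bin_hours
    a_early = profile.values[(zts >= early_window[0]) & (zts < early_window[1])].mean()
    a_late = profile.values[(zts >= late_window[0]) & (zts < late_window[1])].mean()
    if a_early + a_late == 0:
        return 0.0
    return float((a_late - a_early) / (a_late + a_early))


def detect_anticipation(
    profile: DayProfile,
    transition: Literal["lights_on", "lights_off"],
    photoperiod_hours: float = 12.0,
) -> bool:
    """Anticipatory activity build-up in the 3 h before a light transition.

    The 3 h window is split into three 1-h thirds with means a1, a2, a3
    (a3 adjacent to the transition); anticipation iff a3 > a2 >= a1 and
    a3 > 0.
    """
    if transition == "lights_on":
        t_zt = 24.0
    elif transition == "lights_off":
        t_zt = photoperiod_hours
    else:
        raise ValueError("transition must be 'lights_on' or 'lights_off'")
    zts = np.arange(PROFILE_BINS) * profile.bin_hours
    thirds = []
    for j in range(3):
        lo = (t_zt - 3.0 + j) % 24.0
        hi = lo + 1.0
        thirds.append(profile.values[(zts >= lo) & (zts < hi)].mean())
    a1, a2, a3 = thirds
    return bool(a3 > a2 >= a1 and a3 > 0)


def evening_onset(
    profile: DayProfile,
    search_window_zt: tuple[float, float] = (6.0, 13.0),
    rest_threshold_frac: float = 0.25,
    rest_min_bins: int = 2,
    rest_search_start_zt: float = 2.0,
) -> float | None:
    """ZT of the evening-bout onset, or None if no qualifying bout.

    Operationalizes the manual scoring rule: (1) the evening peak is the
    profile argmax within the search window (ties -> latest); (2) a "rest"
    (siesta) is a maximal run of >= ``rest_min_bins`` consecutive bins each
    below ``rest_threshold_frac`` of the profile maximum, between
    ``rest_search_start_zt`` and the peak; (3) walking backward from the
    peak, the bout extends while each earlier bin <= its successor,
    tolerating at most one zero-activity bin inside the run; (4) the onset
    is the ZT of the first (non-zero) bin of the bout, accepted only when
    the bout directly follows a rest (the sub-threshold run ends at the bin
    before the onset).  Flies with no onset are excluded from cohort onset
    averages, which is why onset tables report a reduced N.
    """
    v = profile.values
    zts = np.arange(PROFILE_BINS) * profile.bin_hours
    win = np.flatnonzero((zts >= search_window_zt[0]) & (zts < search_window_zt[1]))
    if win.size == 0 or v[win].max() == 0:
        return None
    peak = int(win[np.flatnonzero(v[win] == v[win].max())[-1]])  # ties -> latest

    # backward walk: non-increasing going back, bridging at most one zero bin
    run_start = peak
    ref = v[peak]
    zeros_used = 0
    i = peak - 1
    first = int(np.flatnonzero(zts >= rest_search_start_zt)[0])
    while i >= first:
        if v[i] == 0:
            if zeros_used:
                break
            zeros_used += 1
            run_start = i
        elif v[i] <= ref:
            ref = v[i]
            run_start = i
        else:
            break
        i -= 1
    while run_start < peak and v[run_start] == 0:  # a bout cannot open on a zero bin
        run_start += 1
    if run_start == peak:
        return None  # no rise at all: a lone peak bin is not a bout

    # rest: >= rest_min_bins consecutive sub-threshold bins ending right
    # before the onset bin (the bout must emerge from the siesta)
    thr = rest_threshold_frac * v.max()
    j = run_start - 1
    rest_len = 0
    while j >= first and v[j] < thr:
        rest_len += 1
        j -= 1
    if rest_len >= rest_min_bins:
        return float(zts[run_start])
    return None


def dd_phase(
    series: ActivitySeries,
    schedule: LightSchedule,
    day_index: int = 4,
    smooth_bins: int = 3,
) -> float | None:
    """CT of the activity peak on a DD day, on smoothed data.

    ``day_index`` is 1-based within DD (default: fourth day of constant
    conditions).  A centred moving average of width ``smooth_bins`` (odd;
    edges truncated) is applied to the day's 48 half-hour bins and the
    phase is the CT of the maximum smoothed bin (ties -> earliest).
    Returns None for an all-zero day.
    """
    if smooth_bins < 1 or smooth_bins % 2 == 0:
        raise ValueError("smooth_bins must be a positive odd integer")
    if not 1 <= day_index <= schedule.n_dd_days:
        raise ValueError("day_index outside the DD span")
    work = series if series.bin_minutes == 30 else rebin(series, 30)
    bpd = work.bins_per_day
    start = (schedule.n_ld_days + day_index - 1) * bpd
    if start + bpd > len(work):
        raise ValueError("recording does not cover the requested DD day")
    day = work.counts[start: start + bpd].astype(float)
    if not day.any():
        return None
    smoothed = (
        pd.Series(day).rolling(smooth_bins, center=True, min_periods=1).mean().to_numpy()
    )
    i = int(np.argmax(smoothed))  # argmax takes the earliest tie
    return to_zeitgeber(work.bin_start(start + i), schedule)


def sleep_summary(
    series: ActivitySeries,
    schedule: LightSchedule,
    day: int,
) -> tuple[float, float, float]:
    """(total, day, night) sleep minutes over one 0-based recording day.

    Sleep is 5 min of consecutive inactivity, so every zero 5-min bin
    contributes 5 min; minutes are attributed to the light vs dark phase
    by the bin's start ZT.  Must be computed on the raw 5-min bins (the
    rule is undefined at coarser resolution).
    """
    if series.bin_minutes != 5:
        raise ValueError("sleep must be scored on 5-min bins, before rebinning")
    bpd = series.bins_per_day
    start = day * bpd
    if day < 0 or start + bpd > len(series):
        raise ValueError(f"day {day} outside the recording")
    total = day_min = 0.0
    for i in range(start, start + bpd):
        if series.counts[i] == 0:
            total += 5.0
            if is_light_phase(to_zeitgeber(series.bin_start(i), schedule), schedule):
                day_min += 5.0
    return total, day_min, total - day_min


def compute_phase_sleep_metrics(
    series: ActivitySeries,
    schedule: LightSchedule,
    ld_days: Iterable[int] | None = None,
    dd_phase_day: int = 4,
) -> PhaseSleepMetrics:
    """Assemble all per-fly phase and sleep metrics for one recording.

    The LD average-day profile uses all LD days by default; sleep is the
    mean over the LD days; DD phase is computed only when the schedule
    covers the requested DD day.
    """
    if ld_days is None:
        ld_days = range(schedule.n_ld_days)
    ld_days = list(ld_days)
    profile = average_day_profile(series, ld_days, schedule)
    mi = morning_index(profile)
    ma = detect_anticipation(profile, "lights_on", schedule.photoperiod_hours)
    ea = detect_anticipation(profile, "lights_off", schedule.photoperiod_hours)
    onset = evening_onset(profile)
    phase_ct = (
        dd_phase(series, schedule, day_index=dd_phase_day)
        if schedule.n_dd_days >= dd_phase_day and series.bin_minutes <= 30
        else None
    )
    sleeps = np.array([sleep_summary(series, schedule, d) for d in ld_days])
    total, day_m, night_m = sleeps.mean(axis=0)
    return PhaseSleepMetrics(
        morning_index=mi,
        morning_anticipation=ma,
        evening_anticipation=ea,
        evening_onset_zt=onset,
        dd_phase_ct=phase_ct,
        sleep_total_min=float(total),
        sleep_day_min=float(day_m),
        sleep_night_min=float(night_m),
    )
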