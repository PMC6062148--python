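"""I/O and time-base handling for Drosophila Activity Monitor (DAM) data.

Beam-cross counts arrive as one row per timestamp with 32 channel columns
(the Trikinetics monitor dialect) or as a long per-fly CSV.  All analyses
downstream work on :class:`ActivitySeries` objects on a uniform time grid.
Bins are half-open intervals labelled by their start time; Zeitgeber time
is reported at bin start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_DAM_CHANNELS = 32


class DamFormatError(ValueError):
    """Malformed monitor file (bad row, broken timestamp, uneven grid)."""


@dataclass
class LightSchedule:
    """Lighting regime: LD days followed by DD days.

    ``lights_on_clock`` defines ZT0.  During DD the same projection is
    applied and reported as circadian time (CT): ZT0 of the last LD day is
    projected forward with a fixed 24-h cycle, not the fly's fitted period.
    """

    lights_on_clock: time = time(8, 0)
    photoperiod_hours: float = 12.0
    n_ld_days: int = 3
    n_dd_days: int = 7

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_hours < 24:
            raise ValueError("photoperiod_hours must be in (0, 24)")
        if self.n_ld_days < 0 or self.n_dd_days < 0:
            raise ValueError("day counts must be non-negative")
        if self.n_ld_days + self.n_dd_days < 1:
            raise ValueError("schedule must cover at least one day")

    @property
    def n_days(self) -> int:
        return self.n_ld_days + self.n_dd_days


@dataclass
class ActivitySeries:
    """One fly's beam-cross counts on a uniform grid."""

    fly_id: str
    genotype: str
    start_time: datetime
    bin_minutes: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_minutes <= 0:
            raise ValueError("bin_minutes must be positive")
        if 60 % self.bin_minutes != 0 and self.bin_minutes % 60 != 0:
            raise ValueError("bin grid must align to whole hours")

    def __len__(self) -> int:
        return self.counts.size

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_minutes))

    def bin_start(self, i: int) -> datetime:
        return self.start_time + timedelta(minutes=i * self.bin_minutes)

    @property
    def end_time(self) -> datetime:
        return self.bin_start(len(self))


@dataclass
class VitalStatus:
    alive: bool
    death_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.alive and self.death_time is not None:
            raise ValueError("death_time only meaningful for dead flies")
        if not self.alive and self.death_time is None:
            raise ValueError("dead flies must carry a death_time")


def to_zeitgeber(timestamp: datetime, schedule: LightSchedule) -> float:
    """Hours after lights-on, in [0, 24).

    Periodic with period 24 h; during DD the same projection is used and
    interpreted as CT (24-h extrapolation from the last lights-on).
    """
    on = schedule.lights_on_clock
    delta_h = (
        timestamp.hour - on.hour
        + (timestamp.minute - on.minute) / 60.0
        + (timestamp.second - on.second) / 3600.0
    )
    return delta_h % 24.0


def is_light_phase(zt: float, schedule: LightSchedule) -> bool:
    """True if a ZT value falls within the photophase of an LD day."""
    return 0.0 <= (zt % 24.0) < schedule.photoperiod_hours


# --------------------------------------------------------------------------
# monitor-file reading/writing


def _parse_timestamp(date_s: str, time_s: str, lineno: int) -> datetime:
    for fmt in ("%d %b %y", "%Y-%m-%d", "%d/%m/%y"):
        try:
            d = datetime.strptime(date_s.strip(), fmt)
            break
        except ValueError:
            continue
    else:
        raise DamFormatError(f"line {lineno}: unparseable date {date_s!r}")
    try:
        t = datetime.strptime(time_s.strip(), "%H:%M:%S").time()
    except ValueError as exc:
        raise DamFormatError(f"line {lineno}: unparseable time {time_s!r}") from exc
    return datetime.combine(d.date(), t)


def read_dam_monitor(
    path,
    schedule: LightSchedule,
    genotype: str = "",
    count_start_col: int | None = None,
    n_channels: int = N_DAM_CHANNELS,
) -> list[ActivitySeries]:
    """Read a tab-separated DAM monitor file into per-channel series.

    Rows carry an index, date, time, a block of status columns and then
    ``n_channels`` integer count columns.  The reader accepts both the
    42-column dialect (10 leading columns) and minimal files where counts
    directly follow the timestamp; ``count_start_col`` overrides the
    autodetected position of the first count column.  Channels that are
    all-zero over the whole recording are kept but flagged with a warning
    (never silently dropped).
    """
    rows: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 3 + n_channels:
                raise DamFormatError(
                    f"line {lineno}: expected at least {3 + n_channels} columns, "
                    f"got {len(fields)}"
                )
            rows.append([str(lineno)] + fields)
    if not rows:
        raise DamFormatError("empty monitor file")

    if count_start_col is None:
        count_start_col = len(rows[0]) - 1 - n_channels  # index within fields

    timestamps: list[datetime] = []
    counts = np.empty((len(rows), n_channels), dtype=np.int64)
    for r, row in enumerate(rows):
        lineno = int(row[0])
        fields = row[1:]
        timestamps.append(_parse_timestamp(fields[1], fields[2], lineno))
        for c in range(n_channels):
            tok = fields[count_start_col + c].strip()
            try:
                counts[r, c] = int(tok)
            except ValueError as exc:
                raise DamFormatError(
                    f"line {lineno}: non-integer count {tok!r} in channel {c + 1}"
                ) from exc

    steps = np.array(
        [(b - a).total_seconds() for a, b in zip(timestamps, timestamps[1:])]
    )
    if len(steps):
        if (steps <= 0).any() or not np.allclose(steps, steps[0]):
            raise DamFormatError("timestamps are not at a constant positive step")
        bin_minutes = int(round(steps[0] / 60.0))
    else:
        bin_minutes = 5

    series = []
    for c in range(n_channels):
        s = ActivitySeries(
            fly_id=f"ch{c + 1:02d}",
            genotype=genotype,
            start_time=timestamps[0],
            bin_minutes=bin_minutes,
            counts=counts[:, c],
        )
        if not s.counts.any():
            logger.warning("channel %d is all-zero over the whole recording", c + 1)
        series.append(s)
    return series


def write_dam_monitor(path, series: list[ActivitySeries]) -> None:
    """Write series (shared grid) in the minimal monitor dialect.

    Columns: index, date, time, status, then one count column per series.
    Round-trips through :func:`read_dam_monitor` with
    ``n_channels=len(series)``.
    """
    if not series:
        raise ValueError("nothing to write")
    n = len(series[0])
    if any(len(s) != n or s.start_time != series[0].start_time
           or s.bin_minutes != series[0].bin_minutes for s in series):
        raise ValueError("series must share one time grid")
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(n):
            ts = series[0].bin_start(i)
            cells = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"), "1"]
            cells += [str(int(s.counts[i])) for s in series]
            fh.write("\t".join(cells) + "\n")


def read_fly_csv(path) -> list[ActivitySeries]:
    """Read the long per-fly CSV (header fly_id,genotype,timestamp,count)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (fly_id, genotype), g in df.groupby(["fly_id", "genotype"], sort=False):
        g = g.sort_values("timestamp")
        ts = g["timestamp"].to_numpy()
        if len(ts) > 1:
            steps = np.diff(ts).astype("timedelta64[s]").astype(float)
            if (steps <= 0).any() or not np.allclose(steps, steps[0]):
                raise DamFormatError(f"fly {fly_id}: uneven time grid")
            bin_minutes = int(round(steps[0] / 60.0))
        else:
            bin_minutes = 5
        out.append(
            ActivitySeries(
                fly_id=str(fly_id),
                genotype=str(genotype),
                start_time=pd.Timestamp(ts[0]).to_pydatetime(),
                bin_minutes=bin_minutes,
                counts=g["count"].to_numpy(),
            )
        )
    return out


def write_fly_csv(path, series: list[ActivitySeries]) -> None:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": s.fly_id,
                    "genotype": s.genotype,
                    "timestamp": [s.bin_start(i) for i in range(len(s))],
                    "count": s.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# --------------------------------------------------------------------------
# grid operations


def rebin(series: ActivitySeries, target_bin_minutes: int) -> ActivitySeries:
    """Sum consecutive bins into coarser ones (e.g. 5-min -> 30-min).

    The target width must be a positive multiple of the source width; a
    trailing partial bin is truncated (with a warning), never padded, so
    total counts are conserved up to the truncated tail.
    """
    if target_bin_minutes <= 0 or target_bin_minutes % series.bin_minutes != 0:
        raise ValueError(
            f"target bin {target_bin_minutes} min is not a multiple of "
            f"source bin {series.bin_minutes} min"
        )
    ratio = target_bin_minutes // series.bin_minutes
    if ratio == 1:
        return ActivitySeries(
            series.fly_id, series.genotype, series.start_time,
            series.bin_minutes, series.counts.copy(),
        )
    n_full = len(series) // ratio
    if n_full * ratio != len(series):
        logger.warning(
            "fly %s: truncating %d trailing bin(s) at rebinning",
            series.fly_id, len(series) - n_full * ratio,
        )
    summed = series.counts[: n_full * ratio].reshape(n_full, ratio).sum(axis=1)
    return ActivitySeries(
        series.fly_id, series.genotype, series.start_time,
        target_bin_minutes, summed,
    )


def detect_death(
    series: ActivitySeries, min_terminal_zero_hours: float = 24.0
) -> VitalStatus:
    """Call a fly dead if its terminal all-zero run spans >= the threshold.

    ``death_time`` is the end of the last non-zero bin (start of recording
    if the fly never moved).  A long zero run mid-recording followed by
    activity does not count.
    """
    if len(series) * series.bin_minutes / 60.0 < min_terminal_zero_hours:
        raise ValueError("recording shorter than min_terminal_zero_hours")
    nonzero = np.flatnonzero(series.counts)
    if nonzero.size == 0:
        return VitalStatus(alive=False, death_time=series.start_time)
    last = int(nonzero[-1])
    terminal_zero_hours = (len(series) - 1 - last) * series.bin_minutes / 60.0
    if terminal_zero_hours >= min_terminal_zero_hours:
        return VitalStatus(alive=False, death_time=series.bin_start(last + 1))
    return VitalStatus(alive=True)
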