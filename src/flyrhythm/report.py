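"""Cohort-level summaries and pipeline orchestration.

`summarize_cohort` reproduces the layout of a genotype row in a locomotor
summary table: counts, percent rhythmic, period mean +/- SEM over the
rhythmic flies only, percent morning/evening anticipation over the alive
flies, and phase statistics over the subsets for which each metric is
defined.  Percentages are rounded half-up to two decimals, matching
printed-table formatting.  The two `run_*_pipeline` functions are the
config-driven entry points behind the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict, fields as dc_fields
from datetime import datetime, time as dtime
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from .dam_io import (
    ActivitySeries, LightSchedule, detect_death, read_dam_monitor,
    read_fly_csv, write_dam_monitor,
)
from .expression import (
    EnrichmentInput, filter_probes, hypergeometric_enrichment,
    quantile_normalize, read_expression_tsv, read_gene_list, sam_two_class,
)
from .phase_sleep import compute_phase_sleep_metrics
from .rhythm import classify_rhythmicity
from .synthetic import ExpressionSimParams, FlyParams, simulate_cohort, simulate_expression_matrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (all problems listed at once)."""


def pct_half_up(numerator: int, denominator: int) -> float:
    """100*numerator/denominator rounded half-up to 2 decimals."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _mean_sem(x: pd.Series) -> tuple[float, float]:
    x = pd.to_numeric(x, errors="coerce").dropna()
    if len(x) == 0:
        return math.nan, math.nan
    sem = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan
    return float(x.mean()), sem


@dataclass
class CohortSummary:
    genotype: str
    n_total: int
    n_alive: int
    n_rhythmic: int
    pct_rhythmic: float
    tau_mean: float
    tau_sem: float
    pct_ma: float
    pct_ea: float
    mi_mean: float
    mi_sem: float
    e_onset_mean: float
    e_onset_sem: float
    e_onset_n: int
    dd_phase_mean: float
    dd_phase_sem: float
    dd_phase_n: int


def summarize_cohort(per_fly: pd.DataFrame, genotype: str) -> CohortSummary:
    """One table row from per-fly results.

    Expects at least the columns fly_id and alive; the metric columns
    (is_rhythmic, tau_hours, morning_anticipation, evening_anticipation,
    morning_index, evening_onset_zt, dd_phase_ct) are optional and yield
    NaN statistics when absent.  Percentages are over the alive flies; tau
    statistics are over the rhythmic flies only; onset and DD-phase
    statistics are over the flies for which the metric is defined.
    """
    n_total = len(per_fly)
    alive = per_fly[per_fly.get("alive", True) == True]  # noqa: E712
    n_alive = len(alive)

    def col(name: str) -> pd.Series:
        return alive[name] if name in alive.columns else pd.Series(dtype=float)

    rhythmic = col("is_rhythmic")
    n_rhythmic = int((rhythmic == True).sum())  # noqa: E712
    if n_alive == 0:
        pct_r = pct_ma = pct_ea = math.nan
    else:
        pct_r = pct_half_up(n_rhythmic, n_alive)
        pct_ma = (pct_half_up(int((col("morning_anticipation") == True).sum()), n_alive)  # noqa: E712
                  if "morning_anticipation" in alive.columns else math.nan)
        pct_ea = (pct_half_up(int((col("evening_anticipation") == True).sum()), n_alive)  # noqa: E712
                  if "evening_anticipation" in alive.columns else math.nan)

    tau = col("tau_hours")
    tau_mean, tau_sem = _mean_sem(tau[rhythmic == True]) if len(tau) else (math.nan, math.nan)  # noqa: E712
    mi_mean, mi_sem = _mean_sem(col("morning_index"))
    onset = pd.to_numeric(col("evening_onset_zt"), errors="coerce").dropna()
    onset_mean, onset_sem = _mean_sem(onset)
    phase = pd.to_numeric(col("dd_phase_ct"), errors="coerce").dropna()
    phase_mean, phase_sem = _mean_sem(phase)

    return CohortSummary(
        genotype=genotype, n_total=n_total, n_alive=n_alive,
        n_rhythmic=n_rhythmic, pct_rhythmic=pct_r,
        tau_mean=tau_mean, tau_sem=tau_sem,
        pct_ma=pct_ma, pct_ea=pct_ea,
        mi_mean=mi_mean, mi_sem=mi_sem,
        e_onset_mean=onset_mean, e_onset_sem=onset_sem, e_onset_n=len(onset),
        dd_phase_mean=phase_mean, dd_phase_sem=phase_sem, dd_phase_n=len(phase),
    )


def cohort_from_counts(genotype: str, n_total: int, n_alive: int,
                       n_rhythmic: int) -> CohortSummary:
    """Summary from printed integer columns (N tot / N alive / N rhythmic)."""
    if not 0 <= n_rhythmic <= n_alive <= n_total:
        raise ValueError("need n_rhythmic <= n_alive <= n_total")
    rows = [{"fly_id": f"f{i}", "alive": i < n_alive,
             "is_rhythmic": i < n_rhythmic} for i in range(n_total)]
    return summarize_cohort(pd.DataFrame(rows), genotype)


# --------------------------------------------------------------------------
# per-fly analysis


def analyze_fly(
    series: ActivitySeries,
    schedule: LightSchedule,
    min_terminal_zero_hours: float = 24.0,
    dd_window: tuple[int, int] = (2, 7),
    alpha: float = 0.01,
    rs_threshold: float = 1.0,
) -> dict:
    """All per-fly metrics as one flat record; dead flies carry only vitals."""
    row: dict = {"fly_id": series.fly_id, "genotype": series.genotype}
    vital = detect_death(series, min_terminal_zero_hours)
    row["alive"] = vital.alive
    if not vital.alive:
        return row
    if schedule.n_dd_days >= dd_window[1]:
        rr = classify_rhythmicity(series, schedule, dd_window=dd_window,
                                  alpha=alpha, rs_threshold=rs_threshold)
        row.update(
            is_rhythmic=rr.is_rhythmic, tau_hours=rr.tau_hours, rs=rr.rs,
            periodogram_pvalue=rr.periodogram_pvalue,
        )
    if schedule.n_ld_days >= 1:
        m = compute_phase_sleep_metrics(series, schedule)
        row.update(
            morning_index=m.morning_index,
            morning_anticipation=m.morning_anticipation,
            evening_anticipation=m.evening_anticipation,
            evening_onset_zt=m.evening_onset_zt,
            dd_phase_ct=m.dd_phase_ct,
            sleep_total_min=m.sleep_total_min,
            sleep_day_min=m.sleep_day_min,
            sleep_night_min=m.sleep_night_min,
        )
    return row


def analyze_cohort(series_list: list[ActivitySeries],
                   schedule: LightSchedule, **kwargs) -> pd.DataFrame:
    rows = []
    for s in series_list:
        try:
            rows.append(analyze_fly(s, schedule, **kwargs))
        except Exception as exc:  # one bad fly must not sink the cohort
            logger.warning("fly %s skipped: %s", s.fly_id, exc)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# config-driven pipelines


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha1(
        yaml.safe_dump(cfg, sort_keys=True).encode()).hexdigest()[:12]


def _require(cfg: dict, keys: list[str]) -> None:
    missing = [k for k in keys if k not in cfg]
    if missing:
        raise ConfigError("missing config keys: " + ", ".join(sorted(missing)))


def parse_schedule(cfg: dict) -> LightSchedule:
    _require(cfg, ["lights_on", "photoperiod_hours", "n_ld_days", "n_dd_days"])
    hh, mm = str(cfg["lights_on"]).split(":")[:2]
    return LightSchedule(
        lights_on_clock=dtime(int(hh), int(mm)),
        photoperiod_hours=float(cfg["photoperiod_hours"]),
        n_ld_days=int(cfg["n_ld_days"]),
        n_dd_days=int(cfg["n_dd_days"]),
    )


def _header_lines(seed, cfg: dict) -> str:
    return (f"# flyrhythm {_version} seed={seed} "
            f"config_sha1={_config_hash(cfg)} "
            f"written={datetime.now().isoformat(timespec='seconds')}\n")


def _write_csv_with_header(path: Path, df: pd.DataFrame, seed, cfg: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_lines(seed, cfg))
        df.to_csv(fh, index=False)


def _simulated_cohorts(cfg: dict, schedule: LightSchedule, seed: int):
    fly_fields = {f.name for f in dc_fields(FlyParams)}
    out = []
    for i, scen in enumerate(cfg):
        genotype = scen.get("genotype", f"group{i + 1}")
        params = FlyParams(**{k: v for k, v in scen.items() if k in fly_fields})
        series, truth = simulate_cohort(
            n=int(scen.get("n_flies", 32)),
            params_template=params,
            arrhythmic_fraction=float(scen.get("arrhythmic_fraction", 0.0)),
            schedule=schedule,
            seed=seed + 1000 * i,
            genotype=genotype,
        )
        out.append((genotype, series, truth))
    return out


def run_behavior_pipeline(config, out_dir, seed: int = 0):
    """simulate/load -> vitals -> rhythmicity -> phase & sleep -> summary.

    Config keys: ``schedule`` (required) and one of ``simulate`` (list of
    cohort scenarios), ``monitor_files`` (list of {path, genotype}) or
    ``per_fly_csv``.  Optional ``thresholds``: min_terminal_zero_hours,
    dd_window, alpha, rs_threshold.  Writes per_fly.csv and summary.csv
    (header comment carries version, seed and config hash) plus a log.
    Returns (per_fly frame, summary frame).
    """
    cfg = _load_config(config)
    _require(cfg, ["schedule"])
    if not any(k in cfg for k in ("simulate", "monitor_files", "per_fly_csv")):
        raise ConfigError(
            "missing config keys: one of simulate | monitor_files | per_fly_csv")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "behavior.log")
    logging.getLogger("flyrhythm").addHandler(fh)
    try:
        schedule = parse_schedule(cfg["schedule"])
        thr = cfg.get("thresholds", {})
        kw = dict(
            min_terminal_zero_hours=float(thr.get("min_terminal_zero_hours", 24.0)),
            dd_window=tuple(thr.get("dd_window", (2, 7))),
            alpha=float(thr.get("alpha", 0.01)),
            rs_threshold=float(thr.get("rs_threshold", 1.0)),
        )
        logger.info("thresholds in effect: %s", kw)

        cohorts: list[tuple[str, list[ActivitySeries]]] = []
        if "simulate" in cfg:
            for genotype, series, _truth in _simulated_cohorts(
                    cfg["simulate"], schedule, seed):
                cohorts.append((genotype, series))
        if "monitor_files" in cfg:
            for spec_ in cfg["monitor_files"]:
                try:
                    series = read_dam_monitor(
                        spec_["path"], schedule, genotype=spec_.get("genotype", ""))
                except Exception as exc:
                    logger.warning("skipping unreadable monitor %s: %s",
                                   spec_.get("path"), exc)
                    continue
                cohorts.append((spec_.get("genotype", ""), series))
        if "per_fly_csv" in cfg:
            series = read_fly_csv(cfg["per_fly_csv"])
            for genotype in sorted({s.genotype for s in series}):
                cohorts.append(
                    (genotype, [s for s in series if s.genotype == genotype]))

        frames, summaries = [], []
        for genotype, series in cohorts:
            per_fly = analyze_cohort(series, schedule, **kw)
            frames.append(per_fly)
            summaries.append(asdict(summarize_cohort(per_fly, genotype)))
        per_fly_all = pd.concat(frames, ignore_index=True)
        summary = pd.DataFrame(summaries)
        _write_csv_with_header(out_dir / "per_fly.csv", per_fly_all, seed, cfg)
        _write_csv_with_header(out_dir / "summary.csv", summary, seed, cfg)
        return per_fly_all, summary
    finally:
        logging.getLogger("flyrhythm").removeHandler(fh)
        fh.close()


def run_expression_pipeline(config, out_dir, seed: int = 0):
    """filter -> quantile normalize -> SAM -> target overlap -> enrichment.

    Config keys: one of ``simulate`` (expression sim params) or
    ``matrix_file`` + ``groups`` (map sample label -> group); optional
    ``target_list`` (path or inline list), ``sam``: {delta | target_fdr,
    n_permutations, s0}, ``max_na_fraction``.  Writes sam.csv and
    enrichment.json; enrichment is skipped (logged) when no probes are
    called or no target list is given.  Returns (SamResult, enrichment
    dict or None).
    """
    cfg = _load_config(config)
    if ("simulate" not in cfg) and ("matrix_file" not in cfg):
        raise ConfigError("missing config keys: one of simulate | matrix_file")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out_dir / "expression.log")
    logging.getLogger("flyrhythm").addHandler(fh)
    try:
        if "simulate" in cfg:
            sim_fields = {f.name for f in dc_fields(ExpressionSimParams)}
            params = ExpressionSimParams(
                **{k: v for k, v in cfg["simulate"].items() if k in sim_fields})
            if "seed" not in cfg["simulate"]:
                params.seed = seed
            matrix, _truth = simulate_expression_matrix(params)
        else:
            groups = cfg.get("groups")
            if not isinstance(groups, dict):
                raise ConfigError("missing config keys: groups")
            def group_of(col: str) -> str:
                for label, g in groups.items():
                    if col.startswith(label) or col == label:
                        return g
                raise ConfigError(f"group label absent from header: {col}")
            matrix = read_expression_tsv(cfg["matrix_file"], group_of)

        matrix = filter_probes(matrix, float(cfg.get("max_na_fraction", 0.5)))
        matrix = quantile_normalize(matrix)
        sam_cfg = cfg.get("sam", {})
        result = sam_two_class(
            matrix,
            n_permutations=int(sam_cfg.get("n_permutations", 1000)),
            delta=sam_cfg.get("delta"),
            target_fdr=(sam_cfg.get("target_fdr", 0.07)
                        if sam_cfg.get("delta") is None else None),
            seed=seed,
            s0=sam_cfg.get("s0"),
        )
        calls = pd.DataFrame({
            "probe_id": result.d_scores.index,
            "d": result.d_scores.to_numpy(),
            "call": ["up" if p in set(result.significant_up)
                     else "down" if p in set(result.significant_down)
                     else "" for p in result.d_scores.index],
        })
        _write_csv_with_header(out_dir / "sam.csv", calls, seed, cfg)

        enrichment = None
        targets = cfg.get("target_list")
        if isinstance(targets, str):
            targets = read_gene_list(targets)
        if not result.significant:
            logger.info("no probes called; enrichment skipped")
        elif not targets:
            logger.info("no target list given; enrichment skipped")
        else:
            universe = set(matrix.values.index)
            k_set = universe & set(targets)
            called = set(result.significant)
            overlap = called & k_set
            inp = EnrichmentInput(
                universe_size=len(universe), annotated=len(k_set),
                drawn=len(called), overlap=len(overlap))
            enrichment = {
                "universe_size": inp.universe_size, "annotated": inp.annotated,
                "drawn": inp.drawn, "overlap": inp.overlap,
                "p_value": hypergeometric_enrichment(inp),
            }
            with open(out_dir / "enrichment.json", "w", encoding="utf-8") as jf:
                json.dump({"_meta": {"version": _version, "seed": seed,
                                     "config_sha1": _config_hash(cfg)},
                           **enrichment}, jf, indent=2)
        return result, enrichment
    finally:
        logging.getLogger("flyrhythm").removeHandler(fh)
        fh.close()


def simulate_to_files(config, out_dir, seed: int = 0) -> None:
    """Write simulated cohorts as DAM-format monitor files + truth CSVs."""
    cfg = _load_config(config)
    _require(cfg, ["schedule", "simulate"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    schedule = parse_schedule(cfg["schedule"])
    for genotype, series, truth in _simulated_cohorts(cfg["simulate"], schedule, seed):
        write_dam_monitor(out_dir / f"monitor_{genotype}.txt", series)
        with open(out_dir / f"truth_{genotype}.csv", "w", encoding="utf-8") as fh:
            fh.write(_header_lines(seed, cfg))
            truth.to_csv(fh, index=False)
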