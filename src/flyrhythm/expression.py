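"""Expression statistics: probe filtering, quantile normalization,
two-class SAM with permutation FDR, target-set enrichment, and the small
normalization formulas for qPCR (2^-ddCt), immunofluorescence intensity
and dual-luciferase assays.

The matrix container is probes x samples on the log2 scale with NaN as
the missing-value marker (written "NA" on disk).  Exactly two sample
groups are supported, matching a two-genotype microarray design with a
few biological replicates per group.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probes x samples values with a two-group column labelling."""

    values: pd.DataFrame
    group_labels: list[str]

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("probe ids must be unique")
        if len(self.group_labels) != self.values.shape[1]:
            raise ValueError("one group label per column required")
        counts = pd.Series(self.group_labels).value_counts()
        if len(counts) != 2 or (counts < 2).any():
            raise ValueError("need exactly two groups with >= 2 columns each")

    @property
    def groups(self) -> tuple[str, str]:
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_columns(self, group: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.group_labels) == group)


@dataclass
class SamResult:
    d_scores: pd.Series
    s0: float
    delta: float
    fdr_estimate: float
    significant_up: list[str]
    significant_down: list[str]
    n_permutations: int
    seed: int
    flagged: list[str] = field(default_factory=list)

    @property
    def significant(self) -> list[str]:
        return self.significant_up + self.significant_down


@dataclass
class EnrichmentInput:
    """Hypergeometric overlap: k of n drawn genes hit K annotated of N."""

    universe_size: int
    annotated: int
    drawn: int
    overlap: int

    def __post_init__(self) -> None:
        n_, k_, n, k = self.universe_size, self.annotated, self.drawn, self.overlap
        if not (0 <= k <= min(k_, n) and 0 <= k_ <= n_ and 0 <= n <= n_):
            raise ValueError("invalid hypergeometric bounds")


# --------------------------------------------------------------------------
# matrix preprocessing


def filter_probes(matrix: ExpressionMatrix,
                  max_na_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop probes whose missing fraction exceeds the threshold.

    A probe with missing fraction exactly equal to the threshold is kept;
    survivor order is preserved.
    """
    na_frac = matrix.values.isna().mean(axis=1)
    keep = na_frac <= max_na_fraction
    if not keep.any():
        logger.warning("probe filter removed every probe")
    return ExpressionMatrix(values=matrix.values.loc[keep].copy(),
                            group_labels=list(matrix.group_labels))


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common mean-of-sorted-values distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values at each rank, preserving within-column rank order; tied
    values receive the mean of the tied ranks' reference values.  Columns
    with missing entries are normalized through the ranks of their
    available values (the reference is interpolated to the column's
    available count); missing entries stay missing.
    """
    v = matrix.values.to_numpy(dtype=float)
    m, n_cols = v.shape
    if n_cols == 1:
        logger.warning("single-column matrix: quantile normalization is identity")
        return ExpressionMatrix(matrix.values.copy(), list(matrix.group_labels))

    grid = np.linspace(0.0, 1.0, m)
    ref = np.zeros(m)
    for j in range(n_cols):
        col = np.sort(v[~np.isnan(v[:, j]), j])
        if col.size == 0:
            raise ValueError(f"column {j} has no available values")
        ref += np.interp(grid, np.linspace(0.0, 1.0, col.size), col)
    ref /= n_cols

    out = np.full_like(v, np.nan)
    for j in range(n_cols):
        avail = ~np.isnan(v[:, j])
        col = v[avail, j]
        nj = col.size
        ref_j = ref if nj == m else np.interp(
            np.linspace(0.0, 1.0, nj), grid, ref)
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(nj)
        assigned[order] = ref_j
        # ties: mean of the tied ranks' reference values
        assigned = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[avail, j] = assigned
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=matrix.values.index,
                            columns=matrix.values.columns),
        group_labels=list(matrix.group_labels),
    )


# --------------------------------------------------------------------------
# SAM two-class


def _group_stats(v: np.ndarray, idx1: np.ndarray, idx2: np.ndarray):
    """Per-probe numerator r, pooled denominator s, and validity mask.

    r = mean1 - mean2; s = sqrt(a * (SS1 + SS2)) with
    a = (1/n1 + 1/n2)/(n1 + n2 - 2), computed over available values;
    probes with < 2 available values in either group are invalid.
    """
    x1, x2 = v[:, idx1], v[:, idx2]
    n1 = (~np.isnan(x1)).sum(axis=1)
    n2 = (~np.isnan(x2)).sum(axis=1)
    valid = (n1 >= 2) & (n2 >= 2)
    r = np.full(v.shape[0], np.nan)
    s = np.full(v.shape[0], np.nan)
    if valid.any():
        y1, y2 = x1[valid], x2[valid]
        m1 = np.nanmean(y1, axis=1)
        m2 = np.nanmean(y2, axis=1)
        ss1 = np.nansum((y1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((y2 - m2[:, None]) ** 2, axis=1)
        a = (1.0 / n1[valid] + 1.0 / n2[valid]) / (n1[valid] + n2[valid] - 2)
        r[valid] = m1 - m2
        s[valid] = np.sqrt(a * (ss1 + ss2))
    return r, s, valid


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Fudge factor: the percentile of s (0-100 grid, step 5) minimizing the
    coefficient of variation of window-wise MADs of d across s-quantile
    windows (100 windows for >= 1000 probes, 10 otherwise)."""
    n_windows = 100 if s.size >= 1000 else 10
    edges = np.percentile(s, np.linspace(0, 100, n_windows + 1))
    window = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_windows - 1)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    best_cv, best_s0 = np.inf, candidates[0]
    for s0 in candidates:
        d = r / (s + s0) if s0 > 0 or (s > 0).all() else None
        if d is None:
            continue
        mads = []
        for w in range(n_windows):
            dw = d[window == w]
            if dw.size:
                mads.append(stats.median_abs_deviation(dw, scale="normal"))
        mads = np.asarray(mads)
        mu = mads.mean()
        if mu == 0:
            continue
        cv = mads.std() / mu
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _permutation_assignments(n_cols: int, n1: int, n_permutations: int,
                             rng: np.random.Generator) -> list[np.ndarray]:
    """Distinct group-1 column sets: all of them if few, else a seeded sample."""
    total = math.comb(n_cols, n1)
    if total <= n_permutations:
        return [np.array(c) for c in itertools.combinations(range(n_cols), n1)]
    picks = set()
    out = []
    while len(out) < n_permutations:
        c = tuple(sorted(rng.choice(n_cols, size=n1, replace=False).tolist()))
        if c not in picks:
            picks.add(c)
            out.append(np.array(c))
    return out


def sam_two_class(
    matrix: ExpressionMatrix,
    n_permutations: int = 1000,
    delta: float | None = None,
    target_fdr: float | None = None,
    seed: int = 0,
    s0: float | None = None,
) -> SamResult:
    """Two-class (unpaired) significance analysis with permutation FDR.

    Per probe, d = (mean1 - mean2) / (s + s0), where s is the pooled
    standard error and the fudge factor s0 damps the variance of d for
    low-expression probes.  The null is built from distinct relabellings
    of the columns (all of them when fewer than ``n_permutations`` exist,
    otherwise a seeded sample): observed order statistics of d are
    compared to the mean permuted order statistics, and probes whose
    deviation exceeds ``delta`` define the up/down cut points.  The FDR
    estimate is the median number of permuted probes beyond the cuts,
    scaled by the null proportion pi0 (estimated from the central 50% of
    the permuted d values) and divided by the number of calls; it is
    reported capped at 1.

    Give either ``delta`` directly or ``target_fdr`` (the smallest delta
    on the deviation grid whose estimated FDR is below the target is
    used).  Probes with fewer than 2 available values in a group, or with
    s + s0 == 0, are flagged and excluded from calling.
    """
    if (delta is None) == (target_fdr is None):
        raise ValueError("give exactly one of delta or target_fdr")
    v = matrix.values.to_numpy(dtype=float)
    probes = matrix.values.index.to_numpy()
    g1, g2 = matrix.groups
    idx1, idx2 = matrix.group_columns(g1), matrix.group_columns(g2)
    rng = np.random.default_rng(seed)

    r, s, valid = _group_stats(v, idx1, idx2)
    if s0 is None:
        s0 = _choose_s0(r[valid], s[valid])
    denom_ok = valid & ((s + s0) > 0)
    flagged = probes[~denom_ok].tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        d_obs = np.where(denom_ok, r / (s + s0), np.nan)

    assignments = _permutation_assignments(
        v.shape[1], len(idx1), n_permutations, rng)
    all_cols = np.arange(v.shape[1])
    d_perm = []
    for cols1 in assignments:
        cols2 = np.setdiff1d(all_cols, cols1)
        rp, sp, vp = _group_stats(v, cols1, cols2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dp = np.where(vp & ((sp + s0) > 0), rp / (sp + s0), np.nan)
        d_perm.append(dp)
    d_perm = np.asarray(d_perm)  # perms x probes

    ok = denom_ok & ~np.isnan(d_perm).any(axis=0)
    d_sorted = np.sort(d_obs[ok])
    dbar = np.sort(d_perm[:, ok], axis=1).mean(axis=0)

    def _call(dlt: float):
        # scan outward from the centre of the sorted d's: the up cut is the
        # first order statistic above the centre whose deviation from the
        # mean permuted order statistic reaches delta (and symmetrically
        # for the down cut), so a deviation deep in the opposite tail can
        # never define a cut
        dev = d_sorted - dbar
        centre = int(np.argmin(np.abs(dbar)))
        cut_up, cut_down = np.inf, -np.inf
        for i in range(centre, d_sorted.size):
            if dev[i] >= dlt:
                cut_up = d_sorted[i]
                break
        for i in range(centre, -1, -1):
            if dev[i] <= -dlt:
                cut_down = d_sorted[i]
                break
        called_up = denom_ok & (d_obs >= cut_up)
        called_down = denom_ok & (d_obs <= cut_down)
        n_called = int(called_up.sum() + called_down.sum())
        false_per_perm = ((d_perm >= cut_up) | (d_perm <= cut_down)).sum(axis=1)
        med_false = float(np.median(false_per_perm))
        return called_up, called_down, n_called, med_false

    pooled = d_perm[:, ok].ravel()
    q25, q75 = np.percentile(pooled, [25, 75])
    pi0 = min(1.0, ((d_sorted >= q25) & (d_sorted <= q75)).sum() / (0.5 * d_sorted.size))

    def _fdr(n_called: int, med_false: float) -> float:
        if n_called == 0:
            return 0.0
        return min(1.0, pi0 * med_false / n_called)

    if delta is None:
        deviations = np.sort(np.abs(d_sorted - dbar))[::-1]
        grid = np.unique(deviations)[::-1]  # large delta -> few calls, low FDR
        delta = float(grid[0]) + 1.0
        for cand in grid:
            _, _, n_called, med_false = _call(cand)
            if n_called > 0 and _fdr(n_called, med_false) <= target_fdr:
                delta = float(cand)
            else:
                break

    called_up, called_down, n_called, med_false = _call(delta)
    return SamResult(
        d_scores=pd.Series(d_obs, index=matrix.values.index, name="d"),
        s0=float(s0),
        delta=float(delta),
        fdr_estimate=_fdr(n_called, med_false),
        significant_up=probes[called_up].tolist(),
        significant_down=probes[called_down].tolist(),
        n_permutations=len(assignments),
        seed=seed,
        flagged=flagged,
    )


# --------------------------------------------------------------------------
# small closed-form statistics


def log2_fold_change(mean_treated: float, mean_control: float) -> float:
    """log2(treated/control); both means must be positive."""
    if mean_treated <= 0 or mean_control <= 0:
        raise ValueError("means must be positive for a log ratio")
    return float(np.log2(mean_treated / mean_control))


def hypergeometric_enrichment(inp: EnrichmentInput) -> float:
    """Exact upper-tail overlap probability P(X >= k), in (0, 1]."""
    if inp.overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(
        inp.overlap - 1, inp.universe_size, inp.annotated, inp.drawn))


def delta_delta_ct(
    ct_target_sample,
    ct_ref_sample,
    ct_target_calibrator,
    ct_ref_calibrator,
) -> float:
    """Relative quantification RQ = 2^-ddCt.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator);
    replicate Ct values (array-like inputs) are averaged before the formula.
    """
    cts = [np.mean(np.asarray(c, dtype=float)) for c in
           (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)]
    if not all(np.isfinite(cts)):
        raise ValueError("Ct values must be finite")
    ddct = (cts[0] - cts[1]) - (cts[2] - cts[3])
    return float(2.0 ** (-ddct))


def rq_from_ct_table(table: pd.DataFrame) -> float:
    """RQ from a tidy Ct table (columns gene, condition, replicate, ct)."""
    def _ct(gene, condition):
        sel = table[(table["gene"] == gene) & (table["condition"] == condition)]
        if sel.empty:
            raise ValueError(f"no rows for {gene}/{condition}")
        return sel["ct"].to_numpy()

    return delta_delta_ct(
        _ct("target", "sample"), _ct("reference", "sample"),
        _ct("target", "calibrator"), _ct("reference", "calibrator"),
    )


def per_intensity(signal: float, background: float) -> float:
    """Background-normalized staining intensity: 100*(signal-background)/background."""
    if background <= 0:
        raise ValueError("background must be positive")
    return 100.0 * (signal - background) / background


def luciferase_relative_activity(
    firefly: float, renilla: float, control_ratio: float
) -> float:
    """Firefly/Renilla ratio normalized to the control-transfection ratio."""
    if renilla <= 0 or control_ratio <= 0:
        raise ValueError("renilla and control_ratio must be positive")
    return (firefly / renilla) / control_ratio


# --------------------------------------------------------------------------
# disk formats


def read_expression_tsv(path, group_of_column) -> ExpressionMatrix:
    """Tab-delimited matrix: first column probe id, header of sample labels,
    missing values as "NA".  ``group_of_column`` maps column name -> group."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    labels = [group_of_column(c) for c in df.columns]
    return ExpressionMatrix(values=df, group_labels=labels)


def write_expression_tsv(path, matrix: ExpressionMatrix) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA")


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one id per line; blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]
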