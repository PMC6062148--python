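import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flyrhythm import (
    EnrichmentInput, ExpressionMatrix, delta_delta_ct, filter_probes,
    hypergeometric_enrichment, log2_fold_change, luciferase_relative_activity,
    per_intensity, quantile_normalize, sam_two_class,
)
from flyrhythm.expression import read_expression_tsv, write_expression_tsv
from flyrhythm.synthetic import ExpressionSimParams, simulate_expression_matrix


def matrix_from(values, labels=("g1", "g1", "g2", "g2")):
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=[f"p{i}" for i in range(len(values))],
                      columns=[f"s{j}" for j in range(len(labels))])
    return ExpressionMatrix(values=df, group_labels=list(labels))


class TestFilterProbes:
    def test_majority_missing_removed_half_missing_kept(self):
        vals = np.ones((3, 8))
        vals[0, :5] = np.nan  # 5/8 missing -> removed
        vals[1, :4] = np.nan  # 4/8 missing -> kept
        m = matrix_from(vals, labels=["a"] * 4 + ["b"] * 4)
        out = filter_probes(m)
        assert list(out.values.index) == ["p1", "p2"]

    def test_complete_matrix_unchanged(self):
        m = matrix_from(np.arange(16.0).reshape(4, 4))
        assert filter_probes(m).values.equals(m.values)


class TestQuantileNormalize:
    def test_hand_computed_reference(self):
        m = matrix_from([[3, 6, 3, 6], [1, 4, 1, 4], [2, 5, 2, 5]])
        out = quantile_normalize(m).values
        assert out.iloc[:, 0].tolist() == [4.5, 2.5, 3.5]
        assert out.iloc[:, 1].tolist() == [4.5, 2.5, 3.5]

    def test_identical_columns_unchanged(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = matrix_from(np.column_stack([col] * 4))
        assert np.allclose(quantile_normalize(m).values.to_numpy(),
                           m.values.to_numpy())

    def test_columns_share_sorted_values_and_idempotent(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.normal(8, 2, size=(50, 4)))
        out = quantile_normalize(m)
        cols = out.values.to_numpy()
        for j in range(1, 4):
            assert np.array_equal(np.sort(cols[:, 0]), np.sort(cols[:, j]))
        again = quantile_normalize(out)
        assert np.allclose(again.values.to_numpy(), cols)

    def test_missing_entries_stay_missing(self):
        vals = np.arange(20.0).reshape(5, 4)
        vals[1, 2] = np.nan
        out = quantile_normalize(matrix_from(vals))
        assert np.isnan(out.values.iloc[1, 2])
        assert out.values.drop(index="p1").notna().all().all()


class TestSamTwoClass:
    def test_hand_evaluated_d_score(self):
        m = matrix_from([[1, 2, 3, 4, 5, 6], [0, 1, 2, 1, 2, 3]],
                        labels=["g1"] * 3 + ["g2"] * 3)
        res = sam_two_class(m, delta=10.0, s0=0.0, seed=0)
        assert res.d_scores["p0"] == pytest.approx(-3.674, abs=5e-4)

    def test_swapping_group_labels_negates_d(self):
        mat, _ = simulate_expression_matrix(ExpressionSimParams(
            n_probes=50, de_fraction=0.1, seed=5))
        res = sam_two_class(mat, delta=1.0, s0=0.1, seed=0)
        # put the control columns first so the group roles swap
        cols = list(mat.values.columns)
        swapped = ExpressionMatrix(mat.values[cols[4:] + cols[:4]],
                                   mat.group_labels[4:] + mat.group_labels[:4])
        res2 = sam_two_class(swapped, delta=1.0, s0=0.1, seed=0)
        assert np.allclose(res2.d_scores, -res.d_scores)

    def test_zero_variance_probe_flagged_not_crashing(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        m = matrix_from(vals, labels=["a"] * 4 + ["b"] * 4)
        res = sam_two_class(m, delta=0.5, s0=0.0, seed=0)
        assert "p0" in res.flagged
        assert np.isnan(res.d_scores["p0"])

    def test_spiked_matrix_sensitivity_at_controlled_fdr(self):
        mat, truth = simulate_expression_matrix(ExpressionSimParams(
            n_probes=2000, de_fraction=0.05, log2_effect=2.0, noise_sd=0.5,
            n_per_group=4, seed=4))
        mat = quantile_normalize(mat)
        res = sam_two_class(mat, target_fdr=0.10, seed=4)
        called = set(res.significant)
        sens = len(called & set(truth.index)) / len(truth)
        assert res.fdr_estimate <= 0.10
        assert sens >= 0.7
        assert set(res.significant_up).isdisjoint(res.significant_down)

    def test_probes_with_missing_values_handled(self):
        mat, _ = simulate_expression_matrix(ExpressionSimParams(
            n_probes=200, de_fraction=0.1, na_fraction=0.1, seed=9))
        mat = filter_probes(mat)
        res = sam_two_class(quantile_normalize(mat), delta=0.5, seed=1)
        assert res.d_scores.notna().sum() > 0


def enumeration_tail(N, K, n, k):
    """Brute-force upper tail by enumerating every size-n draw."""
    annotated = set(range(K))
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_enrichment(EnrichmentInput(100, 10, 10, 0)) == 1.0

    def test_perfect_overlap_small_universe(self):
        p = hypergeometric_enrichment(EnrichmentInput(10, 5, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_enumeration_for_small_universes(self):
        for N in range(1, 13):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    tails = {}
                    for draw in itertools.combinations(range(N), n):
                        h = len(set(range(K)).intersection(draw))
                        tails[h] = tails.get(h, 0) + 1
                    total = sum(tails.values())
                    for k in range(max(1, n + K - N), min(K, n) + 1):
                        oracle = sum(c for h, c in tails.items() if h >= k) / total
                        p = hypergeometric_enrichment(EnrichmentInput(N, K, n, k))
                        assert p == pytest.approx(oracle, rel=1e-12), (N, K, n, k)

    def test_tail_monotone_in_overlap(self):
        ps = [hypergeometric_enrichment(EnrichmentInput(50, 12, 20, k))
              for k in range(0, 13)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            EnrichmentInput(10, 12, 5, 1)


class TestSmallFormulas:
    @pytest.mark.parametrize("t, c, expected", [(8, 2, 2.0), (4, 4, 0.0), (2, 8, -2.0)])
    def test_log2_fold_change(self, t, c, expected):
        assert log2_fold_change(t, c) == pytest.approx(expected)

    def test_log2_fold_change_requires_positive_means(self):
        with pytest.raises(ValueError):
            log2_fold_change(0.0, 2.0)

    @pytest.mark.parametrize(
        "cts, expected",
        [((20, 20, 20, 20), 1.0), ((20, 20, 21, 20), 2.0), ((20, 18, 24, 19), 8.0)],
    )
    def test_delta_delta_ct(self, cts, expected):
        assert delta_delta_ct(*cts) == pytest.approx(expected)

    def test_delta_delta_ct_averages_replicates(self):
        assert delta_delta_ct([19, 21], [17, 19], [24, 24], [19, 19]) == pytest.approx(8.0)

    @pytest.mark.parametrize("sig, bg, expected", [(200, 100, 100.0), (100, 100, 0.0), (50, 100, -50.0)])
    def test_per_intensity(self, sig, bg, expected):
        assert per_intensity(sig, bg) == pytest.approx(expected)

    def test_luciferase_normalization(self):
        assert luciferase_relative_activity(10, 2, 2.5) == pytest.approx(2.0)
        assert luciferase_relative_activity(5, 5, 1.0) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100),
           st.floats(1.1, 10))
    def test_luciferase_scale_invariance(self, f, r, c, scale):
        a = luciferase_relative_activity(f, r, c)
        b = luciferase_relative_activity(f * scale, r * scale, c)
        assert b == pytest.approx(a, rel=1e-9)


class TestDiskFormats:
    def test_tsv_round_trip_with_na(self, tmp_path):
        vals = np.arange(16.0).reshape(4, 4)
        vals[2, 1] = np.nan
        m = matrix_from(vals, labels=["ctrl", "ctrl", "oe", "oe"])
        p = tmp_path / "expr.tsv"
        write_expression_tsv(p, m)
        back = read_expression_tsv(
            p, lambda c: "ctrl" if c in ("s0", "s1") else "oe")
        assert back.values.equals(m.values)
        assert back.group_labels == m.group_labels
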