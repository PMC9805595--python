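import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codep import (
    adjust_bh,
    adjust_pvalues,
    cor_map,
    cor_target_map,
    cor_targets,
    filter_rows,
    pearson_with_p,
    run_chunked,
)
from oracles import bh_stepup, pearson_textbook


def _random_pair(rng, length):
    x = rng.standard_normal(length)
    y = 0.5 * x + rng.standard_normal(length)
    for v in (x, y):
        miss = rng.random(length) < 0.15
        v[miss] = np.nan
    return x, y


class TestPearsonWithP:
    def test_perfect_positive(self):
        r, p, n = pearson_with_p([1, 2, 3, 4], [2, 4, 6, 8], min_n=3)
        assert (r, p, n) == (1.0, 0.0, 4)

    def test_perfect_negative(self):
        r, _, _ = pearson_with_p([1, 2, 3], [3, 2, 1], min_n=3)
        assert r == -1.0

    def test_hand_computed_example(self):
        # deviations give Sxy=10, Sxx=10, Syy=14.8 -> r = 10/sqrt(148)
        r, p, n = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 6], min_n=3)
        assert n == 5
        assert r == pytest.approx(0.8220, abs=1e-4)
        assert 0 < p < 0.1

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            pearson_with_p([1, 2, 3], [1, 2])

    def test_min_n_and_zero_variance_yield_missing(self):
        r, p, n = pearson_with_p([1, 2, np.nan, np.nan], [1, 2, 3, 4], min_n=3)
        assert np.isnan(r) and np.isnan(p) and n == 2
        r, p, n = pearson_with_p([1.0, 1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4, 5],
                                 min_n=5)
        assert np.isnan(r) and np.isnan(p) and n == 5

    def test_agrees_with_textbook_oracle_under_missingness(self):
        rng = np.random.default_rng(101)
        worst_r = worst_p = 0.0
        for _ in range(100):
            x, y = _random_pair(rng, int(rng.integers(5, 51)))
            r, p, n = pearson_with_p(x, y, min_n=3)
            r0, p0, n0 = pearson_textbook(x, y)
            assert n == n0
            if np.isnan(r0):
                assert np.isnan(r)
                continue
            worst_r = max(worst_r, abs(r - r0))
            worst_p = max(worst_p, abs(p - p0))
        assert worst_r < 1e-10
        assert worst_p < 1e-10


class TestAdjustBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.005, 0.5], [0.01, 0.5]),
        ],
    )
    def test_step_up_by_hand(self, p, expected):
        np.testing.assert_allclose(adjust_bh(p), expected, atol=1e-15)

    def test_missing_in_missing_out(self):
        q = adjust_bh([0.02, np.nan, 0.04])
        assert np.isnan(q[1])
        # family size m = 2, not 3
        np.testing.assert_allclose(q[[0, 2]], [0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.5])
        with pytest.raises(ValueError):
            adjust_pvalues([0.5], method="not-a-method")

    def test_matches_reference_stepup_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            m = int(rng.integers(1, 120))
            p = rng.random(m)
            p[rng.random(m) < 0.1] = np.nan
            got = adjust_bh(p)
            want = np.array(bh_stepup(p))
            np.testing.assert_allclose(got, want, atol=1e-14, equal_nan=True)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                 max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_properties_bounds_and_reapplication(self, p):
        q = adjust_bh(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        qq = adjust_bh(q)
        assert np.all(qq >= q - 1e-12)


class TestFilterRows:
    @pytest.fixture
    def meta(self):
        return pd.DataFrame(
            {
                "lineage": ["lung", "lung", "breast"],
                "subtype": ["NSCLC", "SCLC", "NSCLC"],
            },
            index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
        )

    @pytest.fixture
    def data(self):
        return pd.DataFrame(
            np.arange(12.0).reshape(3, 4),
            index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
            columns=list("ABCD"),
        )

    def test_single_column_disjunction(self, data, meta):
        out = filter_rows(data, meta, {"lineage": {"lung"}})
        assert list(out.index) == ["S1", "S2"]
        assert list(out.columns) == list("ABCD")

    def test_empty_spec_is_identity(self, data, meta):
        pd.testing.assert_frame_equal(filter_rows(data, meta, {}), data)

    def test_conjunction_across_columns(self, data, meta):
        out = filter_rows(
            data, meta, {"lineage": {"lung"}, "subtype": {"NSCLC"}}
        )
        assert list(out.index) == ["S1"]

    def test_unknown_column_errors(self, data, meta):
        with pytest.raises(KeyError, match="tissue"):
            filter_rows(data, meta, {"tissue": {"lung"}})

    def test_empty_result_warns(self, data, meta, caplog):
        with caplog.at_level(logging.WARNING, logger="codep.correlate"):
            out = filter_rows(data, meta, {"lineage": {"kidney"}})
        assert out.shape == (0, 4)
        assert any("matched no samples" in m for m in caplog.messages)

    def test_locality_filtering_complete_rows_preserves_r(self, recovery_screen):
        # dropping complete rows only changes which pairs exist, not the r
        # computed on the remaining rows
        matrix, meta, truth = recovery_screen
        complete = matrix.dropna(axis=0).index[:5]
        sub_meta = meta.copy()
        sub_meta["keep"] = np.where(sub_meta.index.isin(complete), "no", "yes")
        filtered = filter_rows(matrix, sub_meta, {"keep": {"yes"}})
        g1, g2 = truth["gene"].iloc[0], truth["gene"].iloc[1]
        r_f, _, n_f = pearson_with_p(filtered[g1], filtered[g2])
        r_d, _, n_d = pearson_with_p(
            matrix.loc[filtered.index, g1], matrix.loc[filtered.index, g2]
        )
        assert n_f == n_d
        assert r_f == r_d


class TestCorTargets:
    def test_self_correlation_record(self, tiny_matrix):
        table = cor_targets(tiny_matrix, "GA", min_n=3)
        self_row = table[table["gene"] == "GA"].iloc[0]
        assert self_row["r"] == 1.0
        assert self_row["p"] == 0.0
        assert self_row["n"] == 5
        assert np.isnan(self_row["q"])  # self excluded from the BH family

    def test_constant_column_yields_missing_stats(self, tiny_matrix):
        table = cor_targets(tiny_matrix, "GA", min_n=3)
        row = table[table["gene"] == "GD"].iloc[0]
        assert np.isnan(row["r"]) and np.isnan(row["p"]) and np.isnan(row["q"])

    def test_q_is_bh_over_this_targets_family(self, recovery_table):
        table, target, _ = recovery_table
        sub = table[table["gene"] != target]
        expected = adjust_bh(sub["p"].to_numpy())
        np.testing.assert_allclose(
            sub["q"].to_numpy(), expected, atol=1e-14, equal_nan=True
        )

    def test_sorted_by_ascending_q(self, recovery_table):
        table, _, _ = recovery_table
        q = table["q"].dropna().to_numpy()
        assert np.all(np.diff(q) >= 0)

    def test_absent_target_errors(self, tiny_matrix):
        with pytest.raises(KeyError):
            cor_targets(tiny_matrix, "NOPE")

    def test_bounds_invariants(self, recovery_table):
        table, _, _ = recovery_table
        r, p, q = table["r"], table["p"], table["q"]
        assert r.dropna().between(-1, 1).all()
        assert p.dropna().between(0, 1).all()
        assert q.dropna().between(0, 1).all()
        both = table.dropna(subset=["p", "q"])
        assert (both["q"] >= both["p"] - 1e-15).all()


class TestCorTargetMap:
    def test_record_count(self, tiny_matrix):
        table = cor_target_map(tiny_matrix, ["GA"], select=["GA", "GB", "GC"],
                               min_n=3)
        assert len(table) == 3

    def test_r_symmetric_across_target_families(self, tiny_matrix):
        table = cor_target_map(tiny_matrix, ["GA", "GB"], min_n=3)
        ab = table[(table.target == "GA") & (table.gene == "GB")]["r"].iloc[0]
        ba = table[(table.target == "GB") & (table.gene == "GA")]["r"].iloc[0]
        assert ab == ba

    def test_missing_target_errors_before_computation(self, tiny_matrix):
        with pytest.raises(KeyError, match="NOPE"):
            cor_target_map(tiny_matrix, ["GA", "NOPE"])

    def test_targets_kept_in_input_order(self, tiny_matrix):
        table = cor_target_map(tiny_matrix, ["GB", "GA"], min_n=3)
        assert list(pd.unique(table["target"])) == ["GB", "GA"]


class TestCorMap:
    def test_three_genes_nine_records_three_self(self, tiny_matrix):
        table = cor_map(tiny_matrix, select=["GA", "GB", "GC"], min_n=3)
        assert len(table) == 9
        assert (table["r"] == 1.0).sum() == 3

    def test_reconstructed_matrix_symmetric_unit_diagonal(self, tiny_matrix):
        table = cor_map(tiny_matrix, select=["GA", "GB", "GC"], min_n=3)
        R = table.pivot(index="target", columns="gene", values="r")
        np.testing.assert_allclose(R.values, R.values.T)
        np.testing.assert_allclose(np.diag(R.values), 1.0)

    def test_agrees_with_cor_targets_on_shared_pairs(self):
        rng = np.random.default_rng(42)
        vals = rng.standard_normal((20, 10))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        data = pd.DataFrame(vals, columns=[f"G{i}" for i in range(10)])
        sym = cor_map(data, min_n=5)
        tgt = cor_targets(data, "G0", min_n=5)
        merged = tgt.merge(
            sym[sym["target"] == "G0"], on=("target", "gene"),
            suffixes=("_t", "_s"),
        )
        assert len(merged) == 10
        np.testing.assert_allclose(
            merged["r_t"], merged["r_s"], atol=1e-12, equal_nan=True
        )
        np.testing.assert_allclose(
            merged["p_t"], merged["p_s"], atol=1e-12, equal_nan=True
        )


class TestRunChunked:
    def test_workers_and_chunking_do_not_change_results(self, recovery_screen):
        matrix, _, truth = recovery_screen
        targets = list(truth["gene"].iloc[[0, 5, 20, 25, 40, 45, 60, 61]])
        seq = run_chunked(matrix, targets, workers=1)
        par = run_chunked(matrix, targets, workers=4, chunk_size=3)
        pd.testing.assert_frame_equal(seq, par)

    def test_chunk_larger_than_tasks(self, tiny_matrix):
        one = run_chunked(tiny_matrix, ["GA", "GB"], chunk_size=10, min_n=3)
        two = cor_target_map(tiny_matrix, ["GA", "GB"], min_n=3)
        pd.testing.assert_frame_equal(one, two)

    def test_empty_task_list(self, tiny_matrix):
        table = run_chunked(tiny_matrix, [])
        assert len(table) == 0
        assert list(table.columns) == ["target", "gene", "r", "p", "q", "n"]

    def test_invalid_workers(self, tiny_matrix):
        with pytest.raises(ValueError):
            run_chunked(tiny_matrix, ["GA"], workers=0)
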