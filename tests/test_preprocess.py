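"""Loading, filtering, normalization, and adjacent-profile computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pseudocell_tracer.preprocess as pp


def _toy_expr(values, tag="tpm", genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    cells = cells or [f"c{i}" for i in range(values.shape[0])]
    return pp.ExpressionMatrix(values, genes, cells, tag)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadExpression:
    def test_csv_roundtrip_identity(self, tmp_path):
        df = pd.DataFrame(np.arange(12.0).reshape(3, 4),
                          index=["c0", "c1", "c2"],
                          columns=["gA", "gB", "gC", "gD"])
        path = tmp_path / "m.csv"
        df.to_csv(path)
        expr = pp.load_expression(path)
        assert expr.n_cells == 3 and expr.n_genes == 4
        assert expr.gene_ids == ["gA", "gB", "gC", "gD"]
        assert np.array_equal(expr.values, df.to_numpy())

    def test_transposed_csv_matches_untransposed(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 9, size=(3, 5)).astype(float)
        df = pd.DataFrame(vals, index=[f"c{i}" for i in range(3)],
                          columns=[f"g{j}" for j in range(5)])
        df.to_csv(tmp_path / "a.csv")
        df.T.to_csv(tmp_path / "b.csv")
        a = pp.load_expression(tmp_path / "a.csv")
        b = pp.load_expression(tmp_path / "b.csv", orientation="genes_by_cells")
        assert a.gene_ids == b.gene_ids and a.cell_ids == b.cell_ids
        assert np.array_equal(a.values, b.values)

    def test_mtx_roundtrip_keeps_zero_gene_column(self, tmp_path):
        vals = np.array([[1.0, 0.0, 3.0], [2.0, 0.0, 0.0]])
        expr = _toy_expr(vals, tag="raw_counts")
        pp.save_expression_mtx(expr, tmp_path)
        back = pp.load_expression(tmp_path / "matrix.mtx")
        assert back.gene_ids == expr.gene_ids  # all-zero column retained
        assert np.array_equal(back.values, vals)

    def test_mtx_missing_companion_is_format_error(self, tmp_path):
        expr = _toy_expr(np.ones((2, 2)), tag="raw_counts")
        pp.save_expression_mtx(expr, tmp_path)
        (tmp_path / "barcodes.tsv").unlink()
        with pytest.raises(pp.FormatError, match="barcodes"):
            pp.load_expression(tmp_path / "matrix.mtx")

    def test_duplicate_gene_ids_named_in_error(self, tmp_path):
        df = pd.DataFrame(np.ones((2, 3)), columns=["gA", "gB", "gA"],
                          index=["c0", "c1"])
        df.to_csv(tmp_path / "dup.csv")
        with pytest.raises(pp.FormatError, match="gA"):
            pp.load_expression(tmp_path / "dup.csv")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterZeroGenes:
    def test_drops_only_all_zero_genes(self):
        vals = np.zeros((4, 5))
        vals[:, 0] = 1
        vals[2, 2] = 3
        vals[0, 4] = 0.5
        out = pp.filter_zero_genes(_toy_expr(vals))
        assert out.gene_ids == ["g0", "g2", "g4"]

    def test_identity_when_no_zero_genes(self):
        vals = np.ones((3, 4))
        out = pp.filter_zero_genes(_toy_expr(vals))
        assert out.gene_ids == ["g0", "g1", "g2", "g3"]
        assert np.array_equal(out.values, vals)

    def test_matches_bruteforce_column_scan_and_is_idempotent(self):
        rng = np.random.default_rng(1)
        vals = rng.random((10, 20)) * (rng.random((10, 20)) < 0.15)
        expr = _toy_expr(vals)
        out = pp.filter_zero_genes(expr)
        expected = [f"g{j}" for j in range(20) if any(vals[i, j] != 0 for i in range(10))]
        assert out.gene_ids == expected
        again = pp.filter_zero_genes(out)
        assert again.gene_ids == out.gene_ids
        assert np.array_equal(again.values, out.values)

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all genes"):
            pp.filter_zero_genes(_toy_expr(np.zeros((3, 3))))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_known_values(self):
        expr = _toy_expr(np.array([[0.0, 1.0, 7.0]]), tag="tpm")
        out = pp.normalize_log2_tpm1(expr)
        assert np.allclose(out.values, [[0.0, 1.0, 3.0]])
        assert out.normalization_tag == pp.LOG2_TPM1

    def test_double_normalization_guard(self):
        expr = _toy_expr(np.ones((2, 2)), tag="log2_tpm1")
        with pytest.raises(ValueError, match="already"):
            pp.normalize_log2_tpm1(expr)

    def test_counts_are_scaled_per_million_first(self):
        counts = np.array([[100.0, 300.0], [10.0, 30.0]])
        out = pp.normalize_log2_tpm1(_toy_expr(counts, tag="raw_counts"))
        # both cells have the same composition -> identical normalized rows
        assert np.allclose(out.values[0], out.values[1])
        assert np.allclose(out.values[0], np.log2(np.array([0.25, 0.75]) * 1e6 + 1))

    @given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=2,
                    max_size=30, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone_per_entry(self, tpms):
        vals = np.array(tpms, dtype=float)
        out = np.log2(vals + 1.0)
        order_in = np.argsort(vals)
        order_out = np.argsort(out)
        assert np.array_equal(order_in, order_out)


# ---------------------------------------------------------------------------
# adjacent profiles
# ---------------------------------------------------------------------------

class TestAdjacentProfiles:
    channels = list(pp.DEFAULT_CHANNELS)

    def _expr(self, channel_block, extra=0):
        n = channel_block.shape[0]
        vals = np.hstack([channel_block, np.full((n, extra), 2.0)]) if extra \
            else channel_block
        genes = self.channels + [f"x{j}" for j in range(extra)]
        return _toy_expr(vals, tag="log2_tpm1", genes=genes)

    def test_single_isotype_cell_is_one_hot(self):
        block = np.zeros((1, 8))
        block[0, 0] = 5.0
        prof = pp.compute_adjacent_profiles(self._expr(block), self.channels)
        assert np.allclose(prof.weights[0], [1, 0, 0, 0, 0, 0, 0, 0])

    def test_equal_expression_splits_evenly(self):
        block = np.zeros((1, 8))
        block[0, 0] = block[0, 1] = 3.3
        prof = pp.compute_adjacent_profiles(self._expr(block), self.channels)
        assert np.allclose(prof.weights[0], [0.5, 0.5, 0, 0, 0, 0, 0, 0])

    def test_matches_rowsum_oracle_and_sums_to_one(self):
        rng = np.random.default_rng(2)
        block = rng.random((50, 8)) * 6
        prof = pp.compute_adjacent_profiles(self._expr(block, extra=4), self.channels)
        oracle = block / block.sum(axis=1, keepdims=True)
        assert np.allclose(prof.weights, oracle)
        assert np.allclose(prof.weights.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_non_channel_genes(self):
        rng = np.random.default_rng(3)
        block = rng.random((20, 8)) + 0.1
        a = pp.compute_adjacent_profiles(self._expr(block), self.channels)
        b = pp.compute_adjacent_profiles(self._expr(block, extra=7), self.channels)
        assert np.allclose(a.weights, b.weights)

    def test_zero_denominator_cell_gets_uniform_profile_with_warning(self):
        block = np.zeros((2, 8))
        block[0, 3] = 4.0  # cell 1 expresses nothing
        with pytest.warns(UserWarning, match="c1"):
            prof = pp.compute_adjacent_profiles(self._expr(block), self.channels)
        assert np.allclose(prof.weights[1], np.full(8, 1 / 8))
        assert np.all(np.isfinite(prof.weights))

    def test_missing_channel_gene_errors(self):
        expr = _toy_expr(np.ones((2, 3)), tag="log2_tpm1", genes=["a", "b", "c"])
        with pytest.raises(KeyError, match="Ighm"):
            pp.compute_adjacent_profiles(expr, self.channels)


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

class TestSelectVariableGenes:
    def test_k_equal_gene_count_is_identity(self):
        rng = np.random.default_rng(4)
        expr = _toy_expr(rng.random((10, 6)), tag="log2_tpm1")
        out = pp.select_variable_genes(expr, 6)
        assert out.gene_ids == expr.gene_ids
        assert np.array_equal(out.values, expr.values)

    def test_matches_exhaustive_variance_sort(self):
        rng = np.random.default_rng(5)
        vals = rng.random((30, 100)) * rng.random(100) * 5
        expr = _toy_expr(vals, tag="log2_tpm1")
        out = pp.select_variable_genes(expr, 10)
        expected = set(np.array(expr.gene_ids)[np.argsort(vals.var(axis=0))[-10:]])
        assert set(out.gene_ids) == expected
        # original order preserved among the selected
        idx = [expr.gene_ids.index(gid) for gid in out.gene_ids]
        assert idx == sorted(idx)

    def test_topk_nesting_property(self):
        rng = np.random.default_rng(6)
        expr = _toy_expr(rng.random((20, 50)) * rng.random(50), tag="log2_tpm1")
        small = set(pp.select_variable_genes(expr, 5).gene_ids)
        large = set(pp.select_variable_genes(expr, 20).gene_ids)
        assert small <= large

    def test_k_out_of_range_errors(self):
        expr = _toy_expr(np.ones((3, 4)), tag="log2_tpm1")
        with pytest.raises(ValueError):
            pp.select_variable_genes(expr, 5)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

class TestClusterProfiles:
    def test_recovers_three_separated_simplex_blobs(self):
        rng = np.random.default_rng(7)
        blobs = []
        truth = []
        for k in range(3):
            center = np.full(8, 0.02)
            center[k] = 1 - 0.02 * 7
            pts = np.abs(center + rng.normal(0, 0.01, size=(30, 8)))
            pts /= pts.sum(axis=1, keepdims=True)
            blobs.append(pts)
            truth += [k] * 30
        prof = pp.AdjacentProfiles(np.vstack(blobs), list(pp.DEFAULT_CHANNELS))
        labels, order = pp.cluster_adjacent_profiles(prof, n_clusters=3)
        df = pd.crosstab(np.array(truth), labels)
        assert (df.max(axis=1) == 30).all()  # each planted blob maps to one cluster
        assert sorted(order) == list(range(90))

    def test_identical_profiles_share_cluster(self):
        w = np.tile(np.full(8, 1 / 8), (4, 1))
        prof = pp.AdjacentProfiles(w, list(pp.DEFAULT_CHANNELS))
        labels, _ = pp.cluster_adjacent_profiles(prof, n_clusters=2)
        assert len(set(labels[:2])) == 1

    def test_single_cell_errors(self):
        prof = pp.AdjacentProfiles(np.full((1, 8), 1 / 8), list(pp.DEFAULT_CHANNELS))
        with pytest.raises(ValueError, match="2 cells"):
            pp.cluster_adjacent_profiles(prof)
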