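import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baculonet.expression import (
    ExpressionSeries,
    concatenate_replicates,
    read_expression_table,
    shuffle_time_points,
    write_expression_table,
)
from conftest import make_series


def write_table(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")


class TestReadExpressionTable:
    def test_toy_table_shape(self, tmp_path):
        path = tmp_path / "expr.tsv"
        header = ["orf_id"] + [f"rep1_t{t}" for t in (0, 1, 3, 5, 7, 9, 11, 13, 24, 48)]
        write_table(path, header, [[f"g{i}"] + [0.1 * i] * 10 for i in range(3)])
        series = read_expression_table(path, cell_line="toy")
        assert series.values.shape == (3, 10)
        assert series.cell_line == "toy"
        assert list(series.sample_times) == [0, 1, 3, 5, 7, 9, 11, 13, 24, 48]

    def test_blank_cell_imputed_at_floor_and_reported(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_table(
            path,
            ["orf_id", "rep1_t0", "rep1_t1", "rep1_t2", "rep1_t3", "rep1_t4"],
            [["a", 1, "", 3, 4, 5], ["b", 1, 2, 3, 4, 5]],
        )
        series = read_expression_table(path)
        assert series.values.shape == (2, 5)
        assert series.values[0, 1] == 0.0
        assert series.load_report["n_imputed"] == 1

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_table(path, ["orf_id", "rep1_t0", "rep1_t1"], [["a", 1, 2], ["a", 3, 4]])
        with pytest.raises(ValueError, match="duplicate"):
            read_expression_table(path)

    def test_non_numeric_cell_reported_with_coordinates(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_table(path, ["orf_id", "rep1_t0", "rep1_t1"], [["a", 1, "oops"]])
        with pytest.raises(ValueError, match=r"'oops'.*'a'.*rep1_t1"):
            read_expression_table(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "expr.tsv"
        write_table(path, ["orf_id", "sample1"], [["a", 1]])
        with pytest.raises(ValueError, match="sample1"):
            read_expression_table(path)

    def test_roundtrip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        series = make_series(rng.normal(size=(5, 10)) * np.pi)
        path = tmp_path / "roundtrip.tsv"
        write_expression_table(series, path)
        back = read_expression_table(path)
        assert back.gene_ids == series.gene_ids
        assert np.array_equal(back.values, series.values)
        assert np.array_equal(back.sample_times, series.sample_times)


class TestValidation:
    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            make_series([[1.0, np.nan]])

    def test_times_must_increase_within_replicate(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series([[1.0, 2.0]], times=[3.0, 1.0])


class TestConcatenateReplicates:
    def grids(self):
        times = [0, 1, 3, 5, 7, 9, 11, 13, 24, 48]
        return [
            make_series(np.full((2, 10), float(k)), times=times,
                        reps=[k] * 10, genes=["a", "b"])
            for k in (1, 2, 3)
        ]

    def test_three_replicates_become_thirty_columns(self):
        merged = concatenate_replicates(*self.grids())
        assert merged.n_samples == 30
        assert merged.replicates == [1, 2, 3]
        assert np.all(merged.values[:, :10] == 1.0)
        assert np.all(merged.values[:, 20:] == 3.0)

    def test_single_input_is_identity(self):
        s = self.grids()[0]
        out = concatenate_replicates(s)
        assert out.gene_ids == s.gene_ids
        assert np.array_equal(out.values, s.values)

    def test_rows_aligned_by_gene_id(self):
        s1, s2, _ = self.grids()
        s2_swapped = s2.subset(["b", "a"])
        merged = concatenate_replicates(s1, s2)
        merged_swapped = concatenate_replicates(s1, s2_swapped)
        assert merged.gene_ids == merged_swapped.gene_ids
        assert np.array_equal(merged.values, merged_swapped.values)

    def test_gene_mismatch_rejected(self):
        s1 = make_series(np.ones((2, 5)), genes=["a", "b"])
        s2 = make_series(np.ones((2, 5)), genes=["a", "c"])
        with pytest.raises(ValueError, match="gene id"):
            concatenate_replicates(s1, s2)

    def test_time_grid_mismatch_rejected(self):
        s1 = make_series(np.ones((2, 5)))
        s2 = make_series(np.ones((2, 5)), times=[0, 1, 2, 3, 9])
        with pytest.raises(ValueError, match="time grid"):
            concatenate_replicates(s1, s2)


class TestShuffleTimePoints:
    def test_per_gene_values_conserved_exactly(self, rng):
        series = make_series(rng.normal(size=(6, 12)))
        out = shuffle_time_points(series, seed=3)
        for i in range(6):
            assert np.array_equal(np.sort(out.values[i]), np.sort(series.values[i]))
        assert np.array_equal(out.sample_times, series.sample_times)

    def test_moments_preserved_exactly(self, rng):
        series = make_series(rng.normal(size=(4, 9)))
        out = shuffle_time_points(series, seed=11)
        # values are a per-gene permutation, so every order statistic and
        # (computed in a fixed summation order) every moment is preserved
        a, b = np.sort(out.values, axis=1), np.sort(series.values, axis=1)
        for stat in (np.mean, np.var, np.min, np.max):
            assert np.array_equal(stat(a, axis=1), stat(b, axis=1))

    def test_deterministic_under_fixed_seed(self, rng):
        series = make_series(rng.normal(size=(5, 8)))
        a = shuffle_time_points(series, seed=42)
        b = shuffle_time_points(series, seed=42)
        assert np.array_equal(a.values, b.values)

    def test_single_column_unchanged(self):
        series = make_series([[1.0], [2.0]])
        out = shuffle_time_points(series, seed=0)
        assert np.array_equal(out.values, series.values)

    def test_shared_mode_preserves_cross_gene_correlation(self, rng):
        base = rng.normal(size=20)
        values = np.vstack([base + rng.normal(0, 0.01, 20) for _ in range(8)])
        series = make_series(values)
        shared = shuffle_time_points(series, seed=5, mode="shared")
        corr = np.corrcoef(shared.values)
        off = corr[np.triu_indices(8, 1)]
        assert np.abs(off).mean() > 0.9

    def test_per_gene_mode_destroys_cross_gene_correlation(self, rng):
        base = rng.normal(size=30)
        values = np.vstack([base + rng.normal(0, 0.01, 30) for _ in range(10)])
        series = make_series(values)
        out = shuffle_time_points(series, seed=5, mode="per_gene")
        corr = np.corrcoef(out.values)
        off = corr[np.triu_indices(10, 1)]
        assert np.abs(off).mean() < 0.2

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        st.integers(1, 6), st.integers(2, 12),
        st.integers(0, 10_000), st.sampled_from(["per_gene", "shared"]),
    )
    def test_shuffle_is_a_permutation_for_any_shape(self, n_genes, n_samples, seed, mode):
        values = np.arange(n_genes * n_samples, dtype=float).reshape(n_genes, n_samples)
        series = make_series(values)
        out = shuffle_time_points(series, seed=seed, mode=mode)
        for i in range(n_genes):
            assert sorted(out.values[i]) == sorted(series.values[i])
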