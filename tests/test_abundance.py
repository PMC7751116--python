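"""Abundance-matrix parsing, normalisation, filtering and partitioning."""

import numpy as np
import pytest

from sbnet import (
    AbundanceError, AbundanceMatrix, TIME_COLUMN, add_time_variable,
    filter_top_taxa, normalize_relative, partition_periods,
    read_abundance, write_abundance,
)


class TestReadAbundance:
    def test_parses_tsv_counts(self, toy_counts):
        m = read_abundance(toy_counts)
        assert (m.n_samples, m.n_taxa) == (2, 3)
        assert m.sample_ids == ["s1", "s2"]
        assert m.taxon_names == ["taxA", "taxB", "taxC"]
        assert not m.is_relative
        np.testing.assert_array_equal(m.values, [[2, 3, 5], [1, 0, 9]])

    def test_round_trips_through_writer(self, toy_counts, tmp_path):
        m = read_abundance(toy_counts)
        out = tmp_path / "again.tsv"
        write_abundance(m, out)
        m2 = read_abundance(out)
        np.testing.assert_array_equal(m.values, m2.values)
        assert m2.taxon_names == m.taxon_names

    def test_reads_mothur_shared_table(self, tmp_path):
        path = tmp_path / "table.shared"
        path.write_text(
            "label\tGroup\tnumOtus\tOtu1\tOtu2\n"
            "0.03\tsampleA\t2\t10\t4\n"
            "0.03\tsampleB\t2\t0\t7\n"
        )
        m = read_abundance(path, format="shared")
        assert m.sample_ids == ["sampleA", "sampleB"]
        assert m.taxon_names == ["Otu1", "Otu2"]
        np.testing.assert_array_equal(m.values, [[10, 4], [0, 7]])

    def test_duplicate_taxon_column_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample_id\tA\tA\ns1\t1\t2\n")
        with pytest.raises(AbundanceError, match="duplicate taxon"):
            read_abundance(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(AbundanceError, match="no samples"):
            read_abundance(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tA\tB\ns1\t1\toops\n")
        with pytest.raises(AbundanceError, match=r"'s1'.*'B'"):
            read_abundance(path)


class TestNormalizeRelative:
    @pytest.mark.parametrize("row, expected", [
        ([2, 3, 5], [0.2, 0.3, 0.5]),
        ([1, 1, 1, 1], [0.25, 0.25, 0.25, 0.25]),
        ([0, 4, 6], [0.0, 0.4, 0.6]),
    ])
    def test_divides_rows_by_their_totals(self, row, expected):
        m = AbundanceMatrix([row], ["s1"], [f"t{i}" for i in range(len(row))])
        out = normalize_relative(m)
        np.testing.assert_allclose(out.values[0], expected)
        assert out.is_relative

    def test_zero_total_row_names_the_sample(self):
        m = AbundanceMatrix([[1, 1], [0, 0]], ["good", "empty"], ["a", "b"])
        with pytest.raises(AbundanceError, match="empty"):
            normalize_relative(m)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        m = AbundanceMatrix(rng.integers(1, 50, (10, 6)), range(10), range(6))
        out = normalize_relative(m)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)


class TestFilterTopTaxa:
    def _matrix(self, shares):
        return AbundanceMatrix(
            [list(shares)], ["s1"], [f"t{i}" for i in range(len(shares))],
            is_relative=True,
        )

    def test_keeps_smallest_prefix_reaching_coverage(self):
        # prefix sums 0.5, 0.8, 0.95, 0.99 -> 4 taxa at 99%
        m = self._matrix([0.5, 0.3, 0.15, 0.04, 0.009, 0.001])
        out = filter_top_taxa(m, coverage=0.99)
        assert out.taxon_names == ["t0", "t1", "t2", "t3"]

    def test_kept_set_is_minimal(self):
        m = self._matrix([0.5, 0.3, 0.15, 0.04, 0.009, 0.001])
        out = filter_top_taxa(m, coverage=0.99)
        # dropping the last kept taxon would fall below coverage
        assert 0.5 + 0.3 + 0.15 < 0.99 <= out.values.sum()

    def test_single_dominant_taxon(self):
        m = self._matrix([1.0])
        assert filter_top_taxa(m, 0.99).taxon_names == ["t0"]

    def test_full_coverage_keeps_all_nonzero(self):
        m = self._matrix([0.6, 0.4, 0.0])
        out = filter_top_taxa(m, coverage=1.0)
        assert out.taxon_names == ["t0", "t1"]
        assert out.is_relative  # rows still closed to 1

    @pytest.mark.parametrize("coverage", [0.0, -0.1, 1.5])
    def test_invalid_coverage_rejected(self, coverage):
        with pytest.raises(AbundanceError):
            filter_top_taxa(self._matrix([1.0]), coverage)

    def test_output_subset_and_column_order_preserved(self):
        rng = np.random.default_rng(11)
        vals = rng.dirichlet(np.ones(12) * 0.3, size=20)
        m = AbundanceMatrix(vals, range(20), [f"t{i:02d}" for i in range(12)],
                            is_relative=True)
        out = filter_top_taxa(m, 0.9)
        assert set(out.taxon_names) <= set(m.taxon_names)
        assert out.taxon_names == sorted(out.taxon_names,
                                         key=m.taxon_names.index)


class TestTimeHandling:
    def test_appends_time_pseudo_taxon(self):
        m = AbundanceMatrix(np.eye(3), list("abc"), list("xyz"),
                            times=[1.0, 2.0, 3.0])
        out = add_time_variable(m)
        assert out.taxon_names[-1] == TIME_COLUMN
        np.testing.assert_array_equal(out.values[:, -1], [1, 2, 3])

    def test_requires_times(self):
        m = AbundanceMatrix(np.eye(2), list("ab"), list("xy"))
        with pytest.raises(AbundanceError, match="no sampling times"):
            add_time_variable(m)

    def test_missing_time_value_rejected(self):
        with pytest.raises(AbundanceError, match="missing"):
            AbundanceMatrix(np.eye(2), list("ab"), list("xy"),
                            times=[1.0, np.nan])

    def test_adding_twice_rejected(self):
        m = AbundanceMatrix(np.eye(2), list("ab"), list("xy"),
                            times=[1.0, 2.0])
        with pytest.raises(AbundanceError, match="already present"):
            add_time_variable(add_time_variable(m))


class TestPartitionPeriods:
    def _mat(self, times):
        n = len(times)
        return AbundanceMatrix(np.arange(2 * n).reshape(n, 2),
                               [f"s{i}" for i in range(n)], ["a", "b"],
                               times=times)

    def test_equal_width_half_open_intervals(self):
        m = self._mat(list(range(11)))  # times 0..10
        first, last = partition_periods(m, 2)
        assert first.sample_ids == [f"s{i}" for i in range(5)]
        assert last.sample_ids == [f"s{i}" for i in range(5, 11)]

    def test_k1_is_identity(self):
        m = self._mat([0.0, 1.0, 5.0])
        (out,) = partition_periods(m, 1)
        assert out.sample_ids == m.sample_ids
        np.testing.assert_array_equal(out.values, m.values)

    def test_degenerate_time_axis_fills_last_period(self):
        m = self._mat([2.0, 2.0, 2.0])
        first, last = partition_periods(m, 2)
        assert first.n_samples == 0
        assert last.sample_ids == m.sample_ids

    def test_k_below_one_rejected(self):
        with pytest.raises(AbundanceError):
            partition_periods(self._mat([0.0, 1.0]), 0)

    @pytest.mark.parametrize("seed,k", [(0, 2), (1, 3), (2, 5)])
    def test_periods_partition_the_samples(self, seed, k):
        rng = np.random.default_rng(seed)
        m = self._mat(rng.uniform(0, 10, size=17).tolist())
        parts = partition_periods(m, k)
        ids = [s for p in parts for s in p.sample_ids]
        assert sorted(ids) == sorted(m.sample_ids)
        assert len(ids) == len(set(ids))


# ----------------------------------------------------------------------
# property tests

from hypothesis import given, settings, strategies as st  # noqa: E402

counts_tables = st.integers(1, 12).flatmap(
    lambda p: st.lists(
        st.lists(st.integers(0, 1000), min_size=p, max_size=p)
        .filter(lambda row: sum(row) > 0),
        min_size=1, max_size=10,
    )
)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(counts_tables)
def test_normalized_rows_always_sum_to_one(rows):
    m = AbundanceMatrix(rows, range(len(rows)), range(len(rows[0])))
    out = normalize_relative(m)
    np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(counts_tables, st.floats(0.05, 1.0))
def test_filter_keeps_minimal_prefix_for_any_coverage(rows, coverage):
    m = normalize_relative(
        AbundanceMatrix(rows, range(len(rows)), range(len(rows[0]))))
    out = filter_top_taxa(m, coverage)
    shares = dict(zip(m.taxon_names, m.values.mean(axis=0)))
    kept_mass = sum(shares[t] for t in out.taxon_names)
    dropped = [shares[t] for t in m.taxon_names if t not in set(out.taxon_names)]
    assert kept_mass >= min(coverage, sum(shares.values())) - 1e-9
    # minimality: removing the smallest kept taxon would break coverage
    if out.n_taxa:
        smallest = min(shares[t] for t in out.taxon_names)
        assert kept_mass - smallest < coverage
    # no dropped taxon outranks a kept one
    if dropped and out.n_taxa:
        assert max(dropped) <= min(shares[t] for t in out.taxon_names) + 1e-12
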