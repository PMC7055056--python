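import json
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from microcensus import (
    TaxonTable,
    incidence_tally,
    pool_corpus,
    read_taxon_table,
    to_incidence,
    write_taxon_table,
)
from microcensus.corpus_io import TableFormatError, read_biom_json


def _write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadLong:
    def test_example_triplets(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "s1\ttA\t3\ns1\ttB\t1\ns2\ttA\t2\n")
        table = read_taxon_table(p, dialect="long")
        assert table.sample_ids == ["s1", "s2"]
        assert table.taxon_ids == ["tA", "tB"]
        assert table.sample_totals.tolist() == [4, 2]
        assert table.to_dense().tolist() == [[3, 1], [2, 0]]

    def test_header_row_is_skipped(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "sample\ttaxon\tcount\ns1\ttA\t3\n")
        table = read_taxon_table(p, dialect="long")
        assert table.sample_ids == ["s1"]

    def test_duplicate_pair_rejected_with_row_number(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "s1\ttA\t3\ns1\ttA\t1\n")
        with pytest.raises(TableFormatError, match="row 2"):
            read_taxon_table(p, dialect="long")

    def test_negative_count_rejected(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "s1\ttA\t3\ns2\ttA\t-1\n")
        with pytest.raises(TableFormatError, match="row 2"):
            read_taxon_table(p, dialect="long")

    def test_fractional_count_rejected(self, tmp_path):
        p = _write(tmp_path / "t.tsv", "s1\ttA\t0.5\n")
        with pytest.raises(TableFormatError, match="not a non-negative integer"):
            read_taxon_table(p, dialect="long")

    def test_comma_delimiter_sniffed(self, tmp_path):
        p = _write(tmp_path / "t.csv", "s1,tA,3\ns2,tA,2\n")
        table = read_taxon_table(p, dialect="long")
        assert table.sample_totals.tolist() == [3, 2]


class TestReadWide:
    def test_wide_equivalent_to_long(self, tmp_path):
        long_p = _write(tmp_path / "l.tsv", "s1\ttA\t3\ns1\ttB\t1\ns2\ttA\t2\n")
        wide_p = _write(
            tmp_path / "w.tsv", "sample\ttA\ttB\ns1\t3\t1\ns2\t2\t0\n"
        )
        assert read_taxon_table(long_p, "long") == read_taxon_table(wide_p, "wide")

    def test_zero_total_sample_dropped_with_warning(self, tmp_path, caplog):
        p = _write(
            tmp_path / "w.tsv", "sample\ttA\ttB\ns1\t3\t1\ns2\t0\t0\n"
        )
        with caplog.at_level(logging.WARNING, logger="microcensus.corpus_io"):
            table = read_taxon_table(p, "wide")
        assert table.sample_ids == ["s1"]
        assert any("zero total" in r.message for r in caplog.records)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write(tmp_path / "w.tsv", "sample\ttA\ns1\t3\ns1\t2\n")
        with pytest.raises(TableFormatError, match="duplicate sample"):
            read_taxon_table(p, "wide")

    def test_bad_cell_rejected_with_location(self, tmp_path):
        p = _write(tmp_path / "w.tsv", "sample\ttA\ns1\t3\ns2\tx\n")
        with pytest.raises(TableFormatError, match="row 3"):
            read_taxon_table(p, "wide")


class TestTaxonTable:
    def test_duplicate_taxon_ids_rejected(self):
        with pytest.raises(TableFormatError, match="duplicate taxon"):
            TaxonTable(["s1"], ["t", "t"], np.array([[1, 2]]))

    def test_fractional_counts_rejected(self):
        with pytest.raises(TableFormatError, match="integers"):
            TaxonTable.from_dense([[0.5, 1.0]])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(TableFormatError, match="shape"):
            TaxonTable(["s1"], ["t1"], np.array([[1, 2]]))


class TestRoundTrip:
    @settings(max_examples=25, deadline=None)
    @given(
        counts=hnp.arrays(
            np.int64,
            st.tuples(st.integers(1, 5), st.integers(1, 5)),
            elements=st.integers(0, 50),
        )
    )
    def test_write_read_exact(self, counts, tmp_path_factory):
        counts = np.asarray(counts)
        keep = counts.sum(axis=1) > 0
        if not keep.any():
            counts[0, 0] = 1
            keep = counts.sum(axis=1) > 0
        table = TaxonTable.from_dense(counts).drop_empty_samples()
        tmp = tmp_path_factory.mktemp("rt")
        for dialect in ("long", "wide"):
            path = tmp / f"t.{dialect}.tsv"
            write_taxon_table(table, path, dialect=dialect)
            # the long dialect cannot represent all-zero taxon columns and
            # orders taxa by first appearance; compare canonical frames
            expected = table if dialect == "wide" else table.drop_empty_taxa()
            got = read_taxon_table(path, dialect=dialect)
            assert got.sample_ids == expected.sample_ids
            assert sorted(got.taxon_ids) == sorted(expected.taxon_ids)
            assert got.to_frame().sort_index(axis=1).equals(
                expected.to_frame().sort_index(axis=1)
            )


class TestToIncidence:
    def test_threshold_one(self, toy_table):
        inc = to_incidence(toy_table, threshold=1)
        assert inc.presence.toarray().tolist() == [[1, 0], [1, 1]]
        assert inc.m == 2

    def test_threshold_two(self, toy_table):
        inc = to_incidence(toy_table, threshold=2)
        assert inc.presence.toarray().tolist() == [[1, 0], [0, 1]]

    def test_threshold_below_one_rejected(self, toy_table):
        with pytest.raises(ValueError, match="threshold"):
            to_incidence(toy_table, threshold=0)

    def test_column_sums_count_containing_samples(self, rng):
        counts = rng.integers(0, 4, size=(8, 6))
        table = TaxonTable.from_dense(counts).drop_empty_samples()
        inc = to_incidence(table)
        expected = (table.to_dense() >= 1).sum(axis=0)
        assert inc.incidence_counts.tolist() == expected.tolist()

    def test_all_zero_taxa_flagged_but_retained(self):
        table = TaxonTable.from_dense([[1, 1], [1, 1]])
        inc = to_incidence(table, threshold=2)
        assert inc.taxon_ids == table.taxon_ids
        assert inc.empty_taxa.tolist() == [True, True]


class TestIncidenceTally:
    def test_hand_count_example(self):
        # presence column sums (1, 1, 2, 5) over 5 samples
        counts = np.zeros((5, 4), dtype=int)
        counts[0, 0] = 2
        counts[1, 1] = 1
        counts[0:2, 2] = 1
        counts[:, 3] = 3
        tally = incidence_tally(TaxonTable.from_dense(counts))
        assert dict(tally.tally) == {1: 2, 2: 1, 5: 1}
        assert tally.fraction_rare == pytest.approx(0.75)
        assert tally.n_rare == 3

    def test_everything_everywhere(self):
        table = TaxonTable.from_dense(np.ones((4, 7), dtype=int))
        tally = incidence_tally(table)
        assert dict(tally.tally) == {4: 7}
        assert tally.fraction_rare == 0.0

    def test_total_matches_observed_taxa(self, rng):
        counts = rng.integers(0, 3, size=(6, 10))
        counts[0] += 1  # no empty samples
        table = TaxonTable.from_dense(counts)
        tally = incidence_tally(table)
        assert sum(tally.tally.values()) == tally.n_observed
        assert tally.n_observed == int(((counts > 0).sum(axis=0) > 0).sum())

    def test_permutation_invariance(self, rng):
        counts = rng.integers(0, 3, size=(5, 8)) + 1
        table = TaxonTable.from_dense(counts)
        perm = rng.permutation(5)
        shuffled = TaxonTable.from_dense(
            counts[perm], sample_ids=[f"s{i}" for i in perm]
        )
        assert incidence_tally(table).tally == incidence_tally(shuffled).tally


class TestPoolCorpus:
    def test_example(self, toy_table):
        pooled = pool_corpus(toy_table)
        assert pooled.tolist() == [4, 2]
        assert pooled.sum() == 6
        assert pooled[0] == 4

    def test_single_sample_identity(self):
        table = TaxonTable.from_dense([[5, 1, 3]])
        assert pool_corpus(table).tolist() == [5, 3, 1]

    def test_sample_permutation_invariance(self, rng):
        counts = rng.integers(0, 5, size=(6, 9)) + 1
        table = TaxonTable.from_dense(counts)
        perm = rng.permutation(6)
        shuffled = TaxonTable.from_dense(
            counts[perm], sample_ids=[f"s{i}" for i in perm]
        )
        assert pool_corpus(table).tolist() == pool_corpus(shuffled).tolist()

    def test_empty_table_rejected(self):
        table = TaxonTable(["s1"], ["t1"], np.array([[0]]))
        with pytest.raises(ValueError, match="empty"):
            pool_corpus(table)


def test_biom_json_reader(tmp_path):
    doc = {
        "rows": [{"id": "tA"}, {"id": "tB"}],
        "columns": [{"id": "s1"}, {"id": "s2"}],
        "matrix_type": "sparse",
        "data": [[0, 0, 3], [1, 0, 1], [0, 1, 2]],
    }
    path = tmp_path / "t.biom"
    path.write_text(json.dumps(doc), encoding="utf-8")
    table = read_biom_json(path)
    assert table.sample_ids == ["s1", "s2"]
    assert table.to_dense().tolist() == [[3, 1], [2, 0]]
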