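import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import microcda as m
from microcda.tables import (
    TableValidationError,
    genus_labels,
    parse_lineage,
)


def _write_tsv(path, text):
    path.write_text(text)
    return path


class TestReadWrite:
    def test_round_trip_shape(self, tmp_path, toy_table):
        p = tmp_path / "t.tsv"
        m.write_count_table(toy_table, p)
        back = m.read_count_table(p)
        assert back.shape == (3, 4)
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)

    def test_round_trip_random(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(0, 50, size=(5, 7)),
            index=[f"s{i}" for i in range(5)],
            columns=[f"f{j}" for j in range(7)],
        )
        table = m.CountTable(df)
        p = tmp_path / "r.tsv"
        m.write_count_table(table, p)
        pd.testing.assert_frame_equal(
            m.read_count_table(p).counts, df.astype(np.int64)
        )

    def test_features_as_rows_orientation(self, tmp_path, toy_table):
        p = tmp_path / "t.tsv"
        toy_table.counts.T.to_csv(p, sep="\t", index_label="feature_id")
        back = m.read_count_table(p, orientation="features-as-rows")
        pd.testing.assert_frame_equal(back.counts, toy_table.counts)

    def test_negative_cell_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "bad.tsv",
                       "sample_id\tf1\tf2\ns1\t3\t-1\ns2\t0\t2\n")
        with pytest.raises(TableValidationError, match="negative"):
            m.read_count_table(p)

    def test_non_numeric_cell_named(self, tmp_path):
        p = _write_tsv(tmp_path / "bad.tsv",
                       "sample_id\tf1\tf2\ns1\t3\tx\ns2\t0\t2\n")
        with pytest.raises(TableValidationError, match="s1.*f2"):
            m.read_count_table(p)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = _write_tsv(tmp_path / "bad.tsv",
                       "sample_id\tf1\ns1\t3\ns1\t4\n")
        with pytest.raises(TableValidationError, match="duplicate"):
            m.read_count_table(p)

    def test_metadata_round_trip(self, tmp_path, toy_meta):
        p = tmp_path / "meta.tsv"
        m.write_metadata(toy_meta, p)
        back = m.read_metadata(p)
        assert back.groups.to_dict() == toy_meta.groups.to_dict()

    def test_taxonomy_round_trip(self, tmp_path):
        tax = m.TaxonomyMap({
            "a": parse_lineage("d__Bacteria;p__P;c__C;o__O;f__F;g__G"),
            "b": parse_lineage("d__Bacteria;p__P"),
        })
        p = tmp_path / "tax.tsv"
        m.write_taxonomy(tax, p)
        back = m.read_taxonomy(p)
        assert back.lineage("a") == tax.lineage("a")
        assert back.lineage("b")[2:] == ("unassigned",) * 4


class TestPrevalenceFilter:
    def test_present_everywhere_retained(self, toy_table, toy_meta):
        out = m.prevalence_filter(toy_table, toy_meta)
        assert "f4" in out.feature_ids  # nonzero in every sample

    def test_half_prevalence_is_inclusive(self, four_sample_meta):
        # nonzero in exactly 1 of 2 samples per group: 50% -> retained
        df = pd.DataFrame(
            {"f1": [3, 0, 5, 0], "f2": [1, 1, 1, 1]},
            index=["s1", "s2", "s3", "s4"],
        )
        out = m.prevalence_filter(m.CountTable(df), four_sample_meta, 0.5)
        assert out.feature_ids == ["f1", "f2"]

    def test_one_sided_feature_removed(self, four_sample_meta):
        # 100% of group A, 0% of group B -> removed
        df = pd.DataFrame(
            {"f1": [3, 2, 0, 0], "f2": [1, 1, 1, 1]},
            index=["s1", "s2", "s3", "s4"],
        )
        out = m.prevalence_filter(m.CountTable(df), four_sample_meta, 0.5)
        assert out.feature_ids == ["f2"]

    def test_idempotent(self, signal_dataset):
        _, table, _, meta, _ = signal_dataset
        once = m.prevalence_filter(table, meta)
        twice = m.prevalence_filter(once, meta)
        assert once.feature_ids == twice.feature_ids

    def test_after_pseudocount_keeps_everything(self, toy_table, toy_meta):
        out = m.prevalence_filter(m.add_pseudocount(toy_table), toy_meta)
        assert out.feature_ids == toy_table.feature_ids


class TestPseudocount:
    def test_all_zero_becomes_all_one(self):
        df = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["x", "y"])
        out = m.add_pseudocount(m.CountTable(df), 1)
        assert (out.matrix == 1).all()

    def test_increments_cells(self, toy_table):
        out = m.add_pseudocount(toy_table, 1)
        assert out.counts.loc["s1", "f1"] == 6

    def test_preserves_min_shift(self, toy_table):
        out = m.add_pseudocount(toy_table, 1)
        assert out.matrix.min() == toy_table.matrix.min() + 1

    @pytest.mark.parametrize("bad", [0, -1, -0.5])
    def test_nonpositive_value_rejected(self, toy_table, bad):
        with pytest.raises(ValueError):
            m.add_pseudocount(toy_table, bad)


class TestCollapse:
    @pytest.fixture
    def tax(self):
        lin = "d__Bacteria;p__P;c__C;o__O;f__F;g__{}"
        return m.TaxonomyMap({
            "f1": parse_lineage(lin.format("G1")),
            "f2": parse_lineage(lin.format("G1")),
            "f3": parse_lineage(lin.format("G2")),
            "f4": parse_lineage("d__Bacteria;p__P;c__C;o__Oscillospirales"),
        })

    def test_same_genus_summed(self, toy_table, tax):
        out = m.collapse_to_genus(toy_table, tax)
        assert out.counts.loc["s1", "g__G1"] == 5 + 0

    def test_totals_conserved(self, toy_table, tax):
        out = m.collapse_to_genus(toy_table, tax)
        pd.testing.assert_series_equal(out.totals(), toy_table.totals())

    def test_unassigned_keeps_deepest_rank(self, toy_table, tax):
        out = m.collapse_to_genus(toy_table, tax)
        assert "o__Oscillospirales" in out.feature_ids

    def test_distinct_genera_relabels_only(self, toy_table):
        lin = "d__B;p__P;c__C;o__O;f__F;g__G{}"
        tax = m.TaxonomyMap({
            f"f{i}": parse_lineage(lin.format(i)) for i in range(1, 5)
        })
        out = m.collapse_to_genus(toy_table, tax)
        assert out.shape == toy_table.shape

    def test_missing_asv_listed(self, toy_table):
        tax = m.TaxonomyMap({"f1": parse_lineage("d__B")})
        with pytest.raises(TableValidationError, match="f2"):
            m.collapse_to_genus(toy_table, tax)

    def test_label_collision_uses_lineage(self):
        # same genus token under two different families stays distinct
        df = pd.DataFrame([[1, 2]], index=["s1"], columns=["a", "b"])
        tax = m.TaxonomyMap({
            "a": parse_lineage("d__B;p__P;c__C;o__O;f__F1;g__G"),
            "b": parse_lineage("d__B;p__P;c__C;o__O;f__F2;g__G"),
        })
        out = m.collapse_to_genus(m.CountTable(df), tax)
        assert out.shape[1] == 2

    def test_genus_labels_consistency(self, toy_table, tax):
        labels = genus_labels(toy_table.feature_ids, tax)
        out = m.collapse_to_genus(toy_table, tax)
        assert set(labels.values()) == set(out.feature_ids)


class TestRarefy:
    def test_totals_equal_depth(self, signal_dataset):
        _, table, _, _, _ = signal_dataset
        out = m.rarefy(table, 5000, seed=0)
        assert (out.totals() == 5000).all()

    def test_exhaustive_draw_identity(self):
        df = pd.DataFrame([[3, 4, 3]], index=["s"], columns=list("abc"))
        out = m.rarefy(m.CountTable(df), 10, seed=1)
        pd.testing.assert_frame_equal(out.counts, df)

    def test_seed_reproducible(self, signal_dataset):
        _, table, _, _, _ = signal_dataset
        a = m.rarefy(table, 5000, seed=7)
        b = m.rarefy(table, 5000, seed=7)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_never_exceeds_original(self, toy_table):
        out = m.rarefy(toy_table, 5, seed=3)
        assert (out.counts.values <=
                toy_table.counts.loc[out.sample_ids].values).all()

    def test_under_depth_samples_dropped(self, toy_table):
        out = m.rarefy(toy_table, 9, seed=0)  # s3 has total 8
        assert "s3" not in out.sample_ids

    def test_depth_exceeding_all_errors(self, toy_table):
        with pytest.raises(TableValidationError):
            m.rarefy(toy_table, 100, seed=0)

    def test_hypergeometric_expectation(self):
        # expected rarefied count = depth * count / total
        counts = np.array([40, 30, 20, 10])
        df = pd.DataFrame([counts], index=["s"], columns=list("abcd"))
        table = m.CountTable(df)
        depth, n_rep = 50, 1000
        draws = np.array([
            m.rarefy(table, depth, seed=i).matrix[0] for i in range(n_rep)
        ])
        expect = depth * counts / counts.sum()
        # hypergeometric variance for each feature
        n_tot = counts.sum()
        var = (depth * (counts / n_tot) * (1 - counts / n_tot)
               * (n_tot - depth) / (n_tot - 1))
        se = np.sqrt(var / n_rep)
        assert (np.abs(draws.mean(axis=0) - expect) < 3 * se + 1e-9).all()


class TestOutlierScreen:
    def test_homogeneous_cloud_untouched(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.integers(50, 100, size=(30, 10)),
            index=[f"s{i}" for i in range(30)],
            columns=[f"f{j}" for j in range(10)],
        )
        _, removed = m.pca_outlier_screen(m.CountTable(df), k_sd=6)
        assert removed == []

    def test_gross_outlier_removed(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 100, size=(20, 10))
        counts[0] = [10_000, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        df = pd.DataFrame(counts, index=[f"s{i}" for i in range(20)],
                          columns=[f"f{j}" for j in range(10)])
        kept, removed = m.pca_outlier_screen(m.CountTable(df), k_sd=3)
        assert removed == ["s0"]
        assert "s0" not in kept.sample_ids

    def test_infinite_threshold_is_identity(self, toy_table):
        kept, removed = m.pca_outlier_screen(toy_table, k_sd=np.inf)
        assert removed == []
        assert kept.sample_ids == toy_table.sample_ids


@given(st.integers(1, 20), st.integers(0, 2**32 - 1))
def test_pseudocount_then_filter_property(value, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        rng.integers(0, 5, size=(4, 3)),
        index=["s1", "s2", "s3", "s4"],
        columns=["f1", "f2", "f3"],
    )
    meta = m.SampleMetadata(pd.Series(
        {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}, name="group"))
    out = m.prevalence_filter(m.add_pseudocount(m.CountTable(df), value), meta)
    assert out.feature_ids == ["f1", "f2", "f3"]
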