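"""Abundance counting, rank rollup, top-N display tables, matrix merging."""

import io

import numpy as np
import pytest
from hypothesis import given

from samsa.aggregation import (
    OTHER_LABEL,
    AbundanceTable,
    Lineage,
    TaxonomyMap,
    aggregate_counts,
    merge_to_matrix,
    read_abundance_tsv,
    read_matrix_tsv,
    read_taxonomy_tsv,
    relative_abundance,
    rollup_rank,
    sort_abundance,
    top_n_other,
    write_abundance_tsv,
    write_matrix_tsv,
)
from samsa.annotation_io import AnnotationRecord, SourceDB
from samsa.synthetic_data import sim_annotations

from conftest import abundance_tables


def _rec(read_id, text, db=SourceDB.REFSEQ_ORG):
    return AnnotationRecord(read_id, text, db)


def _table(counts, db=SourceDB.REFSEQ_ORG):
    return AbundanceTable("t", db, {k: float(v) for k, v in counts.items()})


class TestAggregateCounts:
    def test_count_all(self):
        recs = [_rec("r1", "E coli"), _rec("r2", "E coli"), _rec("r3", "B fragilis")]
        t = aggregate_counts(recs)
        assert t.counts == {"E coli": 2.0, "B fragilis": 1.0}
        assert t.total == 3.0

    def test_fractional_splits_tied_read(self):
        recs = [_rec("r1", "A"), _rec("r1", "B")]
        t = aggregate_counts(recs, "fractional")
        assert t.counts == {"A": 0.5, "B": 0.5}
        assert t.total == 1.0

    def test_count_all_counts_tied_read_twice(self):
        recs = [_rec("r1", "A"), _rec("r1", "B")]
        assert aggregate_counts(recs, "count_all").total == 2.0

    def test_mixed_source_db_rejected(self):
        recs = [_rec("r1", "A"), _rec("r2", "B", SourceDB.SUBSYSTEMS)]
        with pytest.raises(ValueError, match="mix"):
            aggregate_counts(recs)

    def test_generator_proportions_within_3_binomial_sd(self, community):
        """Counts from 10,000 planted reads track the planted proportions."""
        n = 10_000
        recs = sim_annotations(community, n, seed=7)
        t = aggregate_counts(recs)
        assert t.total == n
        for taxon, p in zip(community.taxa, community.true_proportions):
            sd = np.sqrt(n * p * (1 - p))
            assert abs(t.counts.get(taxon, 0.0) - n * p) <= 3 * sd + 1


class TestSortAbundance:
    def test_tie_break_lexicographic(self):
        ordered = sort_abundance(_table({"A": 1, "B": 3, "C": 3}))
        assert ordered == [("B", 3.0), ("C", 3.0), ("A", 1.0)]

    def test_empty(self):
        assert sort_abundance(_table({})) == []

    @given(abundance_tables())
    def test_permutation_non_increasing(self, table):
        ordered = sort_abundance(table)
        assert dict(ordered) == table.counts
        counts = [c for _, c in ordered]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


TAX = TaxonomyMap(
    {
        "Escherichia coli": Lineage(
            "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
            "Enterobacteriaceae", "Escherichia",
        ),
        "Shigella flexneri": Lineage(
            "Proteobacteria", "Gammaproteobacteria", "Enterobacterales",
            "Enterobacteriaceae", "Shigella",
        ),
    }
)


class TestRollup:
    def test_family_rollup_sums(self):
        t = _table({"Escherichia coli": 5, "Shigella flexneri": 2})
        rolled = rollup_rank(t, TAX, "family")
        assert rolled.counts == {"Enterobacteriaceae": 7.0}

    def test_unmapped_goes_to_unclassified(self):
        t = _table({"Escherichia coli": 5, "Mystery bug": 3})
        rolled = rollup_rank(t, TAX, "phylum")
        assert rolled.counts["unclassified"] == 3.0

    def test_unknown_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            rollup_rank(_table({"x": 1}), TAX, "kingdom")

    def test_genus_fallback_without_map(self):
        t = _table({"Escherichia coli": 5, "Escherichia albertii": 1})
        rolled = rollup_rank(t, None, "genus")
        assert rolled.counts == {"Escherichia": 6.0}

    def test_coarse_rank_without_map_rejected(self):
        with pytest.raises(ValueError, match="TaxonomyMap"):
            rollup_rank(_table({"x": 1}), None, "phylum")

    def test_conservation_on_community(self, community):
        from samsa.synthetic_data import sim_abundance_table

        t = sim_abundance_table(community, 5000, seed=3)
        tax = community.taxonomy_map()
        for rank in ("phylum", "class", "order", "family", "genus"):
            assert rollup_rank(t, tax, rank).total == t.total


class TestTopNOther:
    def test_40_taxa_top30_conserves(self):
        t = _table({f"t{i:02d}": i + 1 for i in range(40)})
        out = top_n_other(t, 30)
        assert len(out.counts) == 31
        assert out.total == t.total
        assert out.counts[OTHER_LABEL] == sum(range(1, 11))

    def test_fewer_taxa_than_n_unchanged(self):
        t = _table({"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        out = top_n_other(t, 30)
        assert out.counts == t.counts and OTHER_LABEL not in out.counts

    def test_drop_mode_discards_remainder(self):
        t = _table({f"t{i}": i + 1 for i in range(10)})
        out = top_n_other(t, 3, mode="drop")
        assert len(out.counts) == 3 and out.total < t.total

    def test_reserved_label_escaped(self):
        t = _table({"Other": 5, "a": 3, "b": 1})
        out = top_n_other(t, 2)
        assert out.counts == {"Other_": 5.0, "a": 3.0, OTHER_LABEL: 1.0}

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n_other(_table({"a": 1}), 0)


class TestRelativeAbundance:
    def test_simple(self):
        assert relative_abundance(_table({"A": 3, "B": 1})) == {"A": 0.75, "B": 0.25}

    def test_single_key(self):
        assert relative_abundance(_table({"X": 7})) == {"X": 1.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            relative_abundance(_table({"A": 0}))

    @given(abundance_tables(integer=False))
    def test_sums_to_one(self, table):
        if table.total == 0:
            return
        assert abs(sum(relative_abundance(table).values()) - 1.0) < 1e-9


class TestMergeToMatrix:
    def test_union_with_zeros(self):
        t1 = AbundanceTable("s1", SourceDB.REFSEQ_ORG, {"A": 1.0})
        t2 = AbundanceTable("s2", SourceDB.REFSEQ_ORG, {"B": 2.0})
        cm = merge_to_matrix([t1, t2])
        assert cm.values.shape == (2, 2)
        assert cm.values.loc["A", "s2"] == 0
        assert cm.values.loc["B", "s1"] == 0

    def test_single_table_round_trips(self):
        t = AbundanceTable("s1", SourceDB.REFSEQ_ORG, {"A": 3.0, "B": 1.0})
        cm = merge_to_matrix([t])
        assert dict(cm.values["s1"]) == t.counts

    def test_duplicate_sample_rejected(self):
        t = AbundanceTable("s1", SourceDB.REFSEQ_ORG, {"A": 1.0})
        with pytest.raises(ValueError, match="duplicate"):
            merge_to_matrix([t, t])

    def test_column_sums_match_totals(self, community):
        from samsa.synthetic_data import sim_abundance_table

        tables = [
            sim_abundance_table(community, 2000, seed=i, sample_id=f"s{i}")
            for i in range(10)
        ]
        cm = merge_to_matrix(tables, {f"s{i}": "A" for i in range(10)})
        for t in tables:
            assert cm.values[t.sample_id].sum() == t.total


class TestTsvRoundTrips:
    def test_abundance_tsv(self, tmp_path):
        t = AbundanceTable("s9", SourceDB.SUBSYSTEMS, {"A b": 3.0, "C": 1.0})
        p = tmp_path / "t.tsv"
        write_abundance_tsv(t, p, header_comments=["seed=1"])
        back = read_abundance_tsv(p)
        assert back.counts == t.counts
        assert back.sample_id == "s9"
        assert back.source_db == SourceDB.SUBSYSTEMS

    def test_matrix_tsv(self, tmp_path):
        t1 = AbundanceTable("s1", SourceDB.REFSEQ_ORG, {"A": 1.0, "B": 4.0})
        t2 = AbundanceTable("s2", SourceDB.REFSEQ_ORG, {"B": 2.0})
        cm = merge_to_matrix([t1, t2], {"s1": "wt", "s2": "ko"})
        write_matrix_tsv(cm, tmp_path / "m.tsv", tmp_path / "g.tsv")
        back = read_matrix_tsv(tmp_path / "m.tsv", tmp_path / "g.tsv")
        assert (back.values == cm.values).all().all()
        assert back.groups == cm.groups

    def test_taxonomy_tsv(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text(
            "organism\tphylum\tclass\torder\tfamily\tgenus\tis_bacterial\n"
            "Methanobrevibacter smithii\tEuryarchaeota\tMethanobacteria\t"
            "Methanobacteriales\tMethanobacteriaceae\tMethanobrevibacter\tfalse\n"
        )
        tax = read_taxonomy_tsv(p)
        lin = tax.get("Methanobrevibacter smithii")
        assert lin.genus == "Methanobrevibacter" and not lin.is_bacterial
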