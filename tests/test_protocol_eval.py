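"""Ribodepletion bias, mRNA/rRNA concordance, paired-vs-single-end comparison."""

import numpy as np
import pytest

from samsa.aggregation import AbundanceTable, aggregate_counts, rollup_rank
from samsa.annotation_io import SourceDB, filter_rrna
from samsa.protocol_eval import (
    compare_pe_sr,
    depletion_percent,
    rank_correlation,
    simulate_single_end,
    truncate_reads,
)
from samsa.synthetic_data import sim_depleted_pair, sim_fastq


def _table(counts, sid="t", db=SourceDB.SILVA_SSU):
    return AbundanceTable(sid, db, {k: float(v) for k, v in counts.items()})


class TestDepletion:
    def test_identical_relative_abundances_score_zero(self):
        c = _table({"Firmicutes": 100, "Bacteroidetes": 300})
        d = _table({"Firmicutes": 50, "Bacteroidetes": 150})  # same proportions
        rep = depletion_percent(c, d)
        assert all(abs(r.depletion_percent) < 1e-9 for r in rep.rows)

    def test_taxon_absent_from_depleted_scores_100(self):
        c = _table({"A": 50, "B": 50})
        d = _table({"A": 100})
        rep = depletion_percent(c, d).as_dict()
        assert rep["B"] == 100.0

    def test_taxon_absent_from_control_excluded(self):
        c = _table({"A": 100})
        d = _table({"A": 50, "B": 50})
        rep = depletion_percent(c, d)
        assert rep.excluded_taxa == ["B"]
        assert [r.taxon for r in rep.rows] == ["A"]

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            depletion_percent(_table({}), _table({"A": 1}))

    def test_invariant_to_library_scaling(self):
        c = _table({"A": 10, "B": 30, "C": 60})
        d = _table({"A": 5, "B": 30, "C": 65})
        base = depletion_percent(c, d).as_dict()
        scaled = depletion_percent(
            _table({k: 7 * v for k, v in c.counts.items()}),
            _table({k: 3 * v for k, v in d.counts.items()}),
        ).as_dict()
        for taxon in base:
            assert base[taxon] == pytest.approx(scaled[taxon])

    def test_mean_over_pairs(self):
        c1, d1 = _table({"A": 50, "B": 50}), _table({"A": 25, "B": 75})
        c2, d2 = _table({"A": 50, "B": 50}), _table({"A": 50, "B": 50})
        rep = depletion_percent([c1, c2], [d1, d2]).as_dict()
        assert rep["A"] == pytest.approx((100 * (1 - 0.25 / 0.5) + 0.0) / 2)

    def test_planted_retention_recovered(self, rrna_community):
        """Per-phylum retention factors are recovered through the full chain."""
        tax = rrna_community.taxonomy_map()
        expected = rrna_community.expected_depletion_percent()
        estimates = {p: [] for p in expected}
        for seed in range(4):
            pair = sim_depleted_pair(rrna_community, 30_000, seed=seed)
            _, c_r = filter_rrna(pair.control)
            _, d_r = filter_rrna(pair.depleted)
            cp = rollup_rank(aggregate_counts(c_r, sample_id="c"), tax, "phylum")
            dp = rollup_rank(aggregate_counts(d_r, sample_id="d"), tax, "phylum")
            for taxon, val in depletion_percent(cp, dp).as_dict().items():
                estimates[taxon].append(val)
        for phylum, vals in estimates.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected[phylum]) <= 3 * se + 2.0


class TestRankCorrelation:
    def _tax(self, community):
        return community.taxonomy_map()

    def test_proportional_tables_give_one(self, community):
        tax = self._tax(community)
        m = _table({t: 10 * (i + 1) for i, t in enumerate(community.taxa[:8])},
                   db=SourceDB.REFSEQ_ORG)
        r = _table({t: 30 * (i + 1) for i, t in enumerate(community.taxa[:8])})
        assert rank_correlation(m, r, tax, "genus") == pytest.approx(1.0)

    def test_anti_ordered_four_taxa_gives_minus_one(self):
        # Hand Pearson on (0.4,0.3,0.2,0.1) vs (0.1,0.2,0.3,0.4) is exactly -1.
        taxa = ["Wa x", "Xb y", "Yc z", "Zd w"]
        m = _table(dict(zip(taxa, [40, 30, 20, 10])), db=SourceDB.REFSEQ_ORG)
        r = _table(dict(zip(taxa, [10, 20, 30, 40])))
        assert rank_correlation(m, r, None, "genus") == pytest.approx(-1.0)

    def test_too_few_taxa_rejected(self):
        m = _table({"Aa x": 1, "Bb y": 2}, db=SourceDB.REFSEQ_ORG)
        r = _table({"Aa x": 2, "Bb y": 1})
        with pytest.raises(ValueError, match="unstable"):
            rank_correlation(m, r, None, "genus")

    def test_symmetric_and_scale_invariant(self, community):
        tax = self._tax(community)
        rng = np.random.default_rng(3)
        m = _table({t: float(c) for t, c in zip(community.taxa, rng.integers(1, 500, 30))},
                   db=SourceDB.REFSEQ_ORG)
        r = _table({t: float(c) for t, c in zip(community.taxa, rng.integers(1, 500, 30))})
        ab = rank_correlation(m, r, tax, "family")
        ba = rank_correlation(r, m, tax, "family")
        assert ab == pytest.approx(ba)
        m9 = _table({k: 9 * v for k, v in m.counts.items()}, db=SourceDB.REFSEQ_ORG)
        assert rank_correlation(m9, r, tax, "family") == pytest.approx(ab)

    def test_bacteria_only_drops_archaea(self, community):
        tax = self._tax(community)
        archaea = [t for t in community.taxa if not community.lineages[t].is_bacterial]
        bacteria = [t for t in community.taxa if community.lineages[t].is_bacterial]
        counts = {t: float(10 * (i + 1)) for i, t in enumerate(bacteria)}
        m = _table({**counts, archaea[0]: 5000.0}, db=SourceDB.REFSEQ_ORG)
        r = _table({**counts, archaea[0]: 1.0})
        with_arch = rank_correlation(m, r, tax, "genus", bacteria_only=False)
        without = rank_correlation(m, r, tax, "genus", bacteria_only=True)
        assert with_arch < 0.99
        assert without == pytest.approx(1.0)


class TestComparePeSr:
    def test_identical_tables(self):
        t = _table({"A": 10, "B": 5, "C": 1}, db=SourceDB.REFSEQ_FUNC)
        cmp = compare_pe_sr(t, t)
        assert cmp.total_annotations_pe == cmp.total_annotations_sr
        assert cmp.unique_annotations_pe == cmp.unique_annotations_sr == 3
        assert cmp.shared_feature_count == 3
        assert cmp.pearson_r_log == pytest.approx(1.0)

    def test_disjoint_features_share_nothing(self):
        a = _table({"A": 5, "B": 2}, db=SourceDB.REFSEQ_FUNC)
        b = _table({"C": 5, "D": 2}, db=SourceDB.REFSEQ_FUNC)
        assert compare_pe_sr(a, b).shared_feature_count == 0

    def test_source_db_mismatch_rejected(self):
        a = _table({"A": 5}, db=SourceDB.REFSEQ_FUNC)
        b = _table({"A": 5}, db=SourceDB.REFSEQ_ORG)
        with pytest.raises(ValueError):
            compare_pe_sr(a, b)

    def test_dropout_pair_matches_hand_rolled_correlation(self):
        """r on log10(count+1) equals the closed-form Pearson computation."""
        rng = np.random.default_rng(8)
        features = [f"f{i:03d}" for i in range(100)]
        pe_counts = {f: float(c) for f, c in zip(features, rng.integers(1, 2000, 100))}
        sr_counts = {}
        for f, c in pe_counts.items():
            if rng.random() < 0.2:
                continue  # dropout in the single-end processing
            sr_counts[f] = max(1.0, round(c * rng.lognormal(0, 0.3)))
        pe = _table(pe_counts, db=SourceDB.REFSEQ_FUNC)
        sr = _table(sr_counts, db=SourceDB.REFSEQ_FUNC)
        cmp = compare_pe_sr(pe, sr)
        union = sorted(set(pe_counts) | set(sr_counts))
        x = np.log10(np.array([pe_counts.get(f, 0.0) for f in union]) + 1)
        y = np.log10(np.array([sr_counts.get(f, 0.0) for f in union]) + 1)
        xc, yc = x - x.mean(), y - y.mean()
        hand_r = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert cmp.pearson_r_log == pytest.approx(float(hand_r), abs=1e-12)
        assert cmp.shared_feature_count == len(sr_counts)

    def test_intersection_mode(self):
        # counts chosen so log10(count+1) is exactly linear across tables
        a = _table({"A": 9, "B": 99, "C": 999, "D": 1}, db=SourceDB.REFSEQ_FUNC)
        b = _table({"A": 99, "B": 9999, "C": 999999}, db=SourceDB.REFSEQ_FUNC)
        cmp = compare_pe_sr(a, b, feature_mode="intersection")
        assert cmp.pearson_r_log == pytest.approx(1.0, abs=1e-12)


class TestSingleEndSimulation:
    @pytest.fixture()
    def fastq_pair(self, tmp_path):
        from Bio import SeqIO

        r1, r2 = sim_fastq(25, read_length=150, seed=4)
        p1, p2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
        SeqIO.write(r1, p1, "fastq")
        SeqIO.write(r2, p2, "fastq")
        return p1, p2

    def test_truncates_to_keep_length(self, tmp_path, fastq_pair):
        from Bio import SeqIO

        p1, p2 = fastq_pair
        out = tmp_path / "sr.fastq"
        n = simulate_single_end(p1, p2, out, keep_length=100)
        recs = list(SeqIO.parse(out, "fastq"))
        assert n == len(recs) == 25
        assert all(len(r.seq) == 100 for r in recs)
        assert all(len(r.letter_annotations["phred_quality"]) == 100 for r in recs)

    def test_truncation_prefix_preserved(self, tmp_path, fastq_pair):
        from Bio import SeqIO

        p1, _ = fastq_pair
        out = tmp_path / "sr.fastq"
        simulate_single_end(p1, None, out, keep_length=60)
        originals = {r.id: str(r.seq) for r in SeqIO.parse(p1, "fastq")}
        for rec in SeqIO.parse(out, "fastq"):
            assert originals[rec.id].startswith(str(rec.seq))

    def test_short_reads_pass_unchanged_and_idempotent(self):
        r1, _ = sim_fastq(5, read_length=80, seed=6)
        once = list(truncate_reads(r1, 100))
        assert [str(r.seq) for r in once] == [str(r.seq) for r in r1]
        r150, _ = sim_fastq(5, read_length=150, seed=7)
        once = list(truncate_reads(r150, 100))
        twice = list(truncate_reads(once, 100))
        assert [str(r.seq) for r in once] == [str(r.seq) for r in twice]

    def test_invalid_keep_length(self):
        with pytest.raises(ValueError):
            list(truncate_reads([], 0))
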