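"""Synthetic annotation data with known ground truth.

Every analysis stage in this package consumes annotation exports or tables
derived from them; these generators produce the same structures from a known
community, so recovery can be asserted without any download:

* a community profile (taxon proportions from a lognormal or power law,
  lineages from a small built-in mock taxonomy, per-taxon function
  catalogs, an rRNA fraction, per-phylum rRNA retention factors),
* per-read annotation records (multinomial reads, optional tied best hits,
  rRNA records routed to the SILVA SSU source),
* control/ribodepleted sample pairs with planted per-phylum retention,
* NB count matrices with planted log2 fold changes,
* random paired FASTQ reads for the single-end simulation utility.

All generators are pure functions of their seed.  Truths (planted
proportions, retention factors, expected depletion percentages, planted
effects) are returned alongside the data so recovery tests never re-derive
them.  No sequence-level realism is attempted: reads are random bases, and
annotation error is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .aggregation import AbundanceTable, Lineage, TaxonomyMap
from .annotation_io import AnnotationRecord, SourceDB

__all__ = [
    "CommunityProfile",
    "DepletedPair",
    "MOCK_TAXONOMY",
    "mock_taxonomy_map",
    "sim_community",
    "sim_annotations",
    "sim_abundance_table",
    "sim_depleted_pair",
    "sim_count_matrix",
    "sim_fastq",
]

# ---------------------------------------------------------------------------
# Mock taxonomy: 6 phyla, 30 genera.  Real lineages are unnecessary for
# correctness tests; the archaeal phylum exercises bacteria-only filtering.
# (phylum, class, order, family, genus, is_bacterial)
# ---------------------------------------------------------------------------
MOCK_TAXONOMY: tuple[tuple[str, str, str, str, str, bool], ...] = (
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Blautia", True),
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia", True),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium", True),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus", True),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", True),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", True),
    ("Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus", True),
    ("Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella", True),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", True),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", True),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Rikenellaceae", "Alistipes", True),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Parabacteroides", True),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Tannerellaceae", "Tannerella", True),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Flavobacterium", True),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", True),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella", True),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Shigella", True),
    ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", True),
    ("Proteobacteria", "Epsilonproteobacteria", "Campylobacterales", "Helicobacteraceae", "Helicobacter", True),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfovibrionales", "Desulfovibrionaceae", "Desulfovibrio", True),
    ("Actinobacteria", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", True),
    ("Actinobacteria", "Actinomycetia", "Micrococcales", "Micrococcaceae", "Micrococcus", True),
    ("Actinobacteria", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium", True),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella", True),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Akkermansiaceae", "Akkermansia", True),
    ("Verrucomicrobia", "Verrucomicrobiae", "Verrucomicrobiales", "Verrucomicrobiaceae", "Verrucomicrobium", True),
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter", False),
    ("Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanosphaera", False),
    ("Euryarchaeota", "Halobacteria", "Halobacteriales", "Halobacteriaceae", "Halobacterium", False),
    ("Euryarchaeota", "Thermococci", "Thermococcales", "Thermococcaceae", "Thermococcus", False),
)


@dataclass
class CommunityProfile:
    """A synthetic community: who is there, at what abundance, doing what.

    ``function_catalog`` maps each taxon to (function names, within-taxon
    proportions).  ``rrna_fraction`` is the probability a read is ribosomal;
    ``retention`` gives each phylum's rRNA survival probability under
    ribodepletion (1.0 = not depleted at all).
    """

    taxa: list[str]
    true_proportions: np.ndarray
    lineages: dict[str, Lineage]
    function_catalog: dict[str, tuple[list[str], np.ndarray]]
    rrna_fraction: float = 0.0
    retention: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isclose(self.true_proportions.sum(), 1.0):
            raise ValueError("true_proportions must sum to 1")
        if not (0.0 <= self.rrna_fraction < 1.0):
            raise ValueError("rrna_fraction must lie in [0, 1)")
        for phylum, r in self.retention.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"retention for {phylum} out of [0,1]: {r}")

    def taxonomy_map(self) -> TaxonomyMap:
        return TaxonomyMap(self.lineages)

    def phylum_of(self, taxon: str) -> str:
        return self.lineages[taxon].phylum

    def phylum_proportions(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for taxon, p in zip(self.taxa, self.true_proportions):
            out[self.phylum_of(taxon)] = out.get(self.phylum_of(taxon), 0.0) + float(p)
        return out

    def expected_depletion_percent(self) -> dict[str, float]:
        """Expected per-phylum depletion under the relative-abundance metric.

        After per-library renormalization the expected depletion of phylum p
        is 100 * (1 - r_p / rbar) with rbar the abundance-weighted mean
        retention over the community's rRNA — not simply 100 * (1 - r_p).
        """
        w = self.phylum_proportions()
        rbar = sum(w[p] * self.retention.get(p, 1.0) for p in w)
        return {
            p: 100.0 * (1.0 - self.retention.get(p, 1.0) / rbar) for p in w
        }


def sim_community(
    n_taxa: int,
    abundance_law: str = "lognormal",
    params: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    rrna_fraction: float = 0.0,
    retention: Mapping[str, float] | None = None,
    n_functions_per_taxon: int = 8,
) -> CommunityProfile:
    """Draw a community profile with proportions from the stated abundance law.

    ``lognormal`` (param ``sigma``, default 1.5) gives the long-tailed rank
    abundance typical of gut communities; ``power`` (param ``exponent``,
    default 1.0) gives a Zipf-like profile.  Taxa cycle through the built-in
    mock taxonomy, acquiring unique species epithets; each taxon also gets a
    catalog of functions with Dirichlet within-taxon proportions.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if abundance_law == "lognormal":
        sigma = float(params.get("sigma", 1.5))
        if sigma <= 0:
            raise ValueError(f"sigma must be positive, got {sigma}")
        weights = rng.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
    elif abundance_law == "power":
        exponent = float(params.get("exponent", 1.0))
        if exponent <= 0:
            raise ValueError(f"exponent must be positive, got {exponent}")
        weights = 1.0 / np.arange(1, n_taxa + 1, dtype=float) ** exponent
        rng.shuffle(weights)
    else:
        raise ValueError(f"unknown abundance_law {abundance_law!r}")
    proportions = weights / weights.sum()

    taxa: list[str] = []
    lineages: dict[str, Lineage] = {}
    for i in range(n_taxa):
        phylum, class_, order, family, genus, is_bact = MOCK_TAXONOMY[
            i % len(MOCK_TAXONOMY)
        ]
        species = f"{genus} sp{i // len(MOCK_TAXONOMY) + 1:03d}"
        taxa.append(species)
        lineages[species] = Lineage(phylum, class_, order, family, genus, is_bact)

    catalog: dict[str, tuple[list[str], np.ndarray]] = {}
    for i, taxon in enumerate(taxa):
        fns = [f"F{(i * 3 + j) % (n_taxa * 2) + 1:04d} hypothetical enzyme" for j in range(n_functions_per_taxon)]
        props = rng.dirichlet(np.ones(n_functions_per_taxon))
        catalog[taxon] = (fns, props)

    return CommunityProfile(
        taxa=taxa,
        true_proportions=proportions,
        lineages=lineages,
        function_catalog=catalog,
        rrna_fraction=rrna_fraction,
        retention=dict(retention or {}),
    )


def mock_taxonomy_map() -> TaxonomyMap:
    """TaxonomyMap over the bare mock genera (genus name used as organism)."""
    return TaxonomyMap(
        {
            genus: Lineage(phylum, class_, order, family, genus, is_bact)
            for phylum, class_, order, family, genus, is_bact in MOCK_TAXONOMY
        }
    )


def _records_from_categories(
    taxa_idx: np.ndarray,
    is_rrna: np.ndarray,
    profile: CommunityProfile,
    source_db: SourceDB,
    tie_rate: float,
    rng: np.random.Generator,
    read_prefix: str = "read",
) -> list[AnnotationRecord]:
    """Emit annotation records for pre-drawn (taxon, rRNA-flag) read categories."""
    n = len(taxa_idx)
    tie_mask = rng.random(n) < tie_rate
    records: list[AnnotationRecord] = []
    n_taxa = len(profile.taxa)
    for i in range(n):
        read_id = f"{read_prefix}{i + 1:08d}"
        taxon = profile.taxa[taxa_idx[i]]
        if is_rrna[i]:
            texts = [taxon]
            db = SourceDB.SILVA_SSU
        elif source_db in (SourceDB.REFSEQ_FUNC, SourceDB.SUBSYSTEMS):
            fns, props = profile.function_catalog[taxon]
            texts = [fns[rng.choice(len(fns), p=props)]]
            db = source_db
        else:
            texts = [taxon]
            db = source_db
        if tie_mask[i]:
            if db is SourceDB.SILVA_SSU or source_db is SourceDB.REFSEQ_ORG:
                other = profile.taxa[(taxa_idx[i] + 1 + rng.integers(n_taxa - 1)) % n_taxa]
                texts.append(other)
            else:
                fns, _ = profile.function_catalog[taxon]
                texts.append(fns[rng.integers(len(fns))])
        for j, text in enumerate(texts):
            records.append(
                AnnotationRecord(
                    read_id=read_id,
                    match_id=f"m5|{i + 1:08d}_{j}",
                    annotation_text=text,
                    source_db=db,
                    percent_identity=float(np.round(80 + 20 * rng.random(), 2)),
                    alignment_length=int(rng.integers(60, 151)),
                    evalue=float(10.0 ** -rng.integers(10, 60)),
                )
            )
    return records


def sim_annotations(
    profile: CommunityProfile,
    n_reads: int,
    source_db: SourceDB = SourceDB.REFSEQ_ORG,
    tie_rate: float = 0.0,
    seed: int = 0,
) -> list[AnnotationRecord]:
    """Per-read annotation records drawn from the community.

    Reads are assigned to taxa multinomially by the true proportions; a
    fraction ``rrna_fraction`` of reads become SILVA-SSU rRNA records
    (annotated with the organism); the rest are annotated with the organism
    (RefSeq-organism source) or a function from the taxon's catalog
    (function/ontology sources).  A ``tie_rate`` fraction of reads emit a
    second, tied record sharing the read id.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    taxa_idx = rng.choice(len(profile.taxa), size=n_reads, p=profile.true_proportions)
    is_rrna = rng.random(n_reads) < profile.rrna_fraction
    return _records_from_categories(
        taxa_idx, is_rrna, profile, source_db, tie_rate, rng
    )


def sim_abundance_table(
    profile: CommunityProfile,
    n_reads: int,
    source_db: SourceDB = SourceDB.REFSEQ_ORG,
    seed: int = 0,
    sample_id: str = "sim",
) -> AbundanceTable:
    """Multinomial organism abundance table drawn directly from the profile.

    Equivalent in distribution to aggregating ``sim_annotations`` output
    with no ties and no rRNA, but O(n_taxa) instead of O(n_reads) — the
    right tool for deep parents in the depth analysis.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    draw = rng.multinomial(n_reads, profile.true_proportions)
    counts = {t: float(c) for t, c in zip(profile.taxa, draw) if c > 0}
    return AbundanceTable(sample_id=sample_id, source_db=source_db, counts=counts)


@dataclass
class DepletedPair:
    """A control/ribodepleted record pair plus the planted truth."""

    control: list[AnnotationRecord]
    depleted: list[AnnotationRecord]
    truth: dict


def sim_depleted_pair(
    profile: CommunityProfile,
    n_reads: int,
    seed: int = 0,
) -> DepletedPair:
    """Simulate a control library and its ribodepleted counterpart.

    The control is an ordinary draw.  For the depleted library, reads are
    drawn the same way, each rRNA read of phylum p then survives with
    probability retention(p), and the surviving pool is resampled with
    replacement back to ``n_reads`` — mimicking fixed sequencing throughput,
    which (realistically) inflates non-depleted taxa.  The truth records the
    planted retentions and the expected per-phylum depletion percentages
    under the relative-abundance depletion metric.
    """
    if not profile.retention:
        raise ValueError("profile.retention must be set to simulate depletion")
    if profile.rrna_fraction <= 0:
        raise ValueError("profile.rrna_fraction must be positive for a depletion pair")
    rng = np.random.default_rng(seed)
    control = sim_annotations(
        profile, n_reads, SourceDB.REFSEQ_ORG, tie_rate=0.0,
        seed=int(rng.integers(2**31)),
    )

    sub = np.random.default_rng(int(rng.integers(2**31)))
    taxa_idx = sub.choice(len(profile.taxa), size=n_reads, p=profile.true_proportions)
    is_rrna = sub.random(n_reads) < profile.rrna_fraction
    ret = np.array(
        [profile.retention.get(profile.phylum_of(t), 1.0) for t in profile.taxa]
    )
    survive = ~is_rrna | (sub.random(n_reads) < ret[taxa_idx])
    survivors = np.flatnonzero(survive)
    if len(survivors) == 0:
        raise ValueError("depletion removed every read; lower rrna_fraction")
    resampled = survivors[sub.integers(len(survivors), size=n_reads)]
    depleted = _records_from_categories(
        taxa_idx[resampled],
        is_rrna[resampled],
        profile,
        SourceDB.REFSEQ_ORG,
        tie_rate=0.0,
        rng=sub,
        read_prefix="dread",
    )
    return DepletedPair(
        control=control,
        depleted=depleted,
        truth={
            "retention": dict(profile.retention),
            "rrna_fraction": profile.rrna_fraction,
            "expected_depletion_percent": profile.expected_depletion_percent(),
        },
    )


def sim_count_matrix(
    n_features: int,
    n_per_group: int,
    planted_log2fc: Mapping[int, float] | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    *,
    base_mean_median: float = 50.0,
    base_mean_sigma: float = 1.0,
    size_factor_sigma: float = 0.15,
):
    """NB count matrix with planted group effects, plus the truth table.

    Feature base means are lognormal (median ``base_mean_median``, log-SD
    ``base_mean_sigma``); sample depths vary by lognormal size factors
    (log-SD ``size_factor_sigma``).  Group B means are the base means times
    2**planted_log2fc for planted features.  Counts are NB with the given
    dispersion alpha (Var = mu + alpha mu^2; alpha = 0 means Poisson).

    Returns ``(CountMatrix, truth)`` with truth a DataFrame of feature,
    base_mean, true_log2fc.
    """
    import pandas as pd

    from .aggregation import CountMatrix

    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    planted = dict(planted_log2fc or {})
    features = [f"feat{i + 1:05d}" for i in range(n_features)]
    base = rng.lognormal(np.log(base_mean_median), base_mean_sigma, size=n_features)
    lfc = np.zeros(n_features)
    for idx, val in planted.items():
        lfc[idx] = val
    n_samples = 2 * n_per_group
    sf = rng.lognormal(0.0, size_factor_sigma, size=n_samples)
    mean_a = base[:, None] * sf[None, :n_per_group]
    mean_b = (base * 2.0**lfc)[:, None] * sf[None, n_per_group:]
    mu = np.concatenate([mean_a, mean_b], axis=1)
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"A{i + 1}" for i in range(n_per_group)] + [
        f"B{i + 1}" for i in range(n_per_group)
    ]
    df = pd.DataFrame(counts, index=pd.Index(features, name="feature"), columns=samples)
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    truth = pd.DataFrame(
        {"feature": features, "base_mean": base, "true_log2fc": lfc}
    )
    return CountMatrix(values=df, groups=groups), truth


def sim_fastq(
    n_reads: int,
    read_length: int = 150,
    seed: int = 0,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Random-base paired reads (R1, R2) with constant quality 40."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    out: tuple[list[SeqRecord], list[SeqRecord]] = ([], [])
    for mate, reads in enumerate(out, start=1):
        for i in range(n_reads):
            seq = "".join(rng.choice(bases, size=read_length))
            rec = SeqRecord(
                Seq(seq),
                id=f"read{i + 1:06d}/{mate}",
                description="",
            )
            rec.letter_annotations["phred_quality"] = [40] * read_length
            reads.append(rec)
    return out
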