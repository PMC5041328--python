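"""Protocol comparisons: ribodepletion bias, mRNA/rRNA concordance, PE vs SR.

Three evaluations of sequencing/library-preparation choices, each operating
on abundance tables produced by the aggregation stage:

* **Ribodepletion bias** — rRNA depletion kits do not remove ribosomes from
  every phylum equally.  Comparing control (non-depleted) against depleted
  libraries at a chosen rank, the per-taxon depletion percentage is

      d_i(t) = 100 * (1 - rel_depleted_i(t) / rel_control_i(t))

  per sample pair i, averaged over pairs.  Relative abundances normalize
  each library, so the metric is invariant to library size; note that this
  renormalization means a uniformly-depleted community shows 0% everywhere
  and taxa depleted less than average can show negative values (apparent
  enrichment).

* **mRNA vs rRNA concordance** — do organism abundances estimated from mRNA
  (RefSeq) agree with those from rRNA (SILVA SSU)?  Pearson correlation of
  relative abundances after rollup to a rank, over the union of taxa
  (absent = 0), optionally restricted to bacteria.

* **Paired-end vs single-read** — totals, unique annotation counts, shared
  features, and Pearson correlation of log10(count+1) between the two
  processings of the same library; plus the digital single-end simulation
  that discards reverse reads and truncates forward reads to a fixed length.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .aggregation import AbundanceTable, TaxonomyMap, relative_abundance, rollup_rank

__all__ = [
    "DepletionRow",
    "DepletionReport",
    "PeSrComparison",
    "depletion_percent",
    "rank_correlation",
    "compare_pe_sr",
    "simulate_single_end",
    "truncate_reads",
]


@dataclass
class DepletionRow:
    """Per-taxon depletion summary across sample pairs.

    ``depletion_percent`` may be negative (relative enrichment after the
    per-library renormalization).
    """

    taxon: str
    control_counts: list[float]
    depleted_counts: list[float]
    depletion_percent: float


@dataclass
class DepletionReport:
    """Depletion rows plus taxa that had to be excluded (absent from control)."""

    rows: list[DepletionRow]
    excluded_taxa: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[DepletionRow]:
        return iter(self.rows)

    def as_dict(self) -> dict[str, float]:
        return {r.taxon: r.depletion_percent for r in self.rows}


def _as_table_list(x) -> list[AbundanceTable]:
    if isinstance(x, AbundanceTable):
        return [x]
    return list(x)


def depletion_percent(
    control: AbundanceTable | Sequence[AbundanceTable],
    depleted: AbundanceTable | Sequence[AbundanceTable],
    paired_samples: Sequence[tuple[int, int]] | None = None,
) -> DepletionReport:
    """Per-taxon depletion percentage, averaged over control/depleted pairs.

    Tables must already be at the rank of interest (roll up first; phylum is
    the conventional choice).  ``paired_samples`` gives (control index,
    depleted index) pairs; by default tables are paired positionally.  Taxa
    absent from every control library cannot be scored and are reported as
    excluded; a taxon present in control but absent from a depleted library
    scores 100% for that pair.
    """
    controls = _as_table_list(control)
    depleteds = _as_table_list(depleted)
    if not controls or all(t.total == 0 for t in controls):
        raise ValueError("control table(s) empty")
    if paired_samples is None:
        if len(controls) != len(depleteds):
            raise ValueError(
                f"{len(controls)} control vs {len(depleteds)} depleted tables; "
                "supply paired_samples to pair them explicitly"
            )
        paired_samples = [(i, i) for i in range(len(controls))]

    taxa = sorted(
        set().union(*(t.counts.keys() for t in controls + depleteds))
    )
    rel_c = [relative_abundance(t) for t in controls]
    rel_d = [relative_abundance(t) for t in depleteds]

    rows: list[DepletionRow] = []
    excluded: list[str] = []
    for taxon in taxa:
        per_pair: list[float] = []
        for ci, di in paired_samples:
            pc = rel_c[ci].get(taxon, 0.0)
            pd_ = rel_d[di].get(taxon, 0.0)
            if pc == 0.0:
                continue  # not measurable in this pair
            per_pair.append(100.0 * (1.0 - pd_ / pc))
        if not per_pair:
            excluded.append(taxon)
            continue
        rows.append(
            DepletionRow(
                taxon=taxon,
                control_counts=[t.counts.get(taxon, 0.0) for t in controls],
                depleted_counts=[t.counts.get(taxon, 0.0) for t in depleteds],
                depletion_percent=float(np.mean(per_pair)),
            )
        )
    return DepletionReport(rows=rows, excluded_taxa=excluded)


def rank_correlation(
    mrna: AbundanceTable,
    rrna: AbundanceTable,
    tax: TaxonomyMap | None,
    rank: str = "genus",
    bacteria_only: bool = False,
) -> float:
    """Pearson r between mRNA- and rRNA-based organism abundances at a rank.

    Both tables are rolled up to the rank, optionally filtered to bacterial
    lineages, renormalized, and correlated over the union of taxa (a taxon
    absent from one table contributes 0 there).  Symmetric in its two
    tables and invariant to proportional rescaling of either.
    """
    rolled_m = rollup_rank(mrna, tax, rank)
    rolled_r = rollup_rank(rrna, tax, rank)
    if bacteria_only:
        if tax is None:
            raise ValueError("bacteria_only filtering requires a TaxonomyMap")
        bacterial = {
            lin.rank(rank) for _, lin in tax.items() if lin.is_bacterial
        }
        rolled_m.counts = {k: v for k, v in rolled_m.counts.items() if k in bacterial}
        rolled_r.counts = {k: v for k, v in rolled_r.counts.items() if k in bacterial}
    if rolled_m.total == 0 or rolled_r.total == 0:
        raise ValueError("a table is empty after rollup/filtering")
    taxa = sorted(set(rolled_m.counts) | set(rolled_r.counts))
    if len(taxa) < 3:
        raise ValueError(
            f"only {len(taxa)} taxa at rank {rank!r}; correlation unstable below 3"
        )
    rel_m = relative_abundance(rolled_m)
    rel_r = relative_abundance(rolled_r)
    x = np.array([rel_m.get(t, 0.0) for t in taxa])
    y = np.array([rel_r.get(t, 0.0) for t in taxa])
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class PeSrComparison:
    """Summary of paired-end vs simulated single-read processings of one library."""

    total_annotations_pe: float
    total_annotations_sr: float
    unique_annotations_pe: int
    unique_annotations_sr: int
    shared_feature_count: int
    pearson_r_log: float


def compare_pe_sr(
    pe: AbundanceTable,
    sr: AbundanceTable,
    feature_mode: str = "union",
) -> PeSrComparison:
    """Compare abundance tables from paired-end and single-read processing.

    The correlation is Pearson on log10(count + 1); ``union`` mode (default)
    scores absent features as 0, penalizing annotation dropout, while
    ``intersection`` restricts to shared features.
    """
    if pe.source_db != sr.source_db:
        raise ValueError("tables must share a source database")
    if pe.total == 0 and sr.total == 0:
        raise ValueError("both tables are empty")
    if feature_mode == "union":
        features = sorted(set(pe.counts) | set(sr.counts))
    elif feature_mode == "intersection":
        features = sorted(set(pe.counts) & set(sr.counts))
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    x = np.log10(np.array([pe.counts.get(f, 0.0) for f in features]) + 1.0)
    y = np.log10(np.array([sr.counts.get(f, 0.0) for f in features]) + 1.0)
    if len(features) >= 2 and x.std() > 0 and y.std() > 0:
        r = float(stats.pearsonr(x, y).statistic)
    else:
        r = math.nan
    return PeSrComparison(
        total_annotations_pe=pe.total,
        total_annotations_sr=sr.total,
        unique_annotations_pe=len(pe.counts),
        unique_annotations_sr=len(sr.counts),
        shared_feature_count=len(set(pe.counts) & set(sr.counts)),
        pearson_r_log=r,
    )


def truncate_reads(
    reads: Iterable[SeqRecord],
    keep_length: int,
) -> Iterator[SeqRecord]:
    """Truncate reads to their first ``keep_length`` bases.

    Sequence and per-base qualities are sliced in lockstep; reads already at
    or below the target length pass through unchanged, so the operation is
    idempotent.
    """
    if keep_length < 1:
        raise ValueError(f"keep_length must be >= 1, got {keep_length}")
    for rec in reads:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is not None and len(quals) != len(rec.seq):
            raise ValueError(
                f"read {rec.id}: quality length {len(quals)} != "
                f"sequence length {len(rec.seq)}"
            )
        yield rec[:keep_length] if len(rec.seq) > keep_length else rec


def _open_fastq(path: str | Path, mode: str):
    path = Path(path)
    return gzip.open(path, mode + "t") if path.suffix == ".gz" else open(path, mode)


def simulate_single_end(
    fastq_r1: str | Path,
    fastq_r2: str | Path | None,
    out_path: str | Path,
    keep_length: int = 100,
) -> int:
    """Digitally convert a paired-end library to a single-end one.

    The reverse-read file is discarded entirely; every forward read is
    truncated to its first ``keep_length`` bases (default 100 bp, the
    conventional short-read length), qualities in lockstep.  The read count
    of the forward file is preserved.  Returns the number of reads written.
    """
    n = 0
    with _open_fastq(fastq_r1, "r") as fin, _open_fastq(out_path, "w") as fout:
        for rec in truncate_reads(SeqIO.parse(fin, "fastq"), keep_length):
            SeqIO.write(rec, fout, "fastq")
            n += 1
    return n


def write_depletion_tsv(
    report: DepletionReport,
    path: str | Path,
    control_ids: Sequence[str] = (),
    depleted_ids: Sequence[str] = (),
) -> None:
    """Depletion report TSV: taxon, per-sample counts, depletion_percent."""
    with open(path, "w") as fh:
        if report.excluded_taxa:
            fh.write(f"# excluded_taxa={','.join(report.excluded_taxa)}\n")
        n_c = len(report.rows[0].control_counts) if report.rows else 0
        n_d = len(report.rows[0].depleted_counts) if report.rows else 0
        c_ids = list(control_ids) or [f"control_{i+1}" for i in range(n_c)]
        d_ids = list(depleted_ids) or [f"depleted_{i+1}" for i in range(n_d)]
        fh.write("taxon\t" + "\t".join(c_ids + d_ids) + "\tdepletion_percent\n")
        for row in sorted(report.rows, key=lambda r: r.taxon):
            cells = [f"{c:.6g}" for c in row.control_counts + row.depleted_counts]
            fh.write(f"{row.taxon}\t" + "\t".join(cells) + f"\t{row.depletion_percent:.2f}\n")


__all__ += ["write_depletion_tsv"]
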