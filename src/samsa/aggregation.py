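"""Collapsing per-read annotations into sorted abundance tables and matrices.

The aggregation stage counts occurrences of each unique annotation in a
sample, optionally rolls organism counts up the taxonomy (phylum through
genus), summarizes the long tail as a top-N + "Other" display table, and
merges per-sample tables into a features x samples count matrix ready for
differential testing.

Tied best hits inflate read counts: a read matched to k references
contributes k records.  The ``count_all`` policy keeps that inflation
(mirroring the annotation service's own convention); ``fractional`` divides
each read's unit weight over its tied hits so totals equal read counts.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import AnnotationRecord, SourceDB

__all__ = [
    "AbundanceTable",
    "Lineage",
    "TaxonomyMap",
    "CountMatrix",
    "RANKS",
    "OTHER_LABEL",
    "aggregate_counts",
    "sort_abundance",
    "rollup_rank",
    "top_n_other",
    "relative_abundance",
    "merge_to_matrix",
    "read_abundance_tsv",
    "write_abundance_tsv",
    "read_taxonomy_tsv",
]

#: Taxonomic ranks handled by the rollup, ordered coarse to fine.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Reserved catch-all label for the long tail; input keys that collide are escaped.
OTHER_LABEL = "Other"

UNCLASSIFIED_LABEL = "unclassified"


@dataclass
class AbundanceTable:
    """Per-sample counts of unique annotations.

    Counts are integers under the ``count_all`` tie policy and may be
    fractional under the ``fractional`` policy; they are never negative.
    """

    sample_id: str
    source_db: SourceDB
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.counts.items():
            if val < 0:
                raise ValueError(f"negative count for {key!r}: {val}")

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class Lineage:
    """Ordered lineage of one organism, coarse to fine; bacterial unless flagged."""

    phylum: str
    class_: str
    order: str
    family: str
    genus: str
    is_bacterial: bool = True

    def rank(self, rank: str) -> str:
        if rank == "class":
            return self.class_
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return getattr(self, rank)


class TaxonomyMap:
    """Exact, case-sensitive mapping from organism name to lineage.

    Lookup of an unmapped organism returns ``None``; callers pool such
    organisms into the ``unclassified`` bucket (the documented fallback).
    """

    def __init__(self, lineages: Mapping[str, Lineage]):
        self._map = dict(lineages)

    def get(self, organism: str) -> Lineage | None:
        return self._map.get(organism)

    def __contains__(self, organism: str) -> bool:
        return organism in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()


@dataclass
class CountMatrix:
    """Features x samples non-negative counts with per-sample group labels.

    ``values`` is a pandas DataFrame indexed by feature with one column per
    sample.  Every sample must carry a group label before differential
    testing; labels may be absent for purely descriptive use.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    source_db: SourceDB | None = None

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def aggregate_counts(
    records: Iterable[AnnotationRecord],
    tie_policy: str = "count_all",
    sample_id: str = "sample",
) -> AbundanceTable:
    """Count occurrences of each unique annotation.

    ``count_all``: every record contributes 1 (a read with k tied hits adds
    k to the total).  ``fractional``: each record of a read with k records
    contributes 1/k, so the total equals the number of distinct reads.
    All records must share a database of origin.
    """
    if tie_policy not in ("count_all", "fractional"):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    records = list(records)
    if not records:
        raise ValueError("cannot aggregate an empty record collection")
    dbs = {rec.source_db for rec in records}
    if len(dbs) > 1:
        raise ValueError(f"records mix source databases: {sorted(d.value for d in dbs)}")
    counts: dict[str, float] = defaultdict(float)
    if tie_policy == "count_all":
        for rec in records:
            counts[rec.annotation_text] += 1
    else:
        per_read = Counter(rec.read_id for rec in records)
        for rec in records:
            counts[rec.annotation_text] += 1.0 / per_read[rec.read_id]
    return AbundanceTable(
        sample_id=sample_id, source_db=dbs.pop(), counts=dict(counts)
    )


def sort_abundance(table: AbundanceTable) -> list[tuple[str, float]]:
    """Sorted (annotation, count) pairs: descending count, ties lexicographic."""
    return sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def rollup_rank(
    table: AbundanceTable,
    tax: TaxonomyMap | None,
    rank: str,
) -> AbundanceTable:
    """Sum organism counts per taxon name at the requested rank.

    Organisms absent from the taxonomy map are pooled into ``unclassified``.
    Without a map only ``genus`` is available, via the fallback of taking
    the first whitespace-delimited token of the organism string (binomial
    names start with the genus); coarser ranks require lineage data the
    annotation text does not carry.  Total counts are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    rolled: dict[str, float] = defaultdict(float)
    for organism, count in table.counts.items():
        if tax is not None:
            lineage = tax.get(organism)
            name = lineage.rank(rank) if lineage is not None else UNCLASSIFIED_LABEL
        elif rank == "genus":
            name = organism.split()[0] if organism.split() else UNCLASSIFIED_LABEL
        else:
            raise ValueError(
                f"rollup to {rank!r} requires a TaxonomyMap; only the genus "
                "fallback works without one"
            )
        rolled[name or UNCLASSIFIED_LABEL] += count
    return AbundanceTable(
        sample_id=table.sample_id, source_db=table.source_db, counts=dict(rolled)
    )


def top_n_other(
    table: AbundanceTable,
    n: int = 30,
    mode: str = "other_bucket",
) -> AbundanceTable:
    """Keep the n most abundant categories; pool or drop the remainder.

    ``other_bucket`` adds an ``Other`` category holding the summed remainder
    (omitted when empty), conserving the total; ``drop`` discards the
    remainder.  The default n of 30 matches the usual stacked-bar display
    convention for long-tailed community profiles.  An input category
    already named ``Other`` is escaped to ``Other_`` so the catch-all label
    stays unambiguous.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if mode not in ("other_bucket", "drop"):
        raise ValueError(f"unknown mode {mode!r}")
    ordered = sort_abundance(table)
    kept = dict(ordered[:n])
    if OTHER_LABEL in kept:
        kept[OTHER_LABEL + "_"] = kept.pop(OTHER_LABEL)
    if mode == "other_bucket":
        remainder = sum(count for _, count in ordered[n:])
        if len(ordered) > n:
            kept[OTHER_LABEL] = remainder
    return AbundanceTable(
        sample_id=table.sample_id, source_db=table.source_db, counts=kept
    )


def relative_abundance(table: AbundanceTable) -> dict[str, float]:
    """Counts normalized to proportions summing to 1 (total must be positive)."""
    total = table.total
    if total <= 0:
        raise ValueError("relative abundance undefined for a zero-total table")
    return {key: count / total for key, count in table.counts.items()}


def merge_to_matrix(
    tables: Sequence[AbundanceTable],
    groups: Mapping[str, str] | None = None,
) -> CountMatrix:
    """Merge per-sample tables into one count matrix.

    The feature set is the union across samples; entries missing from a
    sample are 0, so every column sum equals that table's total.  Tables
    must share a database of origin and carry unique sample ids.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one table")
    dbs = {t.source_db for t in tables}
    if len(dbs) > 1:
        raise ValueError(f"tables mix source databases: {sorted(d.value for d in dbs)}")
    ids = [t.sample_id for t in tables]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    features = sorted(set().union(*(t.counts.keys() for t in tables)))
    df = pd.DataFrame(
        {t.sample_id: [t.counts.get(f, 0) for f in features] for t in tables},
        index=pd.Index(features, name="feature"),
    )
    return CountMatrix(values=df, groups=dict(groups or {}), source_db=dbs.pop())


# ---------------------------------------------------------------------------
# Plain-text interchange formats
# ---------------------------------------------------------------------------

def write_abundance_tsv(
    table: AbundanceTable,
    stream: str | Path | IO[str],
    header_comments: Sequence[str] = (),
) -> None:
    """Sorted abundance table as TSV: annotation, count, relative_abundance."""
    rel = relative_abundance(table) if table.total > 0 else {}
    lines = [f"# {c}" for c in header_comments]
    lines.append(f"# sample={table.sample_id}\tsource_db={table.source_db.value}")
    lines.append("annotation\tcount\trelative_abundance")
    for key, count in sort_abundance(table):
        count_str = str(int(count)) if float(count).is_integer() else f"{count:.6g}"
        lines.append(f"{key}\t{count_str}\t{rel.get(key, 0.0):.6g}")
    text = "\n".join(lines) + "\n"
    if hasattr(stream, "write"):
        stream.write(text)  # type: ignore[union-attr]
    else:
        Path(stream).write_text(text)


def read_abundance_tsv(
    path: str | Path | IO[str],
    sample_id: str | None = None,
    source_db: SourceDB | None = None,
) -> AbundanceTable:
    """Read an abundance TSV written by :func:`write_abundance_tsv`."""
    if hasattr(path, "read"):
        lines = path.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(path).read_text().splitlines()
    counts: dict[str, float] = {}
    for line in lines:
        if not line or line.startswith("#"):
            if line.startswith("# sample="):
                meta = dict(p.split("=", 1) for p in line[2:].split("\t"))
                sample_id = sample_id or meta.get("sample")
                if source_db is None and "source_db" in meta:
                    source_db = SourceDB(meta["source_db"])
            continue
        if line.startswith("annotation\t"):
            continue
        key, count, *_ = line.split("\t")
        counts[key] = float(count)
    return AbundanceTable(
        sample_id=sample_id or "sample",
        source_db=source_db or SourceDB.REFSEQ_ORG,
        counts=counts,
    )


def read_taxonomy_tsv(path: str | Path) -> TaxonomyMap:
    """Read a taxonomy map TSV: organism, phylum, class, order, family, genus.

    An optional seventh column ``is_bacterial`` (true/false) flags
    non-bacterial lineages for concordance filtering; absent means bacterial.
    """
    lineages: dict[str, Lineage] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#") or line.startswith("organism\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"taxonomy line has {len(parts)} columns, need >= 6: {line!r}")
        organism, phylum, class_, order, family, genus = parts[:6]
        is_bact = True
        if len(parts) >= 7:
            is_bact = parts[6].strip().lower() in ("true", "1", "yes")
        lineages[organism] = Lineage(phylum, class_, order, family, genus, is_bact)
    return TaxonomyMap(lineages)


def write_matrix_tsv(
    matrix: CountMatrix,
    path: str | Path,
    groups_path: str | Path | None = None,
    header_comments: Sequence[str] = (),
) -> None:
    """Count matrix as TSV (features x samples) with a sidecar group-label TSV."""
    with open(path, "w") as fh:
        for c in header_comments:
            fh.write(f"# {c}\n")
        matrix.values.to_csv(fh, sep="\t")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            fh.write("sample\tgroup\n")
            for sample in matrix.samples:
                fh.write(f"{sample}\t{matrix.groups.get(sample, '')}\n")


def read_matrix_tsv(
    path: str | Path,
    groups_path: str | Path | None = None,
    source_db: SourceDB | None = None,
) -> CountMatrix:
    """Read a count matrix TSV (and optional sidecar group labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index.name = "feature"
    groups: dict[str, str] = {}
    if groups_path is not None:
        gdf = pd.read_csv(groups_path, sep="\t", comment="#")
        groups = {
            str(row["sample"]): str(row["group"])
            for _, row in gdf.iterrows()
            if not (isinstance(row["group"], float) and math.isnan(row["group"]))
        }
    return CountMatrix(values=df, groups=groups, source_db=source_db)


__all__ += ["write_matrix_tsv", "read_matrix_tsv", "UNCLASSIFIED_LABEL"]
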