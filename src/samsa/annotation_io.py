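"""Reading and writing MG-RAST-style tab-delimited annotation exports.

An annotation export assigns each sequencing read its best similarity-search
hit against a reference database (RefSeq organisms, RefSeq functions, SEED
Subsystems, or SILVA SSU rRNA).  A read whose best score is tied between
several references appears once per tied hit, all rows sharing the read id.
The exact column layout of an export is not standardized, so parsing is
driven by an :class:`AnnotationDialect` describing the column order and the
delimiter used inside multi-annotation cells.

Also provided here: partitioning records into mRNA versus rRNA (by database
of origin first, with a keyword fallback on the annotation text), and offline
construction of MG-RAST RESTful API request URLs.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

__all__ = [
    "SourceDB",
    "AnnotationRecord",
    "AnnotationDialect",
    "ParseResult",
    "parse_annotations",
    "write_annotations",
    "filter_rrna",
    "build_api_request",
    "DEFAULT_RRNA_KEYWORDS",
]


class SourceDB(str, Enum):
    """Reference database an annotation record was matched against."""

    REFSEQ_ORG = "RefSeq-organism"
    REFSEQ_FUNC = "RefSeq-function"
    SUBSYSTEMS = "Subsystems"
    SILVA_SSU = "SILVA-SSU"


# Optional numeric columns and their converters/validators.
_NUMERIC_FIELDS = {
    "percent_identity": float,
    "alignment_length": int,
    "evalue": float,
}


@dataclass(frozen=True)
class AnnotationRecord:
    """One best-hit match of one read against one reference database.

    A read with *k* tied best hits yields *k* records sharing ``read_id``.
    """

    read_id: str
    annotation_text: str
    source_db: SourceDB
    match_id: str = ""
    percent_identity: float | None = None
    alignment_length: int | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.annotation_text:
            raise ValueError("annotation_text must be non-empty")
        if self.percent_identity is not None and not (
            0.0 <= self.percent_identity <= 100.0
        ):
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if self.alignment_length is not None and self.alignment_length < 1:
            raise ValueError(f"alignment_length must be >= 1: {self.alignment_length}")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"evalue must be non-negative: {self.evalue}")


#: BLAST-tabular-flavoured default column order; MG-RAST downloads are
#: similarity-search derived, and real exports can be accommodated by
#: passing a different column_order.
DEFAULT_COLUMN_ORDER = (
    "read_id",
    "match_id",
    "percent_identity",
    "alignment_length",
    "evalue",
    "annotation_text",
)


@dataclass(frozen=True)
class AnnotationDialect:
    """Column layout of a tab-delimited annotation export."""

    column_order: tuple[str, ...] = DEFAULT_COLUMN_ORDER
    annotation_column_delimiter: str = ";"
    comment_prefix: str = "#"

    def __post_init__(self) -> None:
        if "read_id" not in self.column_order or "annotation_text" not in self.column_order:
            raise ValueError(
                "column_order must contain 'read_id' and 'annotation_text'"
            )

    @property
    def n_columns(self) -> int:
        return len(self.column_order)


@dataclass
class ParseResult:
    """Records parsed from one stream plus a tally of malformed lines."""

    records: list[AnnotationRecord]
    malformed: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_malformed(self) -> int:
        return len(self.malformed)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _open_text(source: str | Path | IO[str]) -> tuple[IO[str], bool]:
    """Open *source* for text reading; returns (handle, should_close)."""
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt"), True
    return open(path, "rt"), True


def parse_annotations(
    stream: str | Path | IO[str],
    dialect: AnnotationDialect | None = None,
    source_db: SourceDB = SourceDB.REFSEQ_ORG,
    *,
    strict: bool = False,
) -> ParseResult:
    """Parse a tab-delimited annotation export into records.

    Multi-entry annotation cells (entries separated by the dialect's
    delimiter, the tied-best-hit convention) expand into one record per
    entry, all sharing the line's ``read_id``.  Comment lines are skipped.
    Malformed lines (too few columns, bad numeric fields, empty mandatory
    fields) are counted and reported in the result; with ``strict=True``
    they raise ``ValueError`` instead.

    Parameters
    ----------
    stream
        Path (plain or ``.gz``) or open text handle.
    dialect
        Column layout; defaults to the BLAST-tabular-style layout.
    source_db
        Database of origin recorded on every parsed record.
    """
    dialect = dialect or AnnotationDialect()
    handle, should_close = _open_text(stream)
    result = ParseResult(records=[])
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(dialect.comment_prefix):
                continue
            fields_ = line.split("\t")
            if len(fields_) < dialect.n_columns:
                if strict:
                    raise ValueError(
                        f"line {lineno}: expected {dialect.n_columns} columns, "
                        f"got {len(fields_)}"
                    )
                result.malformed.append((lineno, line))
                continue
            row = dict(zip(dialect.column_order, fields_))
            try:
                kwargs: dict = {
                    "read_id": row["read_id"],
                    "match_id": row.get("match_id", ""),
                    "source_db": source_db,
                }
                for name, conv in _NUMERIC_FIELDS.items():
                    val = row.get(name, "")
                    kwargs[name] = conv(val) if val not in ("", "-", "NA") else None
                cell = row["annotation_text"]
                entries = [
                    e.strip()
                    for e in cell.split(dialect.annotation_column_delimiter)
                    if e.strip()
                ]
                if not entries:
                    raise ValueError("empty annotation cell")
                for entry in entries:
                    result.records.append(
                        AnnotationRecord(annotation_text=entry, **kwargs)
                    )
            except (ValueError, KeyError) as exc:
                if strict:
                    raise ValueError(f"line {lineno}: {exc}") from exc
                result.malformed.append((lineno, line))
    finally:
        if should_close:
            handle.close()
    return result


def write_annotations(
    records: Iterable[AnnotationRecord],
    stream: str | Path | IO[str] | None = None,
    dialect: AnnotationDialect | None = None,
) -> str:
    """Serialize records as tab-delimited text in the given dialect.

    One line per record — tied hits are *not* re-merged into shared cells,
    so ``parse_annotations(write_annotations(x))`` reproduces ``x``
    field-for-field.  Records whose text fields embed a tab or newline are
    refused: the output would be ambiguous on re-parse.

    Returns the serialized text; if *stream* is given, also writes it there.
    """
    dialect = dialect or AnnotationDialect()
    buf = io.StringIO()
    buf.write(dialect.comment_prefix + "\t".join(dialect.column_order) + "\n")
    for rec in records:
        for text_field in (rec.read_id, rec.match_id, rec.annotation_text):
            if "\t" in text_field or "\n" in text_field:
                raise ValueError(
                    f"field {text_field!r} contains a tab or newline; "
                    "refusing to emit ambiguous output"
                )
        if dialect.annotation_column_delimiter in rec.annotation_text:
            raise ValueError(
                f"annotation_text {rec.annotation_text!r} contains the "
                "multi-annotation delimiter; refusing to emit ambiguous output"
            )
        row = []
        for col in dialect.column_order:
            val = getattr(rec, col)
            if val is None:
                row.append("")
            elif col == "evalue":
                row.append(repr(val))
            else:
                row.append(str(val))
        buf.write("\t".join(row) + "\n")
    text = buf.getvalue()
    if stream is not None:
        if hasattr(stream, "write"):
            stream.write(text)  # type: ignore[union-attr]
        else:
            path = Path(stream)
            opener = gzip.open if path.suffix == ".gz" else open
            with opener(path, "wt") as fh:  # type: ignore[operator]
                fh.write(text)
    return text


#: Annotation-text substrings that mark a record as ribosomal RNA even when
#: its database of origin is not SILVA SSU.  Case-insensitive; extensible.
DEFAULT_RRNA_KEYWORDS = ("ribosomal RNA", "16S", "23S", "5S")


def filter_rrna(
    records: Iterable[AnnotationRecord],
    keyword_list: Sequence[str] = DEFAULT_RRNA_KEYWORDS,
) -> tuple[list[AnnotationRecord], list[AnnotationRecord]]:
    """Partition records into (mRNA, rRNA).

    A record goes to the rRNA partition if its database of origin is SILVA
    SSU, or if its annotation text contains any keyword (case-insensitive).
    The two partitions are disjoint and exhaustive.
    """
    keywords = [k.lower() for k in keyword_list]
    mrna: list[AnnotationRecord] = []
    rrna: list[AnnotationRecord] = []
    for rec in records:
        text = rec.annotation_text.lower()
        if rec.source_db is SourceDB.SILVA_SSU or any(k in text for k in keywords):
            rrna.append(rec)
        else:
            mrna.append(rec)
    return mrna, rrna


_API_BASE = "https://api.mg-rast.org/1/annotation/similarity"

_SOURCE_PARAM = {
    SourceDB.REFSEQ_ORG: "RefSeq",
    SourceDB.REFSEQ_FUNC: "RefSeq",
    SourceDB.SUBSYSTEMS: "Subsystems",
    SourceDB.SILVA_SSU: "SSU",
}

_ANNOTATION_TYPES = ("organism", "function", "ontology")


def build_api_request(
    dataset_id: str,
    source_db: SourceDB,
    annotation_type: str,
    auth_key: str,
) -> str:
    """Construct (offline) the MG-RAST RESTful API URL for an annotation download.

    No network call is performed; the returned string is deterministic in its
    arguments.
    """
    if not dataset_id:
        raise ValueError("dataset_id must be non-empty")
    if not auth_key:
        raise ValueError("auth_key must be non-empty")
    if annotation_type not in _ANNOTATION_TYPES:
        raise ValueError(
            f"annotation_type must be one of {_ANNOTATION_TYPES}, got {annotation_type!r}"
        )
    source = _SOURCE_PARAM[SourceDB(source_db)]
    return (
        f"{_API_BASE}/{dataset_id}"
        f"?source={source}&type={annotation_type}&auth={auth_key}"
    )
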