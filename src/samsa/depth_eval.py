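"""Sequencing-depth sufficiency by subsampling an annotated dataset.

How many annotated reads does a metatranscriptome need before relative
abundances stabilize?  The procedure: draw random subsets of the full
dataset at a grid of fractions, many replicates each; for every feature
compare its relative abundance in the subset with its relative abundance in
the full data; summarize that accuracy separately for high-, medium- and
low-abundance features; report the smallest depth at which a class clears a
target accuracy.

Subsampling operates on the count table rather than on raw reads: drawing
round(fraction * total) reads without replacement from the read population
implied by the counts is exactly a multivariate hypergeometric draw, which
is distributionally identical to shuffling the reads themselves and far
cheaper.

Accuracy for feature f in subset s is

    accuracy_f = 100 * (1 - |rel_s(f) - rel_full(f)| / rel_full(f))

clamped to [0, 100]: the relative deviation of a rare feature can exceed
100%, and negative accuracies carry no extra information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import AbundanceTable, sort_abundance

__all__ = [
    "SubsampleSpec",
    "AbundanceClassSpec",
    "AccuracyCurve",
    "ABUNDANCE_CLASSES",
    "subsample_table",
    "classify_abundance",
    "accuracy_curve",
    "min_depth",
]

#: Fractions of the full dataset used by default for the subset grid.
DEFAULT_FRACTIONS = (0.01, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)

ABUNDANCE_CLASSES = ("high", "medium", "low")


@dataclass(frozen=True)
class SubsampleSpec:
    """Grid of subset fractions and replicate count for the depth analysis.

    Defaults: fractions 1-90% of the full dataset and 100 replicate subsets
    per fraction.
    """

    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.fractions
        if not fr:
            raise ValueError("fractions must be non-empty")
        if any(not (0.0 < f <= 1.0) for f in fr):
            raise ValueError(f"fractions must lie in (0, 1]: {fr}")
        if list(fr) != sorted(set(fr)):
            raise ValueError("fractions must be sorted ascending and unique")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass(frozen=True)
class AbundanceClassSpec:
    """How features are stratified into high / medium / low abundance.

    Defaults: high = the 5 most abundant features; medium = features in the
    top half of the sorted list, excluding high; low = the bottom tenth of
    the sorted list.  Percentile-style stratifications can be expressed by
    adjusting the three knobs.
    """

    top_n_high: int = 5
    medium_top_fraction: float = 0.5
    low_bottom_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.top_n_high < 1:
            raise ValueError("top_n_high must be >= 1")
        if not (0 < self.medium_top_fraction <= 1):
            raise ValueError("medium_top_fraction must lie in (0, 1]")
        if not (0 < self.low_bottom_fraction <= 1):
            raise ValueError("low_bottom_fraction must lie in (0, 1]")


@dataclass
class AccuracyCurve:
    """Accuracy summaries per (fraction, abundance class).

    ``data`` columns: fraction, abundance_class, mean_accuracy, sd_accuracy,
    n_features, n_replicates; accuracies are percentages in [0, 100].
    ``total_reads`` is the full dataset's annotation total, used to convert
    fractions into absolute depths.
    """

    data: pd.DataFrame
    total_reads: float = field(default=0.0)


def _counts_vector(table: AbundanceTable) -> tuple[list[str], np.ndarray]:
    """Features (sorted-by-abundance order) and their integer count vector."""
    ordered = sort_abundance(table)
    keys = [k for k, _ in ordered]
    counts = np.array([c for _, c in ordered])
    rounded = np.rint(counts).astype(np.int64)
    if not np.allclose(counts, rounded):
        raise ValueError(
            "subsampling requires integer counts (count_all tie policy); "
            "got fractional counts"
        )
    return keys, rounded


def subsample_table(
    full: AbundanceTable,
    fraction: float,
    seed: int,
) -> AbundanceTable:
    """Draw one random subset of the dataset's reads, without replacement.

    The subset holds exactly round(fraction * total) reads, drawn
    multivariate-hypergeometrically from the feature counts; no feature can
    exceed its parent count.  Deterministic in the seed.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    keys, counts = _counts_vector(full)
    total = int(counts.sum())
    if total < 1:
        raise ValueError("full table must hold at least one read")
    n = int(round(fraction * total))
    rng = np.random.default_rng(seed)
    draw = rng.multivariate_hypergeometric(counts, n)
    sub = {k: float(c) for k, c in zip(keys, draw) if c > 0}
    return AbundanceTable(
        sample_id=f"{full.sample_id}|subsample", source_db=full.source_db, counts=sub
    )


def classify_abundance(
    full: AbundanceTable,
    class_spec: AbundanceClassSpec | None = None,
) -> dict[str, list[str]]:
    """Stratify features into disjoint high / medium / low abundance classes.

    Features are ranked by descending count with lexicographic tie-break, so
    the stratification is deterministic.  A table too small for the spec's
    classes to be disjoint (fewer than top_n_high + 1 features under the
    default spec) is rejected.
    """
    spec = class_spec or AbundanceClassSpec()
    keys, _ = _counts_vector(full)
    n_feat = len(keys)
    if n_feat == 0:
        raise ValueError("full table is empty")
    n_high = spec.top_n_high
    n_medium_end = int(np.floor(spec.medium_top_fraction * n_feat))
    n_low = max(1, int(np.floor(spec.low_bottom_fraction * n_feat)))
    low_start = n_feat - n_low
    if n_feat <= n_high or low_start < n_high or low_start < n_medium_end:
        raise ValueError(
            f"table with {n_feat} features is too small for disjoint classes "
            f"under spec {spec}"
        )
    return {
        "high": keys[:n_high],
        "medium": keys[n_high:n_medium_end],
        "low": keys[low_start:],
    }


def accuracy_curve(
    full: AbundanceTable,
    spec: SubsampleSpec | None = None,
    class_spec: AbundanceClassSpec | None = None,
) -> AccuracyCurve:
    """Mean and SD of per-feature abundance accuracy per (fraction, class).

    For every fraction in the spec's grid, draws ``replicates`` independent
    subsets and scores every classified feature's accuracy against the full
    data; accuracies are aggregated (unweighted) over features x replicates
    within each abundance class.  Classes left empty by the stratification
    are omitted from the output.
    """
    spec = spec or SubsampleSpec()
    keys, counts = _counts_vector(full)
    total = int(counts.sum())
    if total < 10:
        raise ValueError("need a parent of at least 10 reads")
    classes = classify_abundance(full, class_spec)
    index_of = {k: i for i, k in enumerate(keys)}
    class_idx = {
        cls: np.array([index_of[k] for k in feats], dtype=np.int64)
        for cls, feats in classes.items()
        if feats
    }
    rel_full = counts / total
    rng = np.random.default_rng(spec.seed)
    rows = []
    for fraction in spec.fractions:
        n = int(round(fraction * total))
        if n < 1:
            raise ValueError(f"fraction {fraction} yields an empty subset")
        draws = rng.multivariate_hypergeometric(counts, n, size=spec.replicates)
        rel_sub = draws / n  # replicates x features
        acc = 100.0 * (1.0 - np.abs(rel_sub - rel_full) / rel_full)
        np.clip(acc, 0.0, 100.0, out=acc)
        for cls in ABUNDANCE_CLASSES:
            if cls not in class_idx:
                continue
            block = acc[:, class_idx[cls]]
            rows.append(
                {
                    "fraction": fraction,
                    "abundance_class": cls,
                    "mean_accuracy": float(block.mean()),
                    "sd_accuracy": float(block.std(ddof=1)) if block.size > 1 else 0.0,
                    "n_features": int(block.shape[1]),
                    "n_replicates": spec.replicates,
                }
            )
    return AccuracyCurve(data=pd.DataFrame(rows), total_reads=float(total))


def min_depth(
    curve: AccuracyCurve,
    abundance_class: str = "low",
    threshold: float = 90.0,
) -> float | None:
    """Smallest absolute depth at which a class's mean accuracy clears the threshold.

    Returns round(fraction * total_reads) for the smallest qualifying
    fraction, or None if the class never reaches the threshold on the grid.
    Defaults target 90% accuracy for the low-abundance class, the binding
    constraint in practice.
    """
    if curve.data.empty:
        raise ValueError("curve is empty")
    if abundance_class not in ABUNDANCE_CLASSES:
        raise ValueError(
            f"unknown abundance class {abundance_class!r}; expected one of "
            f"{ABUNDANCE_CLASSES}"
        )
    sub = curve.data[curve.data["abundance_class"] == abundance_class]
    if sub.empty:
        raise ValueError(f"curve has no rows for class {abundance_class!r}")
    ok = sub[sub["mean_accuracy"] >= threshold].sort_values("fraction")
    if ok.empty:
        return None
    return float(round(float(ok.iloc[0]["fraction"]) * curve.total_reads))


def write_curve_tsv(curve: AccuracyCurve, path) -> None:
    """Accuracy curve as TSV, one row per (fraction, class)."""
    with open(path, "w") as fh:
        fh.write(f"# total_reads={curve.total_reads:.0f}\n")
        curve.data.to_csv(fh, sep="\t", index=False, float_format="%.6g")


__all__ += ["write_curve_tsv", "DEFAULT_FRACTIONS"]
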