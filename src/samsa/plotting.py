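"""Graphical outputs: stacked community bar charts and sample dendrograms.

Plots are rendered headless (Agg backend) to PNG and/or SVG, and the numbers
behind every plot are also emitted as TSV so tests can assert on data rather
than pixels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .aggregation import (
    OTHER_LABEL,
    AbundanceTable,
    CountMatrix,
    merge_to_matrix,
    top_n_other,
)

__all__ = ["plot_stacked_bars", "plot_dendrogram", "bray_curtis_linkage"]


def _as_matrix(data: CountMatrix | Sequence[AbundanceTable]) -> CountMatrix:
    if isinstance(data, CountMatrix):
        return data
    return merge_to_matrix(list(data))


def stacked_bar_data(
    data: CountMatrix | Sequence[AbundanceTable],
    mode: str = "percent",
    top_n: int = 30,
) -> pd.DataFrame:
    """Category x sample values behind the stacked bar chart.

    Categories are the overall top ``top_n`` features plus an ``Other``
    catch-all (last row, present only when there is a remainder).  In
    ``percent`` mode each sample column sums to 100.
    """
    if mode not in ("percent", "counts"):
        raise ValueError(f"unknown mode {mode!r}")
    matrix = _as_matrix(data)
    if not matrix.samples:
        raise ValueError("no samples to plot")
    pooled = AbundanceTable(
        sample_id="pooled",
        source_db=matrix.source_db,  # type: ignore[arg-type]
        counts=dict(matrix.values.sum(axis=1)),
    )
    kept = top_n_other(pooled, n=top_n, mode="other_bucket")
    top_keys = [k for k in kept.counts if k != OTHER_LABEL]
    top_keys.sort(key=lambda k: (-kept.counts[k], k))
    rows = matrix.values.reindex(top_keys).fillna(0.0)
    if OTHER_LABEL in kept.counts:
        other = matrix.values.sum(axis=0) - rows.sum(axis=0)
        rows.loc[OTHER_LABEL] = other
    if mode == "percent":
        rows = 100.0 * rows / rows.sum(axis=0)
    return rows


def plot_stacked_bars(
    data: CountMatrix | Sequence[AbundanceTable],
    out_path: str | Path,
    mode: str = "percent",
    top_n: int = 30,
    data_tsv: str | Path | None = None,
) -> Path:
    """Stacked bar chart of community composition, one bar per sample.

    ``percent`` mode shows each sample's percentage breakdown (bars sum to
    100); ``counts`` mode shows absolute annotation counts.  At most
    ``top_n`` + 1 categories appear, the catch-all ``Other`` last.
    """
    rows = stacked_bar_data(data, mode=mode, top_n=top_n)
    if data_tsv is not None:
        rows.to_csv(data_tsv, sep="\t", float_format="%.6g")
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * rows.shape[1] + 3), 6))
    bottom = np.zeros(rows.shape[1])
    cmap = plt.get_cmap("tab20")
    for i, (label, vals) in enumerate(rows.iterrows()):
        color = "#9467bd" if label == OTHER_LABEL else cmap(i % 20)
        ax.bar(rows.columns, vals.to_numpy(), bottom=bottom, label=str(label), color=color)
        bottom += vals.to_numpy()
    ax.set_ylabel("% of annotations" if mode == "percent" else "annotations")
    ax.set_xlabel("sample")
    ax.legend(bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def bray_curtis_linkage(matrix: CountMatrix) -> np.ndarray:
    """Average-linkage hierarchy of samples on Bray-Curtis distance.

    Distances are computed on per-sample relative abundances, so library
    size does not drive the clustering.
    """
    if len(matrix.samples) < 3:
        raise ValueError("need at least 3 samples to cluster")
    vals = matrix.values.to_numpy(dtype=float).T  # samples x features
    totals = vals.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("a sample has zero total; cannot normalize")
    rel = vals / totals
    dist = pdist(rel, metric="braycurtis")
    return hierarchy.linkage(dist, method="average")


def plot_dendrogram(
    matrix: CountMatrix,
    out_path: str | Path,
    data_tsv: str | Path | None = None,
) -> Path:
    """Sample dendrogram (Bray-Curtis distance, average linkage)."""
    Z = bray_curtis_linkage(matrix)
    if data_tsv is not None:
        pd.DataFrame(
            Z, columns=["left", "right", "height", "n_leaves"]
        ).to_csv(data_tsv, sep="\t", index=False, float_format="%.6g")
    fig, ax = plt.subplots(figsize=(max(6, 0.6 * len(matrix.samples) + 2), 5))
    hierarchy.dendrogram(Z, labels=matrix.samples, ax=ax)
    ax.set_ylabel("Bray-Curtis distance (average linkage)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
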