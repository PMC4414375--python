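"""Expression quantification, filtering and normalization.

Converts raw read counts to the representations the analyses consume:
RPKM (reads per kilobase of exon per million mapped reads), the detectable-
expression filter (RPKM > 0.2 in over 75% of samples), the minimum-read-count
filter used before enrichment analysis, upper-quartile normalization, and
per-gene log2 median-centering for clustering and heatmaps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import CountMatrix, ExpressionMatrix

__all__ = [
    "compute_rpkm",
    "filter_expressed",
    "filter_min_counts",
    "upper_quartile_normalize",
    "log2_median_center",
]


def compute_rpkm(counts: CountMatrix,
                 totals: pd.Series | None = None) -> ExpressionMatrix:
    """RPKM(g, s) = counts(g, s) * 1e9 / (length(g) * total(s)).

    ``totals`` defaults to the column sums of the provided matrix; pass a
    per-sample Series to use externally known totals of mapped reads
    (e.g. alignment totals computed before any gene filtering).
    """
    if totals is None:
        totals = counts.counts.sum(axis=0)
    else:
        totals = totals.reindex(counts.sample_ids)
        if totals.isna().any():
            raise ValueError("totals missing for some samples")
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"zero total mapped reads for sample(s): {zero}")
    values = (counts.counts * 1e9).div(counts.gene_lengths, axis=0).div(
        totals, axis=1)
    return ExpressionMatrix(values, stage="rpkm")


def filter_expressed(expr: ExpressionMatrix, min_rpkm: float = 0.2,
                     min_fraction: float = 0.75,
                     mode: str = "rpkm") -> ExpressionMatrix:
    """Keep detectably expressed genes.

    mode "rpkm": keep genes with RPKM strictly > ``min_rpkm`` in strictly
    more than ``min_fraction`` of samples.  mode "nonzero": the weaker
    exclusion of genes whose expression is zero across all samples.
    Gene order is preserved; an empty result only warns.
    """
    if expr.stage != "rpkm":
        raise ValueError(f"filter_expressed requires stage 'rpkm', got {expr.stage!r}")
    vals = expr.values
    if mode == "rpkm":
        frac = (vals > min_rpkm).mean(axis=1)
        keep = frac > min_fraction
    elif mode == "nonzero":
        keep = (vals != 0).any(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not keep.any():
        warnings.warn("no genes pass the expression filter", stacklevel=2)
    return expr.subset_genes(vals.index[keep])


def filter_min_counts(counts: CountMatrix, min_reads: int = 10) -> CountMatrix:
    """Keep genes with at least ``min_reads`` mapped reads in >= 1 sample."""
    keep = counts.counts.max(axis=1) >= min_reads
    return counts.subset_genes(counts.counts.index[keep])


def upper_quartile_normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Divide each sample by the 75th percentile of its nonzero counts.

    Columns are then rescaled by the geometric mean of those percentiles so
    the overall magnitude of the matrix is preserved.  Invariant to
    per-sample sequencing-depth scaling.
    """
    mat = counts.counts.to_numpy(dtype=float)
    q75 = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        nz = mat[:, j][mat[:, j] > 0]
        if nz.size == 0:
            raise ValueError(
                f"sample {counts.sample_ids[j]!r} has no nonzero counts")
        q75[j] = np.percentile(nz, 75)
    scale = np.exp(np.mean(np.log(q75)))  # geometric mean preserves magnitude
    values = mat / q75[None, :] * scale
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        stage="uq_normalized")


def log2_median_center(expr: ExpressionMatrix,
                       pseudocount: float = 0.01) -> ExpressionMatrix:
    """Per-gene median-centered log2 expression.

    value = log2(rpkm + pseudocount) - rowmedian(log2(rpkm + pseudocount)).
    Entries that were exactly zero are flagged in ``zero_mask`` so display
    layers can keep the "not expressed" semantic distinct from "low".
    """
    if expr.stage != "rpkm":
        raise ValueError(f"log2_median_center requires stage 'rpkm', got {expr.stage!r}")
    logged = np.log2(expr.values + pseudocount)
    centered = logged.sub(logged.median(axis=1), axis=0)
    return ExpressionMatrix(centered, stage="log2_centered",
                            zero_mask=expr.values == 0)
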