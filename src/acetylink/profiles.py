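"""Metaprofile matrices and sample-correlation matrices.

Reference-point mode averages depth in fixed-width bins around an anchor
(TSS or TES); scale-regions mode bins fixed-width flanks plus a gene body
rescaled to a fixed number of fractional windows.  Rows for minus-strand
genes are reversed so upstream is always on the left.  Sample correlation
is Spearman (rank Pearson, average ranks on ties) or Pearson on
log2(x + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CountMatrix, CoverageTrack, GenomeAnnotation

log = logging.getLogger(__name__)


@dataclass
class MetaMatrix:
    """Anchor-region x genomic-bin mean-depth matrix with axis metadata."""

    values: pd.DataFrame  # rows: gene_id, columns: bin offsets/labels
    mode: str             # "reference-point" | "scale-regions"
    bin_width: int
    flank: int
    body_bins: int = 0

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def reference_point_matrix(track: CoverageTrack, annotation: GenomeAnnotation,
                           anchor: str = "tss", flank: int = 3000,
                           bin_width: int = 50) -> MetaMatrix:
    """Mean depth per ``bin_width`` bin over [anchor - flank, anchor + flank).

    ``anchor`` is "tss" or "tes", strand-aware.  Bins beyond a chromosome
    edge count the missing bases as depth 0.  Minus-strand rows are
    reversed so the left edge is always upstream.
    """
    if anchor not in ("tss", "tes"):
        raise ValueError("anchor must be 'tss' or 'tes'")
    n_bins = (2 * flank) // bin_width
    seen = set()
    rows, index = [], []
    for g in annotation:
        if g.chrom not in track.runs and g.chrom not in seen:
            seen.add(g.chrom)
            log.warning("chromosome %s missing from track; profile zeros", g.chrom)
        pos = g.tss if anchor == "tss" else g.tes
        edges = pos - flank + np.arange(n_bins + 1) * bin_width
        means = np.array([
            track.interval_integral(g.chrom, max(0.0, a), max(0.0, b)) / bin_width
            for a, b in zip(edges[:-1], edges[1:])
        ])
        if g.strand == "-":
            means = means[::-1]
        rows.append(means)
        index.append(g.gene_id)
    cols = (np.arange(n_bins) * bin_width) - flank
    frame = pd.DataFrame(rows, index=index, columns=cols)
    return MetaMatrix(frame, "reference-point", bin_width, flank)


def scale_regions_matrix(track: CoverageTrack, annotation: GenomeAnnotation,
                         flank: int = 1000, body_bins: int = 100,
                         bin_width: int = 50) -> MetaMatrix:
    """Flanks at fixed ``bin_width`` plus body rescaled to ``body_bins``.

    Body windows are fractional for genes shorter than ``body_bins`` bases.
    Minus-strand rows are reversed.
    """
    n_flank = flank // bin_width
    rows, index = [], []
    for g in annotation:
        up = g.start - flank + np.arange(n_flank + 1) * bin_width
        body = g.start + (g.end - g.start) * np.arange(body_bins + 1) / body_bins
        down = g.end + np.arange(n_flank + 1) * bin_width
        means = np.concatenate([
            [track.interval_integral(g.chrom, max(0.0, a), max(0.0, b)) / bin_width
             for a, b in zip(up[:-1], up[1:])],
            [track.mean_depth(g.chrom, a, b)
             for a, b in zip(body[:-1], body[1:])],
            [track.interval_integral(g.chrom, max(0.0, a), max(0.0, b)) / bin_width
             for a, b in zip(down[:-1], down[1:])],
        ])
        if g.strand == "-":
            means = means[::-1]
        rows.append(means)
        index.append(g.gene_id)
    cols = (
        [f"u{k}" for k in range(n_flank)]
        + [f"b{k}" for k in range(body_bins)]
        + [f"d{k}" for k in range(n_flank)]
    )
    frame = pd.DataFrame(rows, index=index, columns=cols)
    return MetaMatrix(frame, "scale-regions", bin_width, flank, body_bins)


def mean_profile(meta: MetaMatrix) -> pd.Series:
    """Per-bin mean over all anchor regions (the figure's summary curve)."""
    if meta.values.empty:
        raise ValueError("empty metaprofile matrix")
    return meta.values.mean(axis=0)


def sample_correlation(matrix: CountMatrix | pd.DataFrame,
                       method: str = "spearman") -> pd.DataFrame:
    """Sample x sample correlation matrix.

    Spearman ranks (average on ties) then Pearson; plain Pearson runs on
    log2(x + 1).  A zero-variance sample yields NaN against every other.
    """
    frame = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if frame.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = frame.to_numpy(dtype=float)
    if method == "spearman":
        ranks = pd.DataFrame(X).rank().to_numpy()  # average ranks on ties
        rho = np.corrcoef(ranks, rowvar=False)
    elif method == "pearson":
        rho = np.corrcoef(np.log2(X + 1.0), rowvar=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    zero_var = X.std(axis=0) == 0
    if zero_var.any():
        log.warning("zero-variance sample(s): %s",
                    list(frame.columns[zero_var]))
        rho[zero_var, :] = np.nan
        rho[:, zero_var] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=frame.columns, columns=frame.columns)
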