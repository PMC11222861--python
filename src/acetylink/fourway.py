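"""Genome-wide four-way classification of peak-gene pairs.

Each differential H3K27ac peak is paired with the gene whose TSS is
nearest (within a distance cap), the peak's normalized signal is
correlated with the gene's expression across samples, and the pair is
placed in one of four quadrants by the sign of the gene's expression fold
change and of the correlation:

* PP — gene up   (log2FC >= 1)  and positively correlated (r >= 0.5)
* PN — gene down (log2FC <= -1) and positively correlated (r >= 0.5)
* NP — gene up   and negatively correlated (r <= -0.5)
* NN — gene down and negatively correlated (r <= -0.5)

Pairs meeting neither bound are labelled "none".  All comparisons are
closed (>=, <=), matching the printed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import GenomeAnnotation, GenomicInterval, PeakSet

QUADRANTS = ("PP", "PN", "NP", "NN")


@dataclass(frozen=True)
class PeakGeneLink:
    """One peak paired with its nearest-TSS gene."""

    peak_id: str
    interval: GenomicInterval
    gene_id: str
    symbol: str
    tss_distance: float  # signed, midpoint - TSS, oriented by gene strand


def assign_peaks_to_genes(peaks: PeakSet, annotation: GenomeAnnotation,
                          max_distance: int = 50_000) -> list[PeakGeneLink]:
    """Link each peak to the gene with nearest TSS (peak midpoint distance).

    Peaks with no TSS within ``max_distance`` stay unlinked; equidistant
    candidates resolve to the lexicographically smaller gene_id.  The
    reported distance is signed and strand-oriented: positive means the
    peak lies downstream of the TSS in the gene's reading direction.
    """
    tss = annotation.tss_positions()
    links: list[PeakGeneLink] = []
    by_chrom = {c: sub.sort_values(["pos", "gene_id"]).reset_index(drop=True)
                for c, sub in tss.groupby("chrom")}
    for iv in peaks:
        sub = by_chrom.get(iv.chrom)
        if sub is None:
            continue
        mid = iv.midpoint
        dist = np.abs(sub["pos"].to_numpy() - mid)
        best = dist.min()
        if best > max_distance:
            continue
        cands = sub[dist == best].sort_values("gene_id")
        row = cands.iloc[0]
        signed = mid - row["pos"]
        if row["strand"] == "-":
            signed = -signed
        gene = annotation.by_id(row["gene_id"])
        links.append(
            PeakGeneLink(
                peak_id=iv.name or str(iv),
                interval=iv,
                gene_id=gene.gene_id,
                symbol=gene.symbol,
                tss_distance=float(signed),
            )
        )
    return links


def peak_gene_correlation(peak_signal: pd.Series | np.ndarray,
                          expression: pd.Series | np.ndarray) -> float:
    """Pearson r between per-sample peak signal and expression.

    A zero-variance vector makes r undefined; it is reported as 0.0 (the
    pair then never passes the |r| >= 0.5 bound).
    """
    x = np.asarray(peak_signal, dtype=float)
    y = np.asarray(expression, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def classify_fourway(gene_log2fc: float, pearson_r: float,
                     cor_threshold: float = 0.5,
                     lfc_threshold: float = 1.0) -> str:
    """Quadrant for one (gene log2FC, peak-gene r) pair; "none" outside."""
    if not (np.isfinite(gene_log2fc) and np.isfinite(pearson_r)):
        return "none"
    pos_r = pearson_r >= cor_threshold
    neg_r = pearson_r <= -cor_threshold
    up = gene_log2fc >= lfc_threshold
    down = gene_log2fc <= -lfc_threshold
    if pos_r and up:
        return "PP"
    if pos_r and down:
        return "PN"
    if neg_r and up:
        return "NP"
    if neg_r and down:
        return "NN"
    return "none"


def fourway_table(links: list[PeakGeneLink],
                  peak_signal: pd.DataFrame,
                  expression: pd.DataFrame,
                  gene_results: pd.DataFrame,
                  diff_peak_ids: set[str] | None = None,
                  cor_threshold: float = 0.5,
                  lfc_threshold: float = 1.0,
                  ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classified link table plus per-quadrant counts.

    ``peak_signal`` (peaks x samples, normalized) and ``expression``
    (genes x samples, FPKM or normalized counts) must share sample order.
    ``gene_results`` supplies each gene's log2FoldChange.  When
    ``diff_peak_ids`` is given, only links whose peak is in it enter the
    table — the differential-peak restriction of the genome-wide plot.
    """
    if list(peak_signal.columns) != list(expression.columns):
        raise ValueError("peak signal and expression sample order differ")
    rows = []
    counts = {q: 0 for q in QUADRANTS}
    for link in links:
        if diff_peak_ids is not None and link.peak_id not in diff_peak_ids:
            continue
        if link.peak_id not in peak_signal.index:
            continue
        if link.gene_id not in expression.index or link.gene_id not in gene_results.index:
            continue
        r = peak_gene_correlation(
            peak_signal.loc[link.peak_id], expression.loc[link.gene_id]
        )
        lfc = float(gene_results.loc[link.gene_id, "log2FoldChange"])
        quadrant = classify_fourway(lfc, r, cor_threshold, lfc_threshold)
        if quadrant in counts:
            counts[quadrant] += 1
        rows.append(
            {
                "peak": link.peak_id,
                "gene": link.gene_id,
                "symbol": link.symbol,
                "distance": link.tss_distance,
                "r": r,
                "gene_log2fc": lfc,
                "quadrant": quadrant,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["peak", "gene", "symbol", "distance", "r", "gene_log2fc",
                 "quadrant"],
    )
    return table, counts
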