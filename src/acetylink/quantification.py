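"""Consensus features and normalized signal/count matrices.

Reproduces the merge -> per-interval coverage -> normalize flow: peak sets
from all samples are merged into one consensus set (bedtools-merge
semantics, book-ended intervals merge at ``min_gap=0``), per-base depth is
summed over each interval (samtools-bedcov semantics), low-expression
features are dropped by the 80%-below-2 rule, and per-sample scale is
estimated by the median-of-ratios.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .genomic_io import CountMatrix, CoverageTrack, GenomicInterval, PeakSet

log = logging.getLogger(__name__)


def merge_intervals(peak_sets: list[PeakSet], min_gap: int = 0) -> PeakSet:
    """Merge >= 1 peak sets into non-overlapping consensus intervals.

    Two intervals merge iff their gap is <= ``min_gap``; at the default 0
    overlapping and book-ended intervals merge, matching ``bedtools merge``.
    Output names are ``merged_<k>`` and the score carries the constituent
    count.
    """
    if not peak_sets:
        raise ValueError("need at least one peak set")
    ivs = sorted(
        (iv for ps in peak_sets for iv in ps),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    if not ivs:
        return PeakSet([])
    cur_chrom, cur_s, cur_e, n = ivs[0].chrom, ivs[0].start, ivs[0].end, 1
    out: list[tuple[str, int, int, int]] = []
    for iv in ivs[1:]:
        if iv.chrom == cur_chrom and iv.start - cur_e <= min_gap:
            cur_e = max(cur_e, iv.end)
            n += 1
        else:
            out.append((cur_chrom, cur_s, cur_e, n))
            cur_chrom, cur_s, cur_e, n = iv.chrom, iv.start, iv.end, 1
    out.append((cur_chrom, cur_s, cur_e, n))
    for k, (chrom, s, e, cnt) in enumerate(out):
        merged.append(
            GenomicInterval(chrom, s, e, name=f"merged_{k + 1}", score=float(cnt))
        )
    return PeakSet(merged)


def quantify_coverage(features: PeakSet, track: CoverageTrack) -> pd.Series:
    """Sum of per-base depth over each feature (bedcov semantics).

    Features on chromosomes absent from the track get signal 0 with a
    warning.  Feature names key the result; unnamed features are keyed by
    their coordinates.
    """
    missing = sorted({iv.chrom for iv in features} - set(track.chroms()))
    if missing:
        log.warning("chromosomes absent from track, signal set to 0: %s", missing)
    values, index = [], []
    for iv in features:
        index.append(iv.name or str(iv))
        values.append(track.interval_sum(iv.chrom, iv.start, iv.end))
    return pd.Series(values, index=index, dtype=float)


def quantify_samples(features: PeakSet, tracks: dict[str, CoverageTrack],
                     groups: dict[str, str]) -> CountMatrix:
    """Per-sample bedcov quantification over one consensus feature set."""
    frame = pd.DataFrame(
        {sample: quantify_coverage(features, trk) for sample, trk in tracks.items()}
    )
    meta = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in features],
            "start": [iv.start for iv in features],
            "end": [iv.end for iv in features],
        },
        index=frame.index,
    )
    return CountMatrix(frame, groups, meta)


def filter_low_expression(matrix: CountMatrix, frac: float = 0.8,
                          min_count: float = 2) -> tuple[CountMatrix, list[str]]:
    """Drop features lowly covered in at least ``ceil(frac * n)`` samples.

    A feature is dropped iff the number of samples with count < ``min_count``
    is >= ceil(frac * n_samples); with the 6-sample default that means 5 of
    6 samples below 2 reads.  Returns (kept matrix, dropped feature ids).
    """
    n = len(matrix.sample_ids)
    cutoff = math.ceil(frac * n)
    low = (matrix.counts < min_count).sum(axis=1)
    dropped = list(matrix.counts.index[low >= cutoff])
    kept = [f for f in matrix.feature_ids if f not in set(dropped)]
    return matrix.subset(kept), dropped


def size_factors_median_of_ratios(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample size factors, rescaled to geometric mean 1.

    factor_j = median over zero-free features of count_ij / geomean_i.  When
    no zero-free feature exists, falls back to total-count ratios with a
    warning.
    """
    counts = matrix.counts.to_numpy(dtype=float)
    zero_free = (counts > 0).all(axis=1)
    if zero_free.any():
        sub = counts[zero_free]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = sub / np.exp(log_geo)
        factors = np.median(ratios, axis=0)
    else:
        log.warning("no zero-free feature; falling back to total-count ratios")
        totals = counts.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.sample_ids)


def fpkm(matrix: CountMatrix, gene_lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (length * library)."""
    lengths = gene_lengths.reindex(matrix.counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ValueError(f"missing gene length for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = matrix.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    return matrix.counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)
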