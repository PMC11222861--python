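"""ROSE-style super-enhancer identification and differential analysis.

Enhancer peaks clear of any TSS (+/- 2.5 kb) are stitched when separated
by at most 12.5 kb; each stitched region is scored by its input-subtracted
H3K27ac coverage sum; regions are ranked by signal and the class boundary
sits where the min-max-scaled rank-signal curve's discrete slope first
exceeds 1 (the slope-1 tangent of the hockey-stick curve).  Regions above
the boundary are super-enhancers.

Group-wise differential super-enhancers: per-sample SE intervals are
merged within each group, unioned across groups, re-quantified on every
sample's ChIP coverage and tested with the shared NB test at the SE
thresholds (|log2FC| >= 0.6, p <= 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import SE_THRESHOLDS, Thresholds, call_features, nb_test
from .genomic_io import (
    CountMatrix,
    CoverageTrack,
    GenomeAnnotation,
    GenomicInterval,
    PeakSet,
)
from .quantification import merge_intervals, quantify_samples, size_factors_median_of_ratios

log = logging.getLogger(__name__)

DEFAULT_STITCH_BP = 12_500
DEFAULT_TSS_EXCLUDE_BP = 2_500


@dataclass
class StitchedEnhancer:
    interval: GenomicInterval
    constituents: list[GenomicInterval] = field(default_factory=list)

    @property
    def n_constituents(self) -> int:
        return len(self.constituents)


@dataclass
class SECall:
    enhancer: StitchedEnhancer
    signal: float
    rank: int
    is_super: bool


def exclude_tss_proximal(peaks: PeakSet, annotation: GenomeAnnotation,
                         window: int = DEFAULT_TSS_EXCLUDE_BP) -> PeakSet:
    """Drop peaks overlapping any TSS +/- ``window`` bp.

    With window 0 only peaks containing the TSS base itself are removed.
    """
    tss = annotation.tss_positions()
    by_chrom = {
        c: np.sort(sub["pos"].to_numpy()) for c, sub in tss.groupby("chrom")
    }
    kept = []
    for iv in peaks:
        pos = by_chrom.get(iv.chrom)
        if pos is not None:
            lo, hi = iv.start - window, iv.end + window  # TSS in [lo, hi)
            i = np.searchsorted(pos, lo, side="left")
            if i < len(pos) and pos[i] < hi:
                continue
        kept.append(iv)
    return PeakSet(kept)


def stitch_enhancers(peaks: PeakSet, stitch_distance: int = DEFAULT_STITCH_BP
                     ) -> list[StitchedEnhancer]:
    """Transitively cluster peaks whose gap is <= ``stitch_distance``."""
    stitched: list[StitchedEnhancer] = []
    cur: list[GenomicInterval] = []
    for iv in peaks:
        if cur and iv.chrom == cur[-1].chrom and iv.start - max(
            c.end for c in cur
        ) <= stitch_distance:
            cur.append(iv)
        else:
            if cur:
                stitched.append(_close_cluster(cur, len(stitched)))
            cur = [iv]
    if cur:
        stitched.append(_close_cluster(cur, len(stitched)))
    return stitched


def _close_cluster(cluster: list[GenomicInterval], k: int) -> StitchedEnhancer:
    start = min(c.start for c in cluster)
    end = max(c.end for c in cluster)
    iv = GenomicInterval(cluster[0].chrom, start, end, name=f"stitched_{k + 1}")
    return StitchedEnhancer(iv, list(cluster))


def se_signal(stitched: list[StitchedEnhancer], chip_track: CoverageTrack,
              input_track: CoverageTrack | None = None) -> np.ndarray:
    """Input-subtracted ChIP coverage sum per region, floored at 0."""
    if input_track is None:
        log.warning("no input track; ranking on ChIP signal alone")
    out = np.empty(len(stitched))
    for i, se in enumerate(stitched):
        iv = se.interval
        chip = chip_track.interval_sum(iv.chrom, iv.start, iv.end)
        inp = (
            input_track.interval_sum(iv.chrom, iv.start, iv.end)
            if input_track is not None
            else 0.0
        )
        out[i] = max(0.0, chip - inp)
    return out


def se_cutoff(signals: np.ndarray) -> float:
    """Signal threshold at the slope-1 tangent of the scaled rank curve.

    Signals are sorted ascending; rank index and signal are each min-max
    scaled to [0, 1]; the cutoff is the (unscaled) signal at the first
    index whose forward discrete slope exceeds 1.  A curve that never
    exceeds slope 1 (e.g. perfectly linear) yields cutoff = max and no
    super-enhancers.
    """
    s = np.sort(np.asarray(signals, dtype=float))
    if s.size < 3 or s[-1] == s[0]:
        log.warning("degenerate signal vector; no super-enhancers")
        return float(s.max()) if s.size else 0.0
    span = s[-1] - s[0]
    y = (s - s[0]) / span
    x = np.arange(len(s)) / (len(s) - 1)
    slopes = np.diff(y) / np.diff(x)
    above = np.nonzero(slopes > 1.0)[0]
    if above.size == 0:
        log.warning("rank-signal curve never exceeds slope 1; no super-enhancers")
        return float(s[-1])
    return float(s[above[0]])


def call_superenhancers(stitched: list[StitchedEnhancer], signals: np.ndarray
                        ) -> list[SECall]:
    """Rank regions by signal and flag those above the tangent cutoff.

    Ranks are 1 = highest signal; ties resolve by genomic position so the
    output is invariant to input order.
    """
    signals = np.asarray(signals, dtype=float)
    if len(signals) != len(stitched):
        raise ValueError("signals and stitched regions differ in length")
    cutoff = se_cutoff(signals) if len(signals) else 0.0
    order = sorted(
        range(len(stitched)),
        key=lambda i: (
            -signals[i],
            stitched[i].interval.chrom,
            stitched[i].interval.start,
        ),
    )
    calls = [None] * len(stitched)
    for rank, i in enumerate(order, start=1):
        calls[i] = SECall(
            enhancer=stitched[i],
            signal=float(signals[i]),
            rank=rank,
            is_super=bool(signals[i] > cutoff),
        )
    return list(calls)


def identify_superenhancers(peaks: PeakSet, annotation: GenomeAnnotation,
                            chip_track: CoverageTrack,
                            input_track: CoverageTrack | None = None,
                            stitch_distance: int = DEFAULT_STITCH_BP,
                            tss_window: int = DEFAULT_TSS_EXCLUDE_BP,
                            ) -> list[SECall]:
    """The full per-sample chain: TSS exclusion, stitching, ranking, calling."""
    distal = exclude_tss_proximal(peaks, annotation, tss_window)
    stitched = stitch_enhancers(distal, stitch_distance)
    signals = se_signal(stitched, chip_track, input_track)
    return call_superenhancers(stitched, signals)


def se_table(calls: list[SECall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [str(c.enhancer.interval) for c in calls],
            "n_constituents": [c.enhancer.n_constituents for c in calls],
            "signal": [c.signal for c in calls],
            "rank": [c.rank for c in calls],
            "is_super": [c.is_super for c in calls],
        }
    )


def differential_se(per_sample_calls: dict[str, list[SECall]],
                    groups: dict[str, str],
                    chip_tracks: dict[str, CoverageTrack],
                    thresholds: Thresholds = SE_THRESHOLDS,
                    size_factors: pd.Series | None = None,
                    ) -> tuple[pd.DataFrame, CountMatrix]:
    """Differential super-enhancers between the two groups.

    Per-sample SE intervals are merged within each group; the group region
    sets are unioned and merged again into one feature set, quantified on
    every sample's ChIP track, size-factor normalized and tested with the
    NB test at the SE thresholds.  Returns (results with call column, the
    SE count matrix).

    Pass ``size_factors`` estimated from a genome-wide feature set (e.g.
    the consensus-peak matrix) when only a handful of SE regions exist —
    the median-of-ratios over very few, partly differential regions is
    unstable.
    """
    levels = list(dict.fromkeys(groups.values()))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    group_sets = []
    for g in levels:
        members = [s for s, grp in groups.items() if grp == g]
        ivs = [
            c.enhancer.interval
            for s in members
            for c in per_sample_calls.get(s, [])
            if c.is_super
        ]
        if not ivs:
            log.warning("group %s has no super-enhancers; using other group's", g)
            continue
        group_sets.append(merge_intervals([PeakSet(ivs)]))
    if not group_sets:
        raise ValueError("no super-enhancers in either group")
    union = merge_intervals(group_sets)
    matrix = quantify_samples(union, chip_tracks, groups)
    sf = size_factors if size_factors is not None else \
        size_factors_median_of_ratios(matrix)
    res = nb_test(matrix, sf)
    res["call"] = call_features(res, thresholds)
    return res, matrix


def annotate_se_genes(calls: list[SECall], annotation: GenomeAnnotation,
                      window: int = 50_000) -> pd.DataFrame:
    """Genes covered by or adjacent to each super-enhancer.

    A gene whose body overlaps the SE interval is labelled "covers"; when
    none does, the nearest-TSS gene within ``window`` bp is labelled
    "adjacent".  SEs with neither get no rows.
    """
    rows = []
    for c in calls:
        if not c.is_super:
            continue
        iv = c.enhancer.interval
        overlapping = [
            g for g in annotation
            if g.chrom == iv.chrom and g.start < iv.end and iv.start < g.end
        ]
        if overlapping:
            for g in overlapping:
                rows.append(
                    {"se": str(iv), "gene": g.gene_id, "symbol": g.symbol,
                     "relation": "covers"}
                )
            continue
        best, best_d = None, None
        for g in annotation:
            if g.chrom != iv.chrom:
                continue
            d = min(abs(g.tss - iv.start), abs(g.tss - (iv.end - 1)))
            if best_d is None or d < best_d or (d == best_d and g.gene_id < best.gene_id):
                best, best_d = g, d
        if best is not None and best_d <= window:
            rows.append(
                {"se": str(iv), "gene": best.gene_id, "symbol": best.symbol,
                 "relation": "adjacent"}
            )
    return pd.DataFrame(rows, columns=["se", "gene", "symbol", "relation"])
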