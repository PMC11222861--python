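import numpy as np
import pytest

from acetylink.genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PeakSet,
)
from acetylink.superenhancer import (
    annotate_se_genes,
    call_superenhancers,
    differential_se,
    exclude_tss_proximal,
    identify_superenhancers,
    se_cutoff,
    se_signal,
    stitch_enhancers,
)


def one_gene_annotation(tss=50_000, strand="+"):
    start = tss if strand == "+" else tss - 999
    g = GeneModel(gene_id="g1", symbol="G1", chrom="chr1", strand=strand,
                  start=start, end=start + 1000, length_bp=1000)
    return GenomeAnnotation([g], {"chr1": 10_000_000})


def peaks(*coords):
    return PeakSet(GenomicInterval("chr1", s, e, name=f"p{i}")
                   for i, (s, e) in enumerate(coords))


class TestExcludeTssProximal:
    def test_overlapping_tss_window_removed(self):
        ann = one_gene_annotation(tss=50_000)
        ps = peaks((49_000, 50_500), (100_000, 101_000))
        kept = exclude_tss_proximal(ps, ann, window=2_500)
        assert [iv.start for iv in kept] == [100_000]

    def test_within_window_but_not_overlapping_tss_removed(self):
        ann = one_gene_annotation(tss=50_000)
        ps = peaks((51_000, 52_000))  # within 2.5 kb of the TSS
        assert len(exclude_tss_proximal(ps, ann, window=2_500)) == 0

    def test_distal_peak_kept(self):
        ann = one_gene_annotation(tss=50_000)
        ps = peaks((60_000, 61_000))
        assert len(exclude_tss_proximal(ps, ann, window=2_500)) == 1

    def test_window_zero_requires_containing_tss(self):
        ann = one_gene_annotation(tss=50_000)
        containing = peaks((49_900, 50_100))
        adjacent = peaks((50_001, 50_100))
        assert len(exclude_tss_proximal(containing, ann, window=0)) == 0
        assert len(exclude_tss_proximal(adjacent, ann, window=0)) == 1


class TestStitchEnhancers:
    def test_gap_below_distance_merges(self):
        out = stitch_enhancers(peaks((0, 100), (12_000, 12_100)))
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 12_100)
        assert out[0].n_constituents == 2

    def test_gap_at_distance_merges_but_one_more_splits(self):
        at = stitch_enhancers(peaks((0, 100), (12_600, 12_700)))
        assert len(at) == 1  # gap 12_500 == stitch distance
        over = stitch_enhancers(peaks((0, 100), (12_601, 12_700)))
        assert len(over) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(200_000, size=30, replace=False))
        ps = PeakSet(GenomicInterval("chr1", int(s), int(s) + 500)
                     for s in starts)
        got = stitch_enhancers(ps, stitch_distance=5_000)
        # oracle: union-find over the pairwise gap relation
        parent = list(range(30))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ivs = list(ps)
        for i in range(30):
            for j in range(i + 1, 30):
                gap = max(ivs[j].start - ivs[i].end,
                          ivs[i].start - ivs[j].end)
                if gap <= 5_000:
                    parent[find(i)] = find(j)
        clusters = {}
        for i in range(30):
            clusters.setdefault(find(i), []).append(ivs[i])
        expected = sorted(
            (min(c.start for c in cl), max(c.end for c in cl))
            for cl in clusters.values()
        )
        assert [(s.interval.start, s.interval.end) for s in got] == expected


class TestSeSignal:
    def test_input_subtraction(self):
        stitched = stitch_enhancers(peaks((0, 100)))
        chip = CoverageTrack({"chr1": ([0], [100], [3.0])})
        inp = CoverageTrack({"chr1": ([0], [100], [1.0])})
        assert se_signal(stitched, chip, inp)[0] == 200.0

    def test_floored_at_zero(self):
        stitched = stitch_enhancers(peaks((0, 100)))
        chip = CoverageTrack({"chr1": ([0], [100], [1.0])})
        inp = CoverageTrack({"chr1": ([0], [100], [5.0])})
        assert se_signal(stitched, chip, inp)[0] == 0.0

    def test_no_coverage_zero(self):
        stitched = stitch_enhancers(peaks((500, 600)))
        chip = CoverageTrack({"chr1": ([0], [100], [3.0])})
        assert se_signal(stitched, chip, None)[0] == 0.0


def brute_force_cutoff(signals):
    """Independent slope-scan: first sorted index with forward slope > 1."""
    s = np.sort(np.asarray(signals, float))
    y = (s - s[0]) / (s[-1] - s[0])
    x = np.arange(len(s)) / (len(s) - 1)
    for i in range(len(s) - 1):
        if (y[i + 1] - y[i]) / (x[i + 1] - x[i]) > 1.0:
            return float(s[i])
    return float(s[-1])


class TestSeCutoff:
    def test_linear_curve_no_superenhancers(self):
        cutoff = se_cutoff(np.arange(10.0))
        assert cutoff == 9.0
        assert (np.arange(10.0) > cutoff).sum() == 0

    def test_single_outlier_is_sole_superenhancer(self):
        signals = np.array([1.0, 1, 1, 1, 100])
        cutoff = se_cutoff(signals)
        assert cutoff < 100
        assert (signals > cutoff).sum() == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_slope_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # convex-ordered hockey-stick: exponential of sorted normals
        signals = np.sort(np.exp(rng.normal(2, 1.5, size=50)))
        assert se_cutoff(signals) == brute_force_cutoff(signals)

    def test_affine_invariance_of_the_class(self, rng):
        signals = np.sort(np.exp(rng.normal(2, 1.5, size=40)))
        base = signals > se_cutoff(signals)
        scaled = 3.0 * signals + 17.0
        assert np.array_equal(scaled > se_cutoff(scaled), base)

    def test_constant_signals_warn_no_super(self):
        assert se_cutoff(np.array([5.0, 5.0, 5.0, 5.0])) == 5.0


class TestCallSuperenhancers:
    def _hockey(self, rng, n=30):
        starts = np.arange(n) * 20_000
        ps = PeakSet(GenomicInterval("chr1", int(s), int(s) + 500)
                     for s in starts)
        stitched = stitch_enhancers(ps, stitch_distance=1_000)
        signals = np.concatenate([rng.uniform(10, 20, n - 1), [500.0]])
        return stitched, signals

    def test_huge_signal_is_unique_super(self, rng):
        stitched, signals = self._hockey(rng)
        calls = call_superenhancers(stitched, signals)
        supers = [c for c in calls if c.is_super]
        assert len(supers) == 1 and supers[0].signal == 500.0
        assert supers[0].rank == 1

    def test_ranks_are_a_permutation(self, rng):
        stitched, signals = self._hockey(rng)
        calls = call_superenhancers(stitched, signals)
        assert sorted(c.rank for c in calls) == list(range(1, len(calls) + 1))

    def test_input_order_invariance(self, rng):
        stitched, signals = self._hockey(rng)
        perm = rng.permutation(len(stitched))
        a = call_superenhancers(stitched, signals)
        b = call_superenhancers([stitched[i] for i in perm], signals[perm])
        key = lambda c: (c.enhancer.interval.start)
        assert [(c.rank, c.is_super) for c in sorted(a, key=key)] == \
            [(c.rank, c.is_super) for c in sorted(b, key=key)]

    def test_top_ranked_is_super_when_any(self, rng):
        stitched, signals = self._hockey(rng)
        calls = call_superenhancers(stitched, signals)
        if any(c.is_super for c in calls):
            top = next(c for c in calls if c.rank == 1)
            assert top.is_super


class TestDifferentialSe:
    @staticmethod
    def _peak_sf(ds, cfg):
        from acetylink.quantification import (
            quantify_samples, size_factors_median_of_ratios)
        mat = quantify_samples(ds.chip.consensus_peaks, ds.chip.chip_tracks,
                               cfg.animal_groups)
        return size_factors_median_of_ratios(mat)

    def test_shared_equal_se_has_near_zero_lfc(self, small_dataset, small_config):
        ds, cfg = small_dataset, small_config
        calls = {
            a: identify_superenhancers(ds.chip.peaks[a], ds.annotation,
                                       ds.chip.chip_tracks[a],
                                       ds.chip.input_tracks[a])
            for a in cfg.animals
        }
        res, mat = differential_se(calls, cfg.animal_groups, ds.chip.chip_tracks,
                                   size_factors=self._peak_sf(ds, cfg))
        shared = ds.truth.se_regions["CTR"]
        for iv in shared:
            hit = mat.feature_meta[
                (mat.feature_meta["chrom"] == iv.chrom)
                & (mat.feature_meta["start"] < iv.end)
                & (mat.feature_meta["end"] > iv.start)
            ]
            assert len(hit) == 1
            assert abs(res.loc[hit.index[0], "log2FoldChange"]) < 0.3

    def test_group_specific_se_called_up(self, small_dataset, small_config):
        ds, cfg = small_dataset, small_config
        calls = {
            a: identify_superenhancers(ds.chip.peaks[a], ds.annotation,
                                       ds.chip.chip_tracks[a],
                                       ds.chip.input_tracks[a])
            for a in cfg.animals
        }
        res, mat = differential_se(calls, cfg.animal_groups, ds.chip.chip_tracks,
                                   size_factors=self._peak_sf(ds, cfg))
        specific = [iv for iv in ds.truth.se_regions["FLHS"]
                    if iv not in ds.truth.se_regions["CTR"]]
        assert specific
        for iv in specific:
            hit = mat.feature_meta[
                (mat.feature_meta["chrom"] == iv.chrom)
                & (mat.feature_meta["start"] < iv.end)
                & (mat.feature_meta["end"] > iv.start)
            ]
            assert (res.loc[hit.index, "call"] == "up").all()


class TestAnnotateSeGenes:
    def _calls(self, start, end):
        from acetylink.superenhancer import SECall
        stitched = stitch_enhancers(
            PeakSet([GenomicInterval("chr1", start, end)]))
        return [SECall(stitched[0], 100.0, 1, True)]

    def test_covering_relation(self):
        ann = one_gene_annotation(tss=50_000)
        out = annotate_se_genes(self._calls(49_000, 52_000), ann)
        assert out.iloc[0]["relation"] == "covers"

    def test_adjacent_relation(self):
        ann = one_gene_annotation(tss=50_000)
        out = annotate_se_genes(self._calls(38_000, 40_000), ann)
        assert out.iloc[0]["relation"] == "adjacent"
        assert out.iloc[0]["gene"] == "g1"

    def test_nothing_in_window(self):
        ann = one_gene_annotation(tss=50_000)
        out = annotate_se_genes(self._calls(500_000, 502_000), ann, window=50_000)
        assert out.empty
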