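import numpy as np
import pandas as pd
import pytest

from acetylink.genomic_io import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
)
from acetylink.profiles import (
    mean_profile,
    reference_point_matrix,
    sample_correlation,
    scale_regions_matrix,
)

from conftest import random_track


def make_annotation(genes):
    models = [
        GeneModel(gene_id=gid, symbol=gid, chrom="chr1", strand=strand,
                  start=start, end=end, length_bp=end - start)
        for gid, start, end, strand in genes
    ]
    return GenomeAnnotation(models, {"chr1": 1_000_000})


def constant_track(depth=3.0, length=1_000_000):
    return CoverageTrack({"chr1": ([0], [length], [depth])})


class TestReferencePoint:
    def test_constant_depth_fills_every_cell(self):
        ann = make_annotation([("g1", 50_000, 51_000, "+")])
        meta = reference_point_matrix(constant_track(3.0), ann)
        assert np.allclose(meta.values.to_numpy(), 3.0)
        assert meta.n_bins == 120

    def test_single_hot_bin(self):
        ann = make_annotation([("g1", 50_000, 51_000, "+")])
        trk = CoverageTrack({"chr1": ([50_000], [50_050], [5.0])})
        meta = reference_point_matrix(trk, ann, flank=500, bin_width=50)
        row = meta.values.iloc[0]
        assert row.loc[0] == 5.0
        assert row.drop(0).sum() == 0.0

    def test_minus_strand_mirrors_plus(self):
        trk = CoverageTrack({"chr1": ([49_000], [50_000], [4.0])})
        plus = make_annotation([("g1", 50_000, 51_000, "+")])
        # minus-strand gene with TSS at the same genomic base 50_000
        minus = make_annotation([("g1", 49_001, 50_001, "-")])
        a = reference_point_matrix(trk, plus, flank=1_000).values.to_numpy()[0]
        b = reference_point_matrix(trk, minus, flank=1_000).values.to_numpy()[0]
        assert np.allclose(a, b[::-1])

    def test_chromosome_edge_pads_with_zero(self):
        ann = make_annotation([("g1", 100, 1_100, "+")])
        meta = reference_point_matrix(constant_track(2.0), ann, flank=500,
                                      bin_width=50)
        row = meta.values.to_numpy()[0]
        # bins upstream of base 0 read depth 0: first 2 bins truncated
        assert row[0] == 0.0
        assert row[-1] == 2.0


class TestScaleRegions:
    def test_constant_depth_flat(self):
        ann = make_annotation([("g1", 50_000, 52_000, "+")])
        meta = scale_regions_matrix(constant_track(2.5), ann)
        assert np.allclose(meta.values.to_numpy(), 2.5)

    def test_body_only_signal(self):
        ann = make_annotation([("g1", 50_000, 52_000, "+")])
        trk = CoverageTrack({"chr1": ([50_000], [52_000], [7.0])})
        meta = scale_regions_matrix(trk, ann, flank=1_000, body_bins=10)
        row = meta.values.iloc[0]
        assert np.allclose(row[[c for c in row.index if c.startswith("b")]], 7.0)
        assert row[[c for c in row.index if not c.startswith("b")]].sum() == 0.0

    def test_short_gene_fractional_windows(self):
        ann = make_annotation([("g1", 50_000, 50_010, "+")])  # 10 bp body
        trk = CoverageTrack({"chr1": ([50_000], [50_010], [4.0])})
        meta = scale_regions_matrix(trk, ann, flank=100, body_bins=40)
        body = meta.values.iloc[0][[f"b{k}" for k in range(40)]]
        assert np.allclose(body, 4.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        trk = random_track(rng, n_runs=30, max_pos=4_000)
        ann = make_annotation([("g1", 1_000, 3_000, "+")])
        meta = scale_regions_matrix(trk, ann, flank=500, body_bins=20,
                                    bin_width=50)
        # brute force mean depth per window over expanded bases
        def depth(b):
            starts, ends, depths = trk.runs["chr1"]
            for s, e, d in zip(starts, ends, depths):
                if s <= b < e:
                    return d
            return 0.0
        got = meta.values.iloc[0]
        for k in range(10):  # upstream flank bins
            lo = 1_000 - 500 + k * 50
            want = np.mean([depth(b) for b in range(lo, lo + 50)])
            assert got[f"u{k}"] == pytest.approx(want)
        for k in range(20):  # body windows (100 bp each here)
            lo = 1_000 + k * 100
            want = np.mean([depth(b) for b in range(lo, lo + 100)])
            assert got[f"b{k}"] == pytest.approx(want)


class TestMetaProperties:
    def test_linearity_over_tracks(self, rng):
        a = random_track(rng, n_runs=25, max_pos=10_000)
        b = random_track(rng, n_runs=25, max_pos=10_000)
        ann = make_annotation([("g1", 3_000, 4_000, "+"),
                               ("g2", 6_000, 7_000, "-")])
        pa = reference_point_matrix(a, ann, flank=1_000).values
        pb = reference_point_matrix(b, ann, flank=1_000).values
        psum = reference_point_matrix(a + b, ann, flank=1_000).values
        assert np.allclose(psum.to_numpy(), (pa + pb).to_numpy())

    def test_strand_flip_mirrors_all_rows(self, rng):
        trk = random_track(rng, n_runs=25, max_pos=10_000)
        fwd = make_annotation([("g1", 3_000, 4_000, "+")])
        rev = make_annotation([("g1", 3_001, 4_001, "-")])  # same TSS-centred span
        a = reference_point_matrix(trk, fwd, flank=500).values.to_numpy()[0]
        # g1 minus-strand TSS = 4_000; reference span [3_500, 4_500) reversed
        b = reference_point_matrix(trk, rev, flank=500).values.to_numpy()[0]
        trk_b = [trk.mean_depth("chr1", 4_000 - 500 + 50 * k,
                                4_000 - 450 + 50 * k) for k in range(20)]
        assert np.allclose(b, trk_b[::-1])

    def test_mean_profile_arithmetic(self):
        frame = pd.DataFrame([[1.0, 2, 3, 4], [3, 2, 1, 0], [5, 5, 5, 8]])
        from acetylink.profiles import MetaMatrix
        meta = MetaMatrix(frame, "reference-point", 50, 100)
        assert np.allclose(mean_profile(meta), [3.0, 3.0, 3.0, 4.0])

    def test_tss_enrichment_peaks_at_tss(self, small_dataset, small_config):
        ds, cfg = small_dataset, small_config
        animal = cfg.animals[0]
        meta = reference_point_matrix(ds.chip.chip_tracks[animal],
                                      ds.annotation, flank=3_000)
        profile = mean_profile(meta)
        tss_col = np.searchsorted(profile.index.to_numpy(), 0)
        assert abs(int(np.argmax(profile.to_numpy())) - tss_col) <= 2


class TestSampleCorrelation:
    def _matrix(self, rng, n=200):
        base = rng.poisson(100, size=(n, 1)).astype(float)
        counts = base + rng.normal(0, 5, size=(n, 4))
        counts = np.clip(counts, 0, None)
        frame = pd.DataFrame(counts, columns=list("wxyz"))
        return frame

    def test_unit_diagonal_and_symmetry(self, rng):
        rho = sample_correlation(self._matrix(rng))
        assert np.allclose(np.diag(rho), 1.0)
        assert np.allclose(rho, rho.T)

    def test_monotone_transform_preserves_spearman(self, rng):
        frame = self._matrix(rng)
        a = sample_correlation(frame, "spearman")
        b = sample_correlation(np.exp(frame / 50.0), "spearman")
        assert np.allclose(a, b)

    def test_matches_rank_then_pearson_oracle(self):
        frame = pd.DataFrame({
            "s1": [1.0, 4, 2, 8, 5], "s2": [2.0, 5, 3, 9, 4],
        })
        got = sample_correlation(frame, "spearman").iloc[0, 1]
        ranks = frame.rank()
        x, y = ranks["s1"], ranks["s2"]
        want = np.corrcoef(x, y)[0, 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_zero_variance_sample_flagged(self):
        frame = pd.DataFrame({"s1": [1.0, 2, 3], "s2": [5.0, 5, 5]})
        rho = sample_correlation(frame, "pearson")
        assert np.isnan(rho.loc["s1", "s2"])
        assert rho.loc["s2", "s2"] == 1.0

    def test_intra_group_correlation_high_on_synthetic_counts(
            self, small_dataset):
        rho = sample_correlation(small_dataset.rna, "spearman")
        ctr = [s for s in rho.index if s.startswith("CTR")]
        sub = rho.loc[ctr, ctr].to_numpy()
        assert sub[np.triu_indices_from(sub, 1)].min() > 0.6
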