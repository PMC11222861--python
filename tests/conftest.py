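import numpy as np
import pytest

from acetylink.genomic_io import CoverageTrack, GenomicInterval, PeakSet
from acetylink.synthetic import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study: 1 chromosome, 40 genes, the default 3-vs-3 design."""
    return SimConfig(seed=11, n_chroms=1, chrom_length_bp=300_000, n_genes=40,
                     n_distal_enhancers=4, frac_diff_peaks=0.3, frac_linked=1.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_track(rng: np.random.Generator, chrom: str = "chr1",
                 n_runs: int = 40, max_pos: int = 2_000) -> CoverageTrack:
    """Random sorted non-overlapping runs with integer depths (incl. gaps)."""
    cuts = np.sort(rng.choice(max_pos, size=2 * n_runs, replace=False))
    starts, ends = cuts[0::2], cuts[1::2]
    depths = rng.integers(0, 6, size=n_runs).astype(float)
    keep = depths > 0
    return CoverageTrack({chrom: (starts[keep], ends[keep], depths[keep])})


def random_peaks(rng: np.random.Generator, chrom: str = "chr1", n: int = 20,
                 max_pos: int = 2_000, max_len: int = 120) -> PeakSet:
    starts = rng.integers(0, max_pos - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return PeakSet(
        GenomicInterval(chrom, int(s), int(s + l), name=f"p{i}")
        for i, (s, l) in enumerate(zip(starts, lengths))
    )


def brute_force_interval_sum(track: CoverageTrack, chrom: str, start: int,
                             end: int) -> float:
    """Per-base oracle for coverage sums."""
    total = 0.0
    if chrom not in track.runs:
        return 0.0
    starts, ends, depths = track.runs[chrom]
    for b in range(start, end):
        for s, e, d in zip(starts, ends, depths):
            if s <= b < e:
                total += d
                break
    return total
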