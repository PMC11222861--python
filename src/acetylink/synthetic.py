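"""Synthetic dataset generator with planted ground truth.

Emulates a 3-vs-3 high-fat-diet study design: negative-binomial gene
counts, TSS-enriched piecewise-constant H3K27ac coverage with matched
input, planted differential peaks and genes, planted peak-gene
correlation structure via a shared per-animal latent factor, and
clustered distal enhancers forming super-enhancers.  Every draw goes
through one seeded :class:`numpy.random.Generator`, so a config fully
determines the dataset.

Layout conventions (see docs/methods.md for rationale):

* genes occupy the first ``gene_territory`` fraction of each chromosome,
  uniformly spaced with jitter and alternating strands;
* each gene carries a promoter enhancer (TSS-centred, 1 kb) with
  probability ``peak_probability``;
* super-enhancer clusters are placed in the gene-free tail of each
  chromosome, so they sit well clear of every TSS;
* coverage is Poisson per-base noise aggregated into 50 bp runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genomic_io import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    PeakSet,
)

CONTROL_GROUP = "CTR"
TREATMENT_GROUP = "FLHS"


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 500_000
    n_genes: int = 200
    n_samples_per_group: int = 3        # 3 animals per diet group
    frac_diff_genes: float = 0.1
    frac_diff_peaks: float = 0.1
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    mean_count: float = 200.0
    background_depth: float = 1.0
    peak_enrichment_fold: float = 8.0
    frac_se_clusters: float = 0.025     # of n_genes -> number of shared SE clusters
    peaks_per_se: int = 5
    se_enrichment_fold: float = 10.0
    n_group_specific_se: int = 1        # extra FLHS-only clusters
    n_distal_enhancers: int = 16        # background singles, the rank curve's tail
    link_correlation: float = 0.9
    frac_linked: float = 0.5            # of differential peaks that get a linked gene
    ct_noise_sd: float = 0.1
    # layout details
    gene_length_bp: int = 1000
    gene_territory: float = 0.6
    peak_probability: float = 0.9
    peak_halfwidth: int = 500
    run_bp: int = 50
    latent_sd_log2: float = 0.5
    library_sd_log: float = 0.1

    def __post_init__(self) -> None:
        for name in ("frac_diff_genes", "frac_diff_peaks", "frac_se_clusters",
                     "frac_linked", "peak_probability", "gene_territory"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be > 0")
        if not 0.0 <= self.link_correlation <= 1.0:
            raise ValueError("link_correlation must be in [0, 1]")

    @property
    def animals(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"{CONTROL_GROUP}_{i + 1}" for i in range(n)] + [
            f"{TREATMENT_GROUP}_{i + 1}" for i in range(n)
        ]

    @property
    def animal_groups(self) -> dict[str, str]:
        return {a: a.rsplit("_", 1)[0] for a in self.animals}


@dataclass
class SimTruth:
    """Planted ground truth for one simulated dataset."""

    diff_gene_effects: dict[str, float] = field(default_factory=dict)
    diff_peak_effects: dict[str, float] = field(default_factory=dict)
    links: list[tuple[str, str, int]] = field(default_factory=list)
    se_regions: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    # per-animal log2 latent jitter for linked peaks (rows: peak_id)
    peak_latent: pd.DataFrame | None = None
    gene_latent: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, eff in self.diff_gene_effects.items():
            rows.append(("diff_gene", gid, "", f"{eff:g}"))
        for pid, eff in self.diff_peak_effects.items():
            rows.append(("diff_peak", pid, "", f"{eff:g}"))
        for pid, gid, sign in self.links:
            rows.append(("link", pid, gid, f"{sign:d}"))
        for group, regions in self.se_regions.items():
            for iv in regions:
                rows.append(
                    ("se_region", f"{iv.chrom}:{iv.start}-{iv.end}", group, "")
                )
        return pd.DataFrame(rows, columns=["kind", "id", "partner", "value"])


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None
                    ) -> GenomeAnnotation:
    """Uniformly spaced, jittered, strand-alternating single-exon genes."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chrom_sizes = {
        f"chr{c + 1}": config.chrom_length_bp for c in range(config.n_chroms)
    }
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return GenomeAnnotation([], chrom_sizes)
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    idx = 0
    for c, n_here in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        territory = int(config.gene_territory * config.chrom_length_bp)
        if n_here == 0:
            continue
        spacing = territory / n_here
        if spacing < config.gene_length_bp * 1.5:
            raise ValueError(
                f"{n_here} genes of {config.gene_length_bp} bp do not fit "
                f"in {territory} bp of {chrom}"
            )
        jitter_max = max(1, int((spacing - config.gene_length_bp) / 4))
        for k in range(n_here):
            jitter = int(rng.integers(-jitter_max, jitter_max + 1))
            start = int(k * spacing + spacing / 4) + jitter
            start = max(0, min(start, territory - config.gene_length_bp))
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{idx:04d}",
                    symbol=f"GENE{idx}",
                    chrom=chrom,
                    strand="+" if idx % 2 else "-",
                    start=start,
                    end=start + config.gene_length_bp,
                    length_bp=config.gene_length_bp,
                )
            )
    return GenomeAnnotation(genes, chrom_sizes)


@dataclass
class ChipSim:
    """Output bundle of :func:`simulate_chip`."""

    peaks: dict[str, PeakSet]            # animal -> peak calls
    chip_tracks: dict[str, CoverageTrack]
    input_tracks: dict[str, CoverageTrack]
    consensus_peaks: PeakSet             # all distinct planted footprints
    truth: SimTruth


class _TailLayout:
    """Sequential placement in the gene-free chromosome tails.

    Keeps one cursor per chromosome, starting 5 kb past the gene territory
    (so TSS exclusion cannot touch anything placed here) and advancing with
    >12.5 kb gaps so distinct elements never stitch together.
    """

    GAP = 15_000  # between placed elements; comfortably above the stitch span

    def __init__(self, config: SimConfig, chrom_sizes: dict[str, int]) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self.chroms = sorted(chrom_sizes)
        self.cursor = {
            c: int(config.gene_territory * chrom_sizes[c]) + 5_000
            for c in self.chroms
        }
        self.slot = 0

    def place(self, span: int, what: str) -> tuple[str, int]:
        chrom = self.chroms[self.slot % len(self.chroms)]
        self.slot += 1
        base = self.cursor[chrom]
        if base + span > self.chrom_sizes[chrom]:
            raise ValueError(
                f"no room for {what} on {chrom}: need {span} bp at {base}, "
                f"chromosome ends at {self.chrom_sizes[chrom]}"
            )
        self.cursor[chrom] = base + span + self.GAP
        return chrom, base


def _place_se_clusters(config: SimConfig, layout: _TailLayout,
                       n_clusters: int, offset: int
                       ) -> list[list[GenomicInterval]]:
    """Lay out enhancer clusters of ``peaks_per_se`` constituents."""
    clusters: list[list[GenomicInterval]] = []
    peak_w, gap = 800, 1200
    span = config.peaks_per_se * peak_w + (config.peaks_per_se - 1) * gap
    for j in range(n_clusters):
        chrom, base = layout.place(span, f"SE cluster {offset + j}")
        peaks = []
        for k in range(config.peaks_per_se):
            s = base + k * (peak_w + gap)
            peaks.append(
                GenomicInterval(chrom, s, s + peak_w, name=f"sepk_{offset + j}_{k}")
            )
        clusters.append(peaks)
    return clusters


def simulate_chip(annotation: GenomeAnnotation, config: SimConfig,
                  rng: np.random.Generator | None = None) -> ChipSim:
    """Simulate per-animal H3K27ac peaks and coverage plus matched input.

    Each gene gets a promoter-proximal peak with probability
    ``peak_probability``; a fraction of those peaks are differential with
    group-specific enrichment ``2**effect_log2fc`` (hyper-acetylated peaks
    elevated in the treatment group, hypo-acetylated in the control).
    Super-enhancer clusters of ``peaks_per_se`` constituents are planted in
    the distal, gene-free chromosome tails.  Coverage is Poisson noise
    around the per-run expected depth; input is background only.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    truth = SimTruth()
    animals = config.animals
    groups = config.animal_groups

    # promoter peaks: a plateau over TSS +/- halfwidth with a sharper
    # summit over the central 100 bp, so metaprofiles peak at the TSS
    promoter_peaks: list[GenomicInterval] = []
    peak_of_gene: dict[str, str] = {}
    summit_of_peak: dict[str, GenomicInterval] = {}
    for g in annotation:
        if rng.random() >= config.peak_probability:
            continue
        size = annotation.chrom_sizes[g.chrom]
        s = max(0, g.tss - config.peak_halfwidth)
        e = min(size, g.tss + config.peak_halfwidth)
        pid = f"peak_{g.gene_id}"
        promoter_peaks.append(GenomicInterval(g.chrom, s, e, name=pid))
        peak_of_gene[g.gene_id] = pid
        cs, ce = max(0, g.tss - 50), min(size, g.tss + 50)
        summit_of_peak[pid] = GenomicInterval(g.chrom, cs, ce, name=pid)

    # differential peaks: half up (treatment-high), half down
    n_diff = int(round(config.frac_diff_peaks * len(promoter_peaks)))
    diff_idx = rng.choice(len(promoter_peaks), size=n_diff, replace=False)
    for j, i in enumerate(sorted(diff_idx)):
        sign = 1 if j % 2 == 0 else -1
        truth.diff_peak_effects[promoter_peaks[i].name] = sign * config.effect_log2fc

    # peak-gene links among differential promoter peaks
    gene_of_peak = {v: k for k, v in peak_of_gene.items()}
    diff_pids = sorted(truth.diff_peak_effects)
    n_link = int(round(config.frac_linked * len(diff_pids)))
    link_pids = [diff_pids[i] for i in
                 sorted(rng.choice(len(diff_pids), size=n_link, replace=False))]
    for pid in link_pids:
        gid = gene_of_peak[pid]
        sign = 1 if truth.diff_peak_effects[pid] > 0 else -1
        truth.links.append((pid, gid, sign))
        truth.diff_gene_effects[gid] = sign * config.effect_log2fc

    # remaining differential genes, unlinked
    n_diff_genes = int(round(config.frac_diff_genes * len(annotation)))
    free_gids = [g.gene_id for g in annotation
                 if g.gene_id not in truth.diff_gene_effects]
    extra = max(0, n_diff_genes - len(truth.diff_gene_effects))
    pick = [free_gids[i] for i in
            sorted(rng.choice(len(free_gids), size=min(extra, len(free_gids)),
                              replace=False))]
    for j, gid in enumerate(pick):
        sign = 1 if j % 2 == 0 else -1
        truth.diff_gene_effects[gid] = sign * config.effect_log2fc

    # latent per-animal structure for linked peak-gene pairs: the gene's
    # total log2 shift tracks the peak's (group effect + jitter) scaled by
    # link_correlation, so rho controls both the planted Pearson r and how
    # much of the peak's fold change the gene inherits
    rho = config.link_correlation
    sd = config.latent_sd_log2
    jit_peak = sd * rng.normal(0.0, 1.0, size=(len(truth.links), len(animals)))
    eps = sd * rng.normal(0.0, 1.0, size=(len(truth.links), len(animals)))
    in_treatment = np.array(
        [groups[a] == TREATMENT_GROUP for a in animals], dtype=float
    )
    shift_peak = np.empty_like(jit_peak)
    for i, (pid, _, _) in enumerate(truth.links):
        eff = truth.diff_peak_effects[pid]
        # group effect on the log2 scale, relative to the lower group
        grp = eff * in_treatment if eff > 0 else (-eff) * (1 - in_treatment)
        shift_peak[i] = grp + jit_peak[i]
    shift_gene = rho * shift_peak + np.sqrt(max(0.0, 1 - rho * rho)) * eps
    truth.peak_latent = pd.DataFrame(
        jit_peak, index=[pid for pid, _, _ in truth.links], columns=animals
    )
    truth.gene_latent = pd.DataFrame(
        shift_gene, index=[gid for _, gid, _ in truth.links], columns=animals
    )
    for pid, gid, sign in truth.links:
        truth.diff_gene_effects[gid] = rho * sign * config.effect_log2fc

    # distal territory: background single enhancers (the low tail of the
    # super-enhancer rank curve), then shared SE clusters, then
    # treatment-only clusters
    layout = _TailLayout(config, annotation.chrom_sizes)
    distal_singles = []
    for j in range(config.n_distal_enhancers):
        chrom, base = layout.place(1_000, f"distal enhancer {j}")
        distal_singles.append(
            GenomicInterval(chrom, base, base + 1_000, name=f"distal_{j}")
        )
    n_shared = max(1, int(round(config.frac_se_clusters * config.n_genes)))
    shared = _place_se_clusters(config, layout, n_shared, 0)
    specific = _place_se_clusters(config, layout, config.n_group_specific_se,
                                  n_shared)
    truth.se_regions[CONTROL_GROUP] = [
        GenomicInterval(c[0].chrom, c[0].start, c[-1].end, name=f"se{j}")
        for j, c in enumerate(shared)
    ]
    truth.se_regions[TREATMENT_GROUP] = truth.se_regions[CONTROL_GROUP] + [
        GenomicInterval(c[0].chrom, c[0].start, c[-1].end, name=f"se{len(shared) + j}")
        for j, c in enumerate(specific)
    ]

    # library scale per animal (exercises size-factor normalization)
    lib = np.exp(rng.normal(0.0, config.library_sd_log, size=len(animals)))

    # expected depth profiles, then Poisson noise per 50 bp run
    run = config.run_bp
    chip_tracks: dict[str, CoverageTrack] = {}
    input_tracks: dict[str, CoverageTrack] = {}
    peaks_by_animal: dict[str, PeakSet] = {}
    all_footprints: dict[str, GenomicInterval] = {}

    for ai, animal in enumerate(animals):
        group = groups[animal]
        lam: dict[str, np.ndarray] = {}
        for chrom, size in annotation.chrom_sizes.items():
            lam[chrom] = np.full(size // run, config.background_depth)

        visible: list[GenomicInterval] = []

        def paint(iv: GenomicInterval, fold: float) -> None:
            a, b = iv.start // run, max(iv.start // run + 1, -(-iv.end // run))
            lam[iv.chrom][a:b] *= fold

        for iv in promoter_peaks:
            fold = config.peak_enrichment_fold
            eff = truth.diff_peak_effects.get(iv.name, 0.0)
            if eff > 0 and group == TREATMENT_GROUP:
                fold *= 2.0 ** eff
            elif eff < 0 and group == CONTROL_GROUP:
                fold *= 2.0 ** (-eff)
            if truth.peak_latent is not None and iv.name in truth.peak_latent.index:
                fold *= 2.0 ** truth.peak_latent.loc[iv.name, animal]
            paint(iv, fold)
            if config.peak_enrichment_fold > 1.0:  # no summit on null peaks
                paint(summit_of_peak[iv.name], 2.0)
            visible.append(iv)
            all_footprints[iv.name] = iv

        for iv in distal_singles:
            paint(iv, config.peak_enrichment_fold)
            visible.append(iv)
            all_footprints[iv.name] = iv

        clusters = shared + (specific if group == TREATMENT_GROUP else [])
        for cluster in clusters:
            for iv in cluster:
                paint(iv, config.se_enrichment_fold)
                visible.append(iv)
                all_footprints[iv.name] = iv

        chip_runs, input_runs = {}, {}
        for chrom, size in annotation.chrom_sizes.items():
            n_runs = size // run
            starts = np.arange(n_runs, dtype=np.int64) * run
            ends = starts + run
            depth = rng.poisson(lam[chrom] * lib[ai] * run) / run
            keep = depth > 0
            chip_runs[chrom] = (starts[keep], ends[keep], depth[keep])
            d_in = rng.poisson(
                np.full(n_runs, config.background_depth) * lib[ai] * run
            ) / run
            keep = d_in > 0
            input_runs[chrom] = (starts[keep], ends[keep], d_in[keep])
        chip_tracks[animal] = CoverageTrack(chip_runs)
        input_tracks[animal] = CoverageTrack(input_runs)
        peaks_by_animal[animal] = PeakSet(visible)

    consensus = PeakSet(all_footprints.values())
    return ChipSim(peaks_by_animal, chip_tracks, input_tracks, consensus, truth)


def simulate_rna(annotation: GenomeAnnotation, config: SimConfig,
                 truth: SimTruth | None = None,
                 rng: np.random.Generator | None = None) -> CountMatrix:
    """Negative-binomial gene counts for the 3-vs-3 design.

    Differential genes are shifted by ``effect_log2fc`` in the treatment
    group; genes linked to a peak share that peak's per-animal latent
    factor so the peak-gene Pearson correlation is planted.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = truth if truth is not None else SimTruth()
    animals = config.animals
    groups = config.animal_groups
    gids = [g.gene_id for g in annotation]
    lib = np.exp(rng.normal(0.0, config.library_sd_log, size=len(animals)))
    # decades-wide per-gene baseline, as in real expression data; shared
    # across samples, so intra-group sample correlations are realistically high
    base = config.mean_count * np.exp(rng.normal(0.0, 1.0, size=len(gids)))

    mean = np.outer(base, lib)
    linked = set(truth.gene_latent.index) if truth.gene_latent is not None else set()
    for i, gid in enumerate(gids):
        for j, animal in enumerate(animals):
            m = 1.0
            if gid in linked:
                # total planted shift (group effect folded in via the peak)
                m *= 2.0 ** truth.gene_latent.loc[gid, animal]
            else:
                eff = truth.diff_gene_effects.get(gid, 0.0)
                if eff != 0.0 and groups[animal] == TREATMENT_GROUP:
                    m *= 2.0 ** eff
            mean[i, j] *= m

    counts = nb_counts(rng, mean, config.nb_dispersion)
    frame = pd.DataFrame(counts, index=gids, columns=animals)
    return CountMatrix(frame, groups)


def nb_counts(rng: np.random.Generator, mean: np.ndarray,
              dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion alpha (var = m + a m^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_qpcr(truth: SimTruth, config: SimConfig,
                  rng: np.random.Generator | None = None,
                  genes: Iterable[str] | None = None,
                  ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Ct table for ChIP-qPCR/RT-PCR-style validation of planted effects.

    Constructed so that the 2^-ddCt fold of the treatment group recovers
    the planted fold ``2**effect`` up to Gaussian Ct noise.  Returns the
    long-format record table and the planted fold per gene.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if genes is None:
        genes = sorted(truth.diff_gene_effects)
    genes = list(genes)
    animals = config.animals
    groups = config.animal_groups
    rows = []
    planted: dict[str, float] = {}
    for gid in genes:
        fold = 2.0 ** truth.diff_gene_effects.get(gid, 0.0)
        planted[gid] = fold
        baseline = float(rng.uniform(2.0, 6.0))
        for animal in animals:
            ct_ref = 20.0 + float(rng.normal(0.0, config.ct_noise_sd))
            dct = baseline + float(rng.normal(0.0, config.ct_noise_sd))
            if groups[animal] == TREATMENT_GROUP:
                dct -= np.log2(fold)
            rows.append(
                {
                    "sample": animal,
                    "group": groups[animal],
                    "target": gid,
                    "ct_target": ct_ref + dct,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows), planted


@dataclass
class SyntheticDataset:
    """A complete simulated study: annotation, ChIP, RNA, qPCR, truth."""

    config: SimConfig
    annotation: GenomeAnnotation
    chip: ChipSim
    rna: CountMatrix
    qpcr: pd.DataFrame
    qpcr_folds: dict[str, float]

    @property
    def truth(self) -> SimTruth:
        return self.chip.truth


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate the full dataset from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    annotation = simulate_genome(config, rng)
    chip = simulate_chip(annotation, config, rng)
    rna = simulate_rna(annotation, config, chip.truth, rng)
    qpcr, folds = simulate_qpcr(chip.truth, config, rng)
    return SyntheticDataset(config, annotation, chip, rna, qpcr, folds)
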