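"""End-to-end orchestration: one config file in, a bundle of tables out.

``run_all`` drives the full integrative analysis — RNA differential
expression, consensus-peak differential acetylation, the four-way
peak-gene classification, per-sample super-enhancer calling with
group-wise differential SEs, metaprofiles and sample correlations, and
(optionally) qPCR folds and cross-species DEG intersection — writing
tab-separated tables plus a reproducibility manifest.  ``make_fixture``
writes a complete synthetic dataset in the exact on-disk formats the
pipeline reads.

Sample correspondence: ChIP and RNA samples of the same group are matched
by their order in the sample sheet (the study profiled the same animals
with both assays), which is what the peak-gene correlation requires.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cross_species, fourway, profiles, superenhancer, validation
from .differential import Thresholds, call_features, nb_test
from .genomic_io import (
    CountMatrix,
    read_bed,
    read_bedgraph,
    read_counts_tsv,
    read_gtf_genes,
    read_sample_sheet,
)
from .quantification import (
    filter_low_expression,
    fpkm,
    merge_intervals,
    quantify_samples,
    size_factors_median_of_ratios,
)
from .synthetic import SimConfig, SyntheticDataset, simulate_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds of one full run (loadable from YAML)."""

    annotation: str
    sample_sheet: str
    rna_counts: str
    peaks: dict[str, str] = field(default_factory=dict)     # chip sample -> BED
    coverage: dict[str, str] = field(default_factory=dict)  # sample -> bedGraph
    qpcr: str | None = None
    deg_tables: dict[str, str] = field(default_factory=dict)
    orthologs: str | None = None
    gene_lfc: float = 1.0
    gene_p: float = 0.05
    peak_lfc: float = 1.0
    peak_p: float = 0.05
    se_lfc: float = 0.6
    se_p: float = 0.05
    cor_threshold: float = 0.5
    stitch_distance: int = 12_500
    tss_exclude: int = 2_500
    max_link_distance: int = 50_000
    control_group: str = "CTR"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_fixture(config: SimConfig, outdir: str | Path) -> SyntheticDataset:
    """Simulate a dataset and write every input file plus truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)

    _write_gtf(ds, outdir / "annotation.gtf")
    sheet_rows = []
    peaks_map, coverage_map = {}, {}
    for animal in config.animals:
        group = config.animal_groups[animal]
        chip_id, input_id, rna_id = (
            f"chip_{animal}", f"input_{animal}", f"rna_{animal}"
        )
        ds.chip.peaks[animal].write_bed(outdir / f"peaks_{chip_id}.bed")
        ds.chip.chip_tracks[animal].write_bedgraph(outdir / f"{chip_id}.bedGraph")
        ds.chip.input_tracks[animal].write_bedgraph(outdir / f"{input_id}.bedGraph")
        peaks_map[chip_id] = f"peaks_{chip_id}.bed"
        coverage_map[chip_id] = f"{chip_id}.bedGraph"
        coverage_map[input_id] = f"{input_id}.bedGraph"
        sheet_rows += [
            {"sample_id": chip_id, "group": group, "assay": "chip"},
            {"sample_id": input_id, "group": group, "assay": "input"},
            {"sample_id": rna_id, "group": group, "assay": "rna"},
        ]
    pd.DataFrame(sheet_rows).to_csv(outdir / "sample_sheet.tsv", sep="\t",
                                    index=False)
    rna = ds.rna.counts.copy()
    rna.columns = [f"rna_{a}" for a in rna.columns]
    rna.index.name = "gene_id"
    rna.to_csv(outdir / "rna_counts.tsv", sep="\t")
    ds.qpcr.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    ds.truth.to_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    run_cfg = PipelineConfig(
        annotation="annotation.gtf",
        sample_sheet="sample_sheet.tsv",
        rna_counts="rna_counts.tsv",
        peaks=peaks_map,
        coverage=coverage_map,
        qpcr="qpcr_ct.tsv",
        seed=config.seed,
    )
    run_cfg.to_yaml(outdir / "pipeline.yaml")
    return ds


def _write_gtf(ds: SyntheticDataset, path: Path) -> None:
    with open(path, "w") as fh:
        for g in ds.annotation:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            for feature in ("gene", "exon"):
                fh.write(
                    f"{g.chrom}\tsim\t{feature}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str | None = "feature"
               ) -> None:
    frame.to_csv(path, sep="\t", index=index_label is not None,
                 index_label=index_label, float_format="%.6g")


def run_all(config: PipelineConfig, outdir: str | Path,
            base_dir: str | Path | None = None) -> dict:
    """Run every stage; returns the manifest.  Relative paths in the config
    resolve against ``base_dir`` (default: the current directory)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(".")
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {},
    }
    written: list[Path] = []

    def resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    def emit(name: str, frame: pd.DataFrame, index_label: str | None = "feature"
             ) -> None:
        path = outdir / name
        _write_tsv(frame, path, index_label)
        written.append(path)
        manifest["outputs"][name] = int(frame.shape[0])

    stage = "load-inputs"
    try:
        annotation = read_gtf_genes(resolve(config.annotation))
        sheet = read_sample_sheet(resolve(config.sample_sheet))
        rna_sheet = sheet[sheet["assay"] == "rna"]
        rna = read_counts_tsv(resolve(config.rna_counts), rna_sheet)
        chip_sheet = sheet[sheet["assay"] == "chip"]
        input_sheet = sheet[sheet["assay"] == "input"]
        chip_groups = dict(zip(chip_sheet["sample_id"], chip_sheet["group"]))
        for s in list(chip_sheet["sample_id"]) + list(input_sheet["sample_id"]):
            if s not in config.coverage:
                raise FileNotFoundError(f"no coverage file configured for {s}")
        chip_tracks = {
            s: read_bedgraph(resolve(config.coverage[s]))
            for s in chip_sheet["sample_id"]
        }
        input_tracks = {
            s: read_bedgraph(resolve(config.coverage[s]))
            for s in input_sheet["sample_id"]
        }
        peak_sets = {
            s: read_bed(resolve(config.peaks[s])) for s in chip_sheet["sample_id"]
        }
        # align chip / input / rna samples animal-wise: order within group
        input_of_chip = _match_by_group(chip_sheet, input_sheet)
        rna_of_chip = _match_by_group(chip_sheet, rna_sheet)

        stage = "rna-differential"
        rna_kept, dropped = filter_low_expression(rna)
        gene_sf = size_factors_median_of_ratios(rna_kept)
        lengths = pd.Series({g.gene_id: g.length_bp for g in annotation})
        gene_fpkm = fpkm(rna_kept, lengths.reindex(rna_kept.counts.index))
        gene_res = nb_test(rna_kept, gene_sf, reference_group=config.control_group)
        gene_res["call"] = call_features(
            gene_res, Thresholds(config.gene_lfc, config.gene_p)
        )
        emit("genes_differential.tsv", gene_res, "gene_id")
        emit("genes_fpkm.tsv", gene_fpkm, "gene_id")

        stage = "peak-differential"
        consensus = merge_intervals(list(peak_sets.values()))
        peak_matrix = quantify_samples(consensus, chip_tracks, chip_groups)
        peak_sf = size_factors_median_of_ratios(peak_matrix)
        peak_res = nb_test(peak_matrix, peak_sf,
                           reference_group=config.control_group)
        peak_res["call"] = call_features(
            peak_res, Thresholds(config.peak_lfc, config.peak_p)
        )
        peak_out = pd.concat([peak_matrix.feature_meta, peak_res], axis=1)
        emit("peaks_differential.tsv", peak_out, "peak")

        stage = "fourway"
        links = fourway.assign_peaks_to_genes(
            consensus, annotation, config.max_link_distance
        )
        norm_signal = peak_matrix.counts.div(peak_sf, axis=1)
        chip_order = list(chip_sheet["sample_id"])
        expr = gene_fpkm[[rna_of_chip[s] for s in chip_order]]
        expr.columns = chip_order
        diff_peaks = set(peak_res.index[peak_res["call"] != "ns"])
        link_table, quadrant_counts = fourway.fourway_table(
            links, norm_signal[chip_order], expr, gene_res,
            diff_peak_ids=diff_peaks, cor_threshold=config.cor_threshold,
            lfc_threshold=config.gene_lfc,
        )
        emit("fourway_links.tsv", link_table, None)
        manifest["quadrant_counts"] = quadrant_counts

        stage = "superenhancer"
        se_calls = {}
        se_counts = {}
        for s in chip_order:
            calls = superenhancer.identify_superenhancers(
                peak_sets[s], annotation, chip_tracks[s],
                input_tracks[input_of_chip[s]],
                config.stitch_distance, config.tss_exclude,
            )
            se_calls[s] = calls
            se_counts[s] = sum(c.is_super for c in calls)
            emit(f"se_{s}.tsv", superenhancer.se_table(calls), None)
        manifest["se_counts"] = se_counts

        stage = "differential-se"
        se_res, se_matrix = superenhancer.differential_se(
            se_calls, chip_groups, chip_tracks,
            Thresholds(config.se_lfc, config.se_p), size_factors=peak_sf,
        )
        se_out = pd.concat([se_matrix.feature_meta, se_res], axis=1)
        emit("se_differential.tsv", se_out, "region")
        se_regions = [
            superenhancer.SECall(
                superenhancer.StitchedEnhancer(iv), 0.0, i + 1, True
            )
            for i, iv in enumerate(
                _meta_to_intervals(se_matrix.feature_meta)
            )
        ]
        emit("se_genes.tsv",
             superenhancer.annotate_se_genes(se_regions, annotation), None)

        stage = "profiles"
        tss_profiles = {}
        for s in chip_order:
            meta = profiles.scale_regions_matrix(chip_tracks[s], annotation)
            tss_profiles[s] = profiles.mean_profile(meta)
        emit("metaprofile_scaled.tsv", pd.DataFrame(tss_profiles), "bin")
        emit("sample_correlation_chip.tsv",
             profiles.sample_correlation(peak_matrix), "sample")
        emit("sample_correlation_rna.tsv",
             profiles.sample_correlation(rna_kept), "sample")

        if config.qpcr:
            stage = "qpcr"
            records = pd.read_csv(resolve(config.qpcr), sep="\t")
            folds = validation.ddct_fold(records, config.control_group)
            emit("qpcr_folds.tsv", folds, None)
            emit("qpcr_summary.tsv",
                 validation.qpcr_summary(folds, config.control_group), None)

        if config.deg_tables:
            stage = "cross-species"
            ortho = (
                pd.read_csv(resolve(config.orthologs), sep="\t")
                if config.orthologs else None
            )
            sets = [
                cross_species.normalize_symbols(
                    pd.read_csv(resolve(p), sep="\t"), species, ortho
                )
                for species, p in config.deg_tables.items()
            ]
            core, regions, table = cross_species.intersect_degs(sets)
            emit("cross_species_core.tsv", table, None)
            manifest["venn_regions"] = regions
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for path in written:
            if path.exists():
                shutil.move(str(path), failed / path.name)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _match_by_group(left: pd.DataFrame, right: pd.DataFrame) -> dict[str, str]:
    """Pair sample ids of two assays by order within each group."""
    out: dict[str, str] = {}
    for group in left["group"].unique():
        l = list(left.loc[left["group"] == group, "sample_id"])
        r = list(right.loc[right["group"] == group, "sample_id"])
        if len(l) != len(r):
            raise ValueError(
                f"group {group}: {len(l)} vs {len(r)} samples across assays"
            )
        out.update(zip(l, r))
    return out


def _meta_to_intervals(meta: pd.DataFrame):
    from .genomic_io import GenomicInterval

    return [
        GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]),
                        name=str(idx))
        for idx, row in meta.iterrows()
    ]
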