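"""Readers, writers and in-memory containers for the genomic formats the
pipeline touches: BED/narrowPeak peak calls, bedGraph coverage, GTF gene
annotation, and tab-separated count matrices with a sample sheet.

All internal coordinates are 0-based half-open (BED convention).  GTF input
is 1-based inclusive and is shifted at the boundary: start − 1, end kept.
Chromosome names are passed through verbatim — no "chr" normalization; a
mismatch between a track and an annotation surfaces as zero coverage or an
explicit error downstream, never as a silent rename.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


class FormatError(ValueError):
    """Malformed input file (carries the offending line number)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def __str__(self) -> str:  # 1-based inclusive display, as in reports
        return f"{self.chrom}:{self.start + 1}-{self.end}"


class PeakSet:
    """An ordered collection of peaks, sorted by (chrom, start, end).

    narrowPeak extra columns (signalValue, pValue, qValue, summit) are kept
    in ``extra`` keyed by peak name but take no part in any computation here
    (peak calling is upstream).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        extra: Mapping[str, tuple] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self.extra = dict(extra) if extra else {}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PeakSet) and self.intervals == other.intervals

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                    f"{iv.score:g}\t{iv.strand}\n"
                )


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and exon-union length.

    ``tss``/``tes`` are single 0-based positions: the 5' and 3' termini in
    transcription order, so on the minus strand tss > tes in genomic
    coordinates.  ``start``/``end`` delimit the gene body half-open.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id}: invalid body coordinates")
        if self.length_bp <= 0:
            raise ValueError(f"gene {self.gene_id}: length_bp must be > 0")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class GenomeAnnotation:
    """A set of gene models plus chromosome sizes."""

    def __init__(
        self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]
    ) -> None:
        self.genes: list[GeneModel] = sorted(
            genes, key=lambda g: (g.chrom, g.start, g.gene_id)
        )
        self.chrom_sizes = dict(chrom_sizes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chrom} ({size})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def tss_positions(self) -> pd.DataFrame:
        """All TSS as a frame with columns chrom, pos, strand, gene_id."""
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "pos": [g.tss for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "gene_id": [g.gene_id for g in self.genes],
            }
        )


class CoverageTrack:
    """Piecewise-constant per-base depth (bedGraph semantics).

    Runs are stored per chromosome as parallel numpy arrays (starts, ends,
    depths), sorted and non-overlapping.  Gaps mean depth 0.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> None:
        self.runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, depths) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            depths = np.asarray(depths, dtype=np.float64)
            if not (len(starts) == len(ends) == len(depths)):
                raise ValueError(f"{chrom}: run arrays have unequal length")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: zero- or negative-length run")
            if np.any(depths < 0):
                raise ValueError(f"{chrom}: negative depth")
            order = np.argsort(starts, kind="stable")
            starts, ends, depths = starts[order], ends[order], depths[order]
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"{chrom}: overlapping runs")
            self.runs[chrom] = (starts, ends, depths)

    def chroms(self) -> list[str]:
        return list(self.runs)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end) — bedcov semantics."""
        return self.interval_integral(chrom, float(start), float(end))

    def interval_integral(self, chrom: str, start: float, end: float) -> float:
        """Integral of depth over a real-valued window (for fractional bins)."""
        if chrom not in self.runs or end <= start:
            return 0.0
        starts, ends, depths = self.runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * depths[lo:hi]))

    def mean_depth(self, chrom: str, start: float, end: float) -> float:
        if end <= start:
            return 0.0
        return self.interval_integral(chrom, start, end) / (end - start)

    def bin_means(
        self, chrom: str, edges: np.ndarray
    ) -> np.ndarray:
        """Mean depth in each window delimited by consecutive ``edges``."""
        out = np.empty(len(edges) - 1)
        for i in range(len(edges) - 1):
            out[i] = self.mean_depth(chrom, edges[i], edges[i + 1])
        return out

    def __add__(self, other: "CoverageTrack") -> "CoverageTrack":
        """Sum of two tracks, resolved on the union of run boundaries."""
        merged: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in sorted(set(self.runs) | set(other.runs)):
            cuts: set[float] = set()
            for trk in (self, other):
                if chrom in trk.runs:
                    s, e, _ = trk.runs[chrom]
                    cuts.update(s.tolist())
                    cuts.update(e.tolist())
            edges = np.array(sorted(cuts), dtype=np.int64)
            starts, ends, depths = [], [], []
            for a, b in zip(edges[:-1], edges[1:]):
                d = self.mean_depth(chrom, a, b) + other.mean_depth(chrom, a, b)
                if d > 0:
                    starts.append(a)
                    ends.append(b)
                    depths.append(d)
            merged[chrom] = (
                np.array(starts, dtype=np.int64),
                np.array(ends, dtype=np.int64),
                np.array(depths),
            )
        return CoverageTrack(merged)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if set(self.runs) != set(other.runs):
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self.runs[c], other.runs[c]))
            for c in self.runs
        )

    def write_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.runs):
                starts, ends, depths = self.runs[chrom]
                for s, e, d in zip(starts, ends, depths):
                    fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


class CountMatrix:
    """Features × samples non-negative counts with group labels.

    ``counts`` is a pandas DataFrame (index = feature ids, columns = sample
    ids); ``groups`` maps each sample to its group label; ``feature_meta``
    optionally carries intervals or gene models aligned to the index.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        groups: Mapping[str, str],
        feature_meta: pd.DataFrame | None = None,
    ) -> None:
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = [s for s in counts.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.counts = counts
        self.groups = pd.Series({s: groups[s] for s in counts.columns})
        if feature_meta is not None and not feature_meta.index.equals(counts.index):
            raise ValueError("feature_meta index does not match counts index")
        self.feature_meta = feature_meta

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, group: str) -> list[str]:
        return list(self.groups[self.groups == group].index)

    def require_two_groups(self) -> tuple[str, str]:
        """The (reference, treatment) pair, in sample-sheet order."""
        levels = list(dict.fromkeys(self.groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly 2 groups, got {levels}")
        for g in levels:
            if len(self.group_samples(g)) < 2:
                raise ValueError(f"group {g} has < 2 samples")
        return levels[0], levels[1]

    def subset(self, feature_ids: Sequence[str]) -> "CountMatrix":
        meta = (
            self.feature_meta.loc[list(feature_ids)]
            if self.feature_meta is not None
            else None
        )
        return CountMatrix(self.counts.loc[list(feature_ids)], self.groups, meta)

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# readers


def read_bed(path: str | Path) -> PeakSet:
    """Read BED3/BED6 or narrowPeak into a :class:`PeakSet`.

    narrowPeak columns 7–10 are preserved in ``PeakSet.extra`` keyed by peak
    name.  Raises :class:`FormatError` naming the line for malformed rows or
    start >= end.
    """
    intervals: list[GenomicInterval] = []
    extra: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            score = 0.0
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) > 6 and name:
                extra[name] = tuple(fields[6:])
    return PeakSet(intervals, extra)


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> GenomeAnnotation:
    """Read gene models from an Ensembl-dialect GTF.

    Gene body comes from ``gene`` features; ``length_bp`` is the union of
    that gene's exon features (falling back to the body span for genes with
    no exon rows).  GTF 1-based inclusive coordinates become 0-based
    half-open: start − 1, end unchanged.  When ``chrom_sizes`` is absent,
    sizes are inferred as the maximal annotated end per chromosome.
    """
    bodies: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = fields
            if feature not in ("gene", "exon"):
                continue
            attrd = dict(_GTF_ATTR.findall(attrs))
            gene_id = attrd.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            start, end = int(start1) - 1, int(end1)
            if feature == "gene":
                bodies[gene_id] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "symbol": attrd.get("gene_name", gene_id),
                }
            else:
                exons.setdefault(gene_id, []).append((start, end))
    genes = []
    for gid, b in bodies.items():
        length = _union_length(exons.get(gid, [(b["start"], b["end"])]))
        genes.append(
            GeneModel(
                gene_id=gid,
                symbol=b["symbol"],
                chrom=b["chrom"],
                strand=b["strand"],
                start=b["start"],
                end=b["end"],
                length_bp=length,
            )
        )
    if chrom_sizes is None:
        chrom_sizes = {}
        for g in genes:
            chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes, chrom_sizes)


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a CoverageTrack."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, depth = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            per_chrom.setdefault(fields[0], []).append((start, end, depth))
    runs = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        arr = np.array(rows, dtype=object)
        runs[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=np.float64),
        )
    try:
        return CoverageTrack(runs)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Tab-separated sample sheet: sample_id, group, assay in {chip,input,rna}."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "assay"}
    if not required.issubset(sheet.columns):
        raise FormatError(
            f"{path}: sample sheet needs columns {sorted(required)}"
        )
    bad = set(sheet["assay"]) - {"chip", "input", "rna"}
    if bad:
        raise FormatError(f"{path}: unknown assay values {sorted(bad)}")
    return sheet


def read_counts_tsv(path: str | Path, sample_sheet: pd.DataFrame) -> CountMatrix:
    """Read a feature × sample count table and attach sample-sheet groups.

    Samples are reordered to sample-sheet order; a sheet sample missing from
    the table is an error.  Non-numeric cells and duplicate feature ids are
    rejected with the offending location.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s) {dup}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        rows, cols = np.nonzero(numeric.isna().to_numpy())
        loc = (raw.index[rows[0]], raw.columns[cols[0]])
        raise FormatError(
            f"{path}: non-numeric value at feature {loc[0]!r}, sample {loc[1]!r}"
        )
    wanted = list(sample_sheet["sample_id"])
    missing = [s for s in wanted if s not in numeric.columns]
    if missing:
        raise FormatError(f"{path}: sheet sample(s) missing from matrix: {missing}")
    groups = dict(zip(sample_sheet["sample_id"], sample_sheet["group"]))
    return CountMatrix(numeric[wanted], groups)
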