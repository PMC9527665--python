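"""Readers and writers for every file the pipeline touches.

The central on-disk format is the edit-site table emitted by an RNA-editing
caller: one row per called site per sample, carrying the genomic location,
the edit type (e.g. A>G on +, T>C on -), and the edited/total read counts
from which the per-site edit/read ratio is derived.  Interval annotations
(Alu repeats, gene features) use BED conventions on disk (0-based half-open)
and 1-based inclusive coordinates in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "EditSite",
    "SiteKey",
    "SampleEditTable",
    "FeatureIntervals",
    "EditTableParseError",
    "FEATURE_CLASSES",
    "read_edit_table",
    "write_edit_table",
    "read_feature_intervals",
    "read_count_matrix",
    "read_marker_table",
    "MarkerRecord",
    "write_results",
    "bed_interval_to_internal",
    "internal_interval_to_bed",
]

#: Gene feature classes recognised by the annotation step.  "intergenic" is
#: not listed because it is the absence of any feature, never stored on disk.
FEATURE_CLASSES = ("intron", "5UTR", "3UTR", "ncRNA")

_NUCLEOTIDES = frozenset("ACGT")


class EditTableParseError(ValueError):
    """Malformed edit-site table row; message names the offending line."""


class SiteKey(NamedTuple):
    """Identity of one editing site; orders by (chrom, pos, strand)."""

    chrom: str
    pos: int  # 1-based
    strand: str
    edit_type: str  # two letters, reference then edited base, e.g. "AG"


@dataclass(frozen=True)
class EditSite:
    """One called editing event at a genomic position in one sample."""

    chrom: str
    pos: int
    strand: str
    edit_type: str
    edits: int
    reads: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if (
            len(self.edit_type) != 2
            or not set(self.edit_type) <= _NUCLEOTIDES
            or self.edit_type[0] == self.edit_type[1]
        ):
            raise ValueError(f"invalid edit type {self.edit_type!r}")
        if self.reads < 1:
            raise ValueError(f"total reads must be positive, got {self.reads}")
        if not 0 <= self.edits <= self.reads:
            raise ValueError(
                f"edits ({self.edits}) must lie in [0, reads={self.reads}]"
            )

    @property
    def ratio(self) -> float:
        """Edit/read ratio at this site in this sample, in [0, 1]."""
        return self.edits / self.reads

    @property
    def key(self) -> SiteKey:
        return SiteKey(self.chrom, self.pos, self.strand, self.edit_type)


@dataclass
class SampleEditTable:
    """All edit sites called in one sample, keyed by site identity."""

    sample_id: str
    cohort_label: str
    sites: dict[SiteKey, EditSite] = field(default_factory=dict)

    def add(self, site: EditSite) -> None:
        if site.key in self.sites:
            raise ValueError(f"duplicate site {site.key} in sample {self.sample_id}")
        self.sites[site.key] = site

    def __len__(self) -> int:
        return len(self.sites)


def bed_interval_to_internal(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [first, last]."""
    if start >= end:
        raise ValueError(f"empty interval: start {start} >= end {end}")
    return start + 1, end


def internal_interval_to_bed(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive [first, last] -> 0-based half-open [start, end)."""
    if first > last:
        raise ValueError(f"empty interval: first {first} > last {last}")
    return first - 1, last


def _normalize_chrom(name: str) -> str:
    return name if name.startswith("chr") else f"chr{name}"


class FeatureIntervals:
    """Indexed interval store for gene features and repeat elements.

    Point queries use 1-based positions; the underlying trees keep BED
    coordinates so that IntervalTree's half-open semantics apply directly.
    """

    def __init__(self) -> None:
        self._genes: dict[str, IntervalTree] = {}
        self._repeats: dict[str, IntervalTree] = {}

    def add_gene_feature(
        self,
        chrom: str,
        start: int,
        end: int,
        gene_id: str,
        feature_class: str,
        strand: str = "+",
    ) -> None:
        if feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {feature_class!r}")
        if start >= end:
            raise ValueError(f"gene feature with start {start} >= end {end}")
        self._genes.setdefault(chrom, IntervalTree())[start:end] = (
            gene_id,
            feature_class,
            strand,
        )

    def add_repeat(
        self,
        chrom: str,
        start: int,
        end: int,
        repeat_name: str,
        repeat_family: str,
        strand: str = "+",
    ) -> None:
        if start >= end:
            raise ValueError(f"repeat with start {start} >= end {end}")
        self._repeats.setdefault(chrom, IntervalTree())[start:end] = (
            repeat_name,
            repeat_family,
            strand,
        )

    def gene_features_at(
        self, chrom: str, pos: int
    ) -> list[tuple[str, str, str, int]]:
        """Gene features covering 1-based ``pos``.

        Returns (gene_id, feature_class, strand, interval_start_1based)
        tuples; the start is exposed so overlap ties can be broken by
        proximity.
        """
        tree = self._genes.get(chrom)
        if tree is None:
            return []
        return [
            (iv.data[0], iv.data[1], iv.data[2], iv.begin + 1)
            for iv in tree.at(pos - 1)
        ]

    def repeats_at(self, chrom: str, pos: int) -> list[tuple[str, str, str]]:
        """(repeat_name, repeat_family, strand) tuples covering ``pos``."""
        tree = self._repeats.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos - 1)]

    @property
    def n_gene_features(self) -> int:
        return sum(len(t) for t in self._genes.values())

    @property
    def n_repeats(self) -> int:
        return sum(len(t) for t in self._repeats.values())


def _split_row(line: str) -> list[str]:
    line = line.rstrip("\n")
    return line.split("\t") if "\t" in line else line.split()


def read_edit_table(
    path: str | Path,
    sample_id: str,
    cohort_label: str,
    normalize_chroms: bool = False,
) -> SampleEditTable:
    """Parse one caller edit-site table.

    The dialect is six columns: chrom, start (0-based), end (1-based,
    start+1), edit type as two letters, strand, and "edits:reads".  Lines
    starting with ``#`` are headers/comments.  Any malformed row aborts the
    parse with the line number; duplicate sites are rejected.
    """
    table = SampleEditTable(sample_id=sample_id, cohort_label=cohort_label)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) != 6:
                raise EditTableParseError(
                    f"{path}:{lineno}: expected 6 columns, found {len(fields)}"
                )
            chrom, start_s, end_s, edit_type, strand, counts = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise EditTableParseError(
                    f"{path}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if end != start + 1:
                raise EditTableParseError(
                    f"{path}:{lineno}: a site spans one base; end must be start+1"
                )
            if ":" not in counts:
                raise EditTableParseError(
                    f"{path}:{lineno}: counts field must be 'edits:reads'"
                )
            edits_s, _, reads_s = counts.partition(":")
            try:
                edits, reads = int(edits_s), int(reads_s)
            except ValueError:
                raise EditTableParseError(
                    f"{path}:{lineno}: non-integer counts {counts!r}"
                ) from None
            if normalize_chroms:
                chrom = _normalize_chrom(chrom)
            try:
                site = EditSite(
                    chrom=chrom,
                    pos=start + 1,
                    strand=strand,
                    edit_type=edit_type,
                    edits=edits,
                    reads=reads,
                )
                table.add(site)
            except ValueError as exc:
                raise EditTableParseError(f"{path}:{lineno}: {exc}") from None
    return table


def write_edit_table(table: SampleEditTable, path: str | Path) -> None:
    """Write a sample table back out in the caller dialect (sorted by site)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tedit_type\tstrand\tedits:reads\n")
        for key in sorted(table.sites):
            s = table.sites[key]
            fh.write(
                f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{s.edit_type}\t{s.strand}"
                f"\t{s.edits}:{s.reads}\n"
            )


def read_feature_intervals(
    gene_path: str | Path | None,
    repeat_path: str | Path | None,
    normalize_chroms: bool = False,
) -> FeatureIntervals:
    """Load gene-feature and repeat BED files into an indexed store.

    Gene features are BED6-like with ``gene_id|feature_class`` in the name
    column; repeats are BED6-like with the repeat name in column 4 and the
    repeat family (e.g. ``Alu``) in column 5.  Either path may be None,
    yielding an empty partition.
    """
    store = FeatureIntervals()
    if gene_path is not None:
        for lineno, fields in _iter_bed_rows(gene_path):
            chrom, start, end, name, _score, strand = fields
            if "|" not in name:
                raise ValueError(
                    f"{gene_path}:{lineno}: name must be 'gene_id|feature_class'"
                )
            gene_id, _, feature_class = name.rpartition("|")
            if normalize_chroms:
                chrom = _normalize_chrom(chrom)
            try:
                store.add_gene_feature(chrom, start, end, gene_id, feature_class, strand)
            except ValueError as exc:
                raise ValueError(f"{gene_path}:{lineno}: {exc}") from None
    if repeat_path is not None:
        for lineno, fields in _iter_bed_rows(repeat_path):
            chrom, start, end, name, family, strand = fields
            if normalize_chroms:
                chrom = _normalize_chrom(chrom)
            try:
                store.add_repeat(chrom, start, end, name, family, strand)
            except ValueError as exc:
                raise ValueError(f"{repeat_path}:{lineno}: {exc}") from None
    return store


def _iter_bed_rows(path: str | Path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = _split_row(line)
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            yield lineno, (fields[0], start, end, fields[3], fields[4], fields[5])


def read_count_matrix(
    path: str | Path, cohort_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a gene x sample count matrix (TSV, first column gene ids).

    When ``cohort_map`` is given, every sample it names must be a column of
    the matrix; a missing sample is an error rather than a silent drop.
    Negative counts are rejected.
    """
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if (mat.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts are not allowed")
    if cohort_map is not None:
        missing = sorted(set(cohort_map) - set(mat.columns))
        if missing:
            raise ValueError(
                f"{path}: samples in cohort map absent from matrix: {missing}"
            )
    return mat


class MarkerRecord(NamedTuple):
    """Per-gene, per-cluster single-cell detection percentages."""

    gene_id: str
    cluster: str
    pct1: float  # fraction of cells in the cluster expressing the gene
    pct2: float  # fraction of cells in all other clusters expressing it


def read_marker_table(path: str | Path) -> list[MarkerRecord]:
    """Read a marker CSV with columns gene, cluster, pct1, pct2."""
    df = pd.read_csv(path)
    required = {"gene", "cluster", "pct1", "pct2"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: marker table needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        pct1, pct2 = float(row.pct1), float(row.pct2)
        for label, val in (("pct1", pct1), ("pct2", pct2)):
            if not (0.0 <= val <= 1.0) or math.isnan(val):
                raise ValueError(
                    f"{path}: {label}={val} outside [0,1] for gene {row.gene}"
                )
        records.append(MarkerRecord(str(row.gene), str(row.cluster), pct1, pct2))
    return records


def write_results(records: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write analysis records as TSV with stable column order."""
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False)
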