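"""Readers and writers for the pipeline's external formats.

All coordinates are 0-based, half-open past the reader boundary (BED
convention).  Inputs written in a 1-based, fully-closed dialect can be
converted on read via :class:`TableDialect` (``one_based=True`` subtracts
one from start coordinates).

The transcription start site (TSS) of a gene is the strand-aware first
transcribed base: ``start`` for ``+`` genes, ``end - 1`` for ``-`` genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "ValidationError",
    "TableDialect",
    "GeneModel",
    "HotspotInterval",
    "HotspotTrack",
    "StateElement",
    "CpRecord",
    "read_gene_models",
    "read_hotspots",
    "read_expression_table",
    "read_segmentation",
    "read_cp_table",
    "write_gene_models",
    "write_hotspots",
    "write_segmentation",
    "write_expression_table",
    "write_cp_table",
    "write_table",
]


class FormatError(ValueError):
    """The file does not match the expected layout (missing/bad columns)."""


class ValidationError(ValueError):
    """The file parsed but one or more records violate an invariant."""


@dataclass(frozen=True)
class TableDialect:
    """How to interpret a delimited text file.

    ``header`` may be True, False or "auto" (sniff: a first line whose
    coordinate fields are non-numeric is treated as a header).
    ``one_based`` converts 1-based fully-closed input coordinates to the
    internal 0-based half-open convention on read.
    """

    delimiter: str = "\t"
    header: bool | str = "auto"
    one_based: bool = False


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand and identifier (TSS anchor source)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (single bp)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HotspotInterval:
    """A scored ChIP enrichment interval, as emitted by a hotspot caller."""

    chrom: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"hotspot {self.chrom}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if not (self.score >= 0):
            raise ValidationError(f"hotspot {self.chrom}:{self.start}: score must be >= 0")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class HotspotTrack:
    """Scored enrichment intervals for one mark, indexed by chromosome.

    Intervals are kept sorted by (chrom, start); overlaps are permitted and
    preserved.  Interval trees are built lazily per chromosome for overlap
    queries.
    """

    def __init__(self, intervals: Iterable[HotspotInterval] = ()) -> None:
        by_chrom: dict[str, list[HotspotInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda iv: (iv.start, iv.end))
        self._by_chrom = dict(sorted(by_chrom.items()))
        self._trees: dict[str, IntervalTree] = {}
        self._midpoints: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __iter__(self) -> Iterator[HotspotInterval]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def intervals(self, chrom: str) -> Sequence[HotspotInterval]:
        return self._by_chrom.get(chrom, ())

    def _tree(self, chrom: str) -> IntervalTree:
        # data payload is the list index, not the interval itself: identical
        # duplicate intervals must survive the tree's set semantics
        if chrom not in self._trees:
            self._trees[chrom] = IntervalTree.from_tuples(
                (iv.start, iv.end, i) for i, iv in enumerate(self._by_chrom.get(chrom, ()))
            )
        return self._trees[chrom]

    def overlapping(self, chrom: str, start: int, end: int) -> list[HotspotInterval]:
        """Intervals with >= 1 bp intersection with [start, end)."""
        if chrom not in self._by_chrom or start >= end:
            return []
        ivs = self._by_chrom[chrom]
        indices = sorted(node.data for node in self._tree(chrom).overlap(start, end))
        return [ivs[i] for i in indices]

    def midpoints(self, chrom: str) -> np.ndarray:
        """Sorted array of interval midpoints on one chromosome."""
        if chrom not in self._midpoints:
            mids = np.array(
                sorted(iv.midpoint for iv in self._by_chrom.get(chrom, ())), dtype=np.int64
            )
            self._midpoints[chrom] = mids
        return self._midpoints[chrom]


@dataclass(frozen=True)
class StateElement:
    """One chromatin-state segment (15-state HMM style, classes 1-15)."""

    chrom: str
    start: int
    end: int
    state_class: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"state element {self.chrom}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.state_class not in range(1, 16):
            raise ValidationError(
                f"state element {self.chrom}:{self.start}: class must be 1-15, "
                f"got {self.state_class}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CpRecord:
    """One qPCR crossing-point measurement."""

    sample_id: str
    target_id: str
    role: str  # gene | reference | ip | input | mock
    timepoint: str
    cp: float
    replicate: str = "1"

    _ROLES = ("gene", "reference", "ip", "input", "mock")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValidationError(
                f"Cp record {self.sample_id}/{self.target_id}: role must be one of "
                f"{self._ROLES}, got {self.role!r}"
            )
        if not (self.cp > 0 and np.isfinite(self.cp)):
            raise ValidationError(
                f"Cp record {self.sample_id}/{self.target_id}: cp must be finite and > 0"
            )

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.sample_id, self.target_id, self.role, self.timepoint, self.replicate)


# ---------------------------------------------------------------------------
# helpers


def _split_lines(path, dialect: TableDialect) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields), skipping blank and '#' lines."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(("#", "track ", "browser ")):
                continue
            if dialect.delimiter == "\t" and "\t" not in line:
                fields = line.split()
            else:
                fields = line.split(dialect.delimiter)
            yield lineno, fields


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def _looks_like_header(fields: Sequence[str], coord_cols: Sequence[int]) -> bool:
    return any(i < len(fields) and not _is_int(fields[i]) for i in coord_cols)


def _coord(value: str, lineno: int, name: str) -> int:
    if not _is_int(value):
        raise FormatError(f"line {lineno}: non-integer {name} {value!r}")
    return int(value)


# ---------------------------------------------------------------------------
# readers


def read_gene_models(path, dialect: TableDialect = TableDialect()) -> list[GeneModel]:
    """Read a BED-like gene table: chrom, start, end, gene_id, strand.

    A header row is auto-detected by default.  Raises
    :class:`ValidationError` naming the first offending line for inverted
    coordinates, bad strands or duplicate gene ids; :class:`FormatError`
    for missing columns.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    first = True
    for lineno, fields in _split_lines(path, dialect):
        if first:
            first = False
            skip = dialect.header is True or (
                dialect.header == "auto" and _looks_like_header(fields, (1, 2))
            )
            if skip:
                continue
        if len(fields) < 5:
            raise FormatError(
                f"line {lineno}: expected 5 columns (chrom, start, end, gene_id, strand), "
                f"got {len(fields)}"
            )
        chrom = fields[0]
        start = _coord(fields[1], lineno, "start")
        end = _coord(fields[2], lineno, "end")
        if dialect.one_based:
            start -= 1
        gene_id, strand = fields[3], fields[4]
        if not (0 <= start < end):
            raise ValidationError(
                f"line {lineno}: gene {gene_id}: require 0 <= start < end, got [{start}, {end})"
            )
        if gene_id in seen:
            raise ValidationError(f"line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, chrom, start, end, strand))
    return genes


def read_hotspots(
    path, dialect: TableDialect = TableDialect(), score_column: int = 5
) -> HotspotTrack:
    """Read a scored BED file into a :class:`HotspotTrack`.

    ``score_column`` is the 1-based BED column holding the signal value
    (default 5); when a row is too short for it, column 4 is used as a
    fallback.  Output is sorted by (chrom, start); an empty file yields an
    empty track.
    """
    intervals: list[HotspotInterval] = []
    first = True
    for lineno, fields in _split_lines(path, dialect):
        if first:
            first = False
            skip = dialect.header is True or (
                dialect.header == "auto" and _looks_like_header(fields, (1, 2))
            )
            if skip:
                continue
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        start = _coord(fields[1], lineno, "start")
        end = _coord(fields[2], lineno, "end")
        if dialect.one_based:
            start -= 1
        col = score_column if len(fields) >= score_column else 4
        if len(fields) < col:
            raise FormatError(f"line {lineno}: no score column (need column {col})")
        try:
            score = float(fields[col - 1])
        except ValueError:
            raise FormatError(
                f"line {lineno}: non-numeric score {fields[col - 1]!r} in column {col}"
            ) from None
        if not (0 <= start < end):
            raise ValidationError(
                f"line {lineno}: require 0 <= start < end, got [{start}, {end})"
            )
        intervals.append(HotspotInterval(chrom, start, end, score))
    return HotspotTrack(intervals)


def read_expression_table(path, dialect: TableDialect = TableDialect()) -> pd.DataFrame:
    """Read a per-gene expression table: gene_id, fpkm_control, fpkm_treated.

    Returns a DataFrame with those three columns.  Duplicate gene ids or
    negative FPKM values raise :class:`ValidationError`.
    """
    rows = []
    first = True
    for lineno, fields in _split_lines(path, dialect):
        if first:
            first = False
            if dialect.header is True:
                continue
            if dialect.header == "auto" and len(fields) > 1 and not _is_float(fields[1]):
                continue
        if len(fields) < 3:
            raise FormatError(
                f"line {lineno}: expected 3 columns (gene_id, fpkm_control, fpkm_treated)"
            )
        try:
            control, treated = float(fields[1]), float(fields[2])
        except ValueError:
            raise FormatError(f"line {lineno}: non-numeric FPKM value") from None
        if control < 0 or treated < 0:
            raise ValidationError(f"line {lineno}: FPKM values must be >= 0")
        rows.append((fields[0], control, treated, lineno))
    df = pd.DataFrame(rows, columns=["gene_id", "fpkm_control", "fpkm_treated", "_line"])
    dup = df["gene_id"].duplicated()
    if dup.any():
        bad = df.loc[dup, ["gene_id", "_line"]].iloc[0]
        raise ValidationError(f"line {bad['_line']}: duplicate gene_id {bad['gene_id']!r}")
    return df.drop(columns="_line")


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_segmentation(path, dialect: TableDialect = TableDialect()) -> list[StateElement]:
    """Read a chromatin-state BED: chrom, start, end, state_class (1-15)."""
    elements: list[StateElement] = []
    first = True
    for lineno, fields in _split_lines(path, dialect):
        if first:
            first = False
            if dialect.header is True or (
                dialect.header == "auto" and _looks_like_header(fields, (1, 2))
            ):
                continue
        if len(fields) < 4:
            raise FormatError(
                f"line {lineno}: expected 4 columns (chrom, start, end, state_class)"
            )
        start = _coord(fields[1], lineno, "start")
        end = _coord(fields[2], lineno, "end")
        if dialect.one_based:
            start -= 1
        state_raw = fields[3]
        # tolerate ChromHMM-style labels such as "3_Poised_Promoter"
        state_token = state_raw.split("_")[0]
        if not _is_int(state_token):
            raise FormatError(f"line {lineno}: non-integer state class {state_raw!r}")
        try:
            elements.append(StateElement(fields[0], start, end, int(state_token)))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    elements.sort(key=lambda e: (e.chrom, e.start, e.end))
    return elements


_CP_COLUMNS = ("sample_id", "target_id", "role", "timepoint", "cp")


def read_cp_table(path, delimiter: str = ",") -> list[CpRecord]:
    """Read a CSV of Cp measurements.

    Requires a header with at least sample_id, target_id, role, timepoint,
    cp (an optional replicate column defaults to "1").  Duplicate
    (sample, target, role, timepoint, replicate) keys raise
    :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [c for c in _CP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Cp table missing column(s): {', '.join(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = "1"
    records: list[CpRecord] = []
    seen: set[tuple] = set()
    for idx, row in df.iterrows():
        if not _is_float(row["cp"]):
            raise FormatError(f"row {idx + 2}: non-numeric cp {row['cp']!r}")
        rec = CpRecord(
            sample_id=row["sample_id"],
            target_id=row["target_id"],
            role=row["role"],
            timepoint=str(row["timepoint"]),
            cp=float(row["cp"]),
            replicate=str(row["replicate"]),
        )
        if rec.key in seen:
            raise ValidationError(f"row {idx + 2}: duplicate Cp key {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# writers


def write_table(frame: pd.DataFrame, path, sort_by: Sequence[str] | None = None) -> None:
    """Write a report as tab-delimited text with a header.

    Rows are emitted in deterministic order, sorted by ``sort_by``
    (default: all columns, left to right).
    """
    cols = list(sort_by) if sort_by is not None else list(frame.columns)
    out = frame.sort_values(cols, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False)


def write_gene_models(genes: Iterable[GeneModel], path) -> None:
    """Write genes as 5-column BED-like text (chrom start end gene_id strand)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t{g.strand}\n")


def write_hotspots(track: HotspotTrack | Iterable[HotspotInterval], path) -> None:
    """Write hotspots as BED5 (name column is a running index, score column 5)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for i, iv in enumerate(track):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\ths{i}\t{iv.score:.6g}\n")


def write_segmentation(elements: Iterable[StateElement], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.state_class}\n")


def write_expression_table(frame: pd.DataFrame, path) -> None:
    cols = ["gene_id", "fpkm_control", "fpkm_treated"]
    frame[cols].to_csv(path, sep="\t", index=False)


def write_cp_table(records: Iterable[CpRecord], path) -> None:
    rows = [
        (r.sample_id, r.target_id, r.role, r.timepoint, repr(r.cp), r.replicate)
        for r in records
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "target_id", "role", "timepoint", "cp", "replicate"]
    )
    df.to_csv(path, index=False)
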