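"""Genomic interval parsing, query preprocessing and overlap counting.

Coordinates are 0-based half-open throughout ([start, end)); VCF positions
(1-based) are converted at parse time.  Intervals sharing only a boundary
point do not overlap.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "QueryOptions",
    "PreprocessReport",
    "IntervalIndex",
    "OverlapCount",
    "GENOME_SIZES",
    "parse_bed",
    "parse_vcf",
    "write_bed",
    "preprocess_query",
    "build_index",
    "count_overlaps",
]

#: Default background genome sizes (bp) per human assembly.
GENOME_SIZES = {
    "GRCh37": 3_095_677_412,
    "GRCh38": 3_088_269_832,
}


class NoUsableIntervalsError(ValueError):
    """Raised when an input source yields no valid intervals."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/negative interval: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class QueryOptions:
    """Query preprocessing options.

    Parameters
    ----------
    assembly:
        Human assembly name; only selects the default background genome size.
    genome_size:
        Background genome size G in bp.  Defaults to the assembly's size.
    max_interval_length:
        Query intervals longer than this are removed (default 500 bp).
    extension:
        Symmetric extension in bp applied to each surviving interval
        (default 0, i.e. no extension).
    central_window:
        If set, each interval is replaced by its centered window of this
        width (bp); intervals shorter than the window are left unchanged.
    tissues / categories:
        Optional profile filters applied downstream.
    """

    assembly: str = "GRCh37"
    genome_size: int | None = None
    max_interval_length: int = 500
    extension: int = 0
    central_window: int | None = None
    tissues: frozenset[str] | None = None
    categories: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.assembly not in GENOME_SIZES:
            raise ValueError(
                f"unknown assembly {self.assembly!r}; expected one of {sorted(GENOME_SIZES)}"
            )
        if self.genome_size is None:
            object.__setattr__(self, "genome_size", GENOME_SIZES[self.assembly])
        if self.genome_size <= 0:
            raise ValueError("genome_size must be positive")
        if self.max_interval_length <= 0:
            raise ValueError("max_interval_length must be positive")
        if self.extension < 0:
            raise ValueError("extension must be non-negative")
        if self.central_window is not None and self.central_window <= 0:
            raise ValueError("central_window must be positive when set")
        for attr in ("tissues", "categories"):
            val = getattr(self, attr)
            if val is not None and not isinstance(val, frozenset):
                object.__setattr__(self, attr, frozenset(val))

    def to_dict(self) -> dict:
        return {
            "assembly": self.assembly,
            "genome_size": self.genome_size,
            "max_interval_length": self.max_interval_length,
            "extension": self.extension,
            "central_window": self.central_window,
            "tissues": sorted(self.tissues) if self.tissues is not None else None,
            "categories": sorted(self.categories) if self.categories is not None else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QueryOptions":
        d = dict(d)
        for attr in ("tissues", "categories"):
            if d.get(attr) is not None:
                d[attr] = frozenset(d[attr])
        return cls(**d)


@dataclass
class PreprocessReport:
    """Counts of intervals affected by each preprocessing step."""

    n_input: int = 0
    n_removed_length: int = 0
    n_extended: int = 0
    n_windowed: int = 0
    n_output: int = 0


def _open_maybe_gzip(source) -> io.TextIOBase:
    """Open text or a path, transparently handling gzip (detected by magic bytes)."""
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
        raw = Path(source).read_bytes()
    elif isinstance(source, bytes):
        raw = source
    else:
        return io.StringIO(str(source))
    if raw[:2] == b"\x1f\x8b":
        raw = gzip.decompress(raw)
    return io.StringIO(raw.decode())


_BED_SKIP_PREFIXES = ("#", "track", "browser")


def parse_bed(source) -> tuple[list[GenomicInterval], int]:
    """Parse a BED-like source into intervals.

    ``source`` may be a path (plain or gzip) or a string of BED text.
    Returns ``(intervals, n_rejected)``; header/comment lines are skipped and
    are not counted as rejections.  Raises :class:`NoUsableIntervalsError`
    if no valid interval remains.
    """
    intervals: list[GenomicInterval] = []
    rejected = 0
    with _open_maybe_gzip(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 3:
                rejected += 1
                continue
            try:
                iv = GenomicInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except ValueError:
                rejected += 1
                continue
            intervals.append(iv)
    if not intervals:
        raise NoUsableIntervalsError("no usable intervals in BED input")
    return intervals, rejected


def parse_vcf(source) -> tuple[list[GenomicInterval], int]:
    """Parse a VCF-like source; each variant becomes the 1-bp interval [POS-1, POS)."""
    intervals: list[GenomicInterval] = []
    rejected = 0
    with _open_maybe_gzip(source) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                rejected += 1
                continue
            try:
                pos = int(fields[1])
            except ValueError:
                rejected += 1
                continue
            if pos < 1:
                rejected += 1
                continue
            name = fields[2] if len(fields) > 2 and fields[2] != "." else None
            intervals.append(GenomicInterval(fields[0], pos - 1, pos, name))
    if not intervals:
        raise NoUsableIntervalsError("no usable intervals in VCF input")
    return intervals, rejected


def write_bed(intervals: Iterable[GenomicInterval], path=None) -> str:
    """Serialize intervals as BED text; write to ``path`` if given."""
    lines = []
    for iv in intervals:
        fields = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.name is not None:
            fields.append(iv.name)
        lines.append("\t".join(fields))
    text = "\n".join(lines) + ("\n" if lines else "")
    if path is not None:
        Path(path).write_text(text)
    return text


def preprocess_query(
    intervals: Sequence[GenomicInterval], opts: QueryOptions
) -> tuple[list[GenomicInterval], PreprocessReport]:
    """Apply query preprocessing in fixed order: length filter, extension, central window.

    1. Remove intervals with length > ``opts.max_interval_length``.
    2. Extend each survivor by ``opts.extension`` bp on both sides (clamped at 0).
    3. If ``opts.central_window`` is set, replace each interval by its centered
       window of that width; intervals shorter than the window are unchanged.

    Raises ``ValueError`` if the length filter removes every interval.
    """
    report = PreprocessReport(n_input=len(intervals))

    kept = [iv for iv in intervals if iv.length <= opts.max_interval_length]
    report.n_removed_length = len(intervals) - len(kept)
    if intervals and not kept:
        raise ValueError(
            "all query intervals removed by the maximum-interval-length filter "
            f"(max_interval_length={opts.max_interval_length})"
        )

    if opts.extension > 0:
        kept = [
            replace(iv, start=max(0, iv.start - opts.extension), end=iv.end + opts.extension)
            for iv in kept
        ]
        report.n_extended = len(kept)

    if opts.central_window is not None:
        w = opts.central_window
        out = []
        for iv in kept:
            if iv.length <= w:
                out.append(iv)
                continue
            mid = (iv.start + iv.end) // 2
            new_start = max(0, mid - w // 2)
            out.append(replace(iv, start=new_start, end=new_start + w))
            report.n_windowed += 1
        kept = out

    report.n_output = len(kept)
    return kept, report


@dataclass(frozen=True)
class OverlapCount:
    """Overlap counts between a query and an index.

    ``pairs`` counts (query interval, indexed interval) pairs with >=1 bp
    overlap (multiset semantics); ``query_hits`` counts query intervals with
    at least one overlapping indexed interval, so ``pairs >= query_hits``.
    """

    pairs: int
    query_hits: int


class IntervalIndex:
    """Immutable per-chromosome overlap index over an interval multiset."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        self._count = len(intervals)
        self._total_length = sum(iv.length for iv in intervals)
        for i, iv in enumerate(intervals):
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            # unique payload keeps duplicated intervals as distinct members
            tree.addi(iv.start, iv.end, i)

    @property
    def count(self) -> int:
        return self._count

    @property
    def total_length(self) -> int:
        return self._total_length

    @property
    def mean_length(self) -> float:
        return self._total_length / self._count if self._count else 0.0

    def n_overlapping(self, iv: GenomicInterval) -> int:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return 0
        return len(tree.overlap(iv.start, iv.end))


def build_index(intervals: Sequence[GenomicInterval]) -> IntervalIndex:
    """Build an overlap index over ``intervals`` (duplicates counted separately)."""
    return IntervalIndex(intervals)


def count_overlaps(query: Sequence[GenomicInterval], index: IntervalIndex) -> OverlapCount:
    """Count overlapping pairs and hit query intervals against an index."""
    pairs = 0
    hits = 0
    for iv in query:
        n = index.n_overlapping(iv)
        pairs += n
        if n:
            hits += 1
    return OverlapCount(pairs=pairs, query_hits=hits)
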