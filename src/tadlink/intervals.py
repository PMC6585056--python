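"""Chromosome-aware interval algebra.

All coordinates are 0-based, half-open (BED convention): an interval
``[start, end)`` covers bases ``start .. end-1``.  Adjacency
(``a.end == b.start``) is therefore *not* overlap.  These primitives are the
currency of every pipeline stage — peak sets, TAD domains, TSS windows and
profile windows are all ``IntervalSet`` instances.

The operations here deliberately act on whole elements: ``intersect_keep``
returns elements of *a* with their original coordinates (no clipping to the
overlap), and ``subtract_drop`` removes whole elements rather than truncating
them.  Region counts downstream (called enhancers, histogram bins) therefore
stay in bijection with input peaks.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "DistanceBin",
    "DISTANCE_BINS",
    "NoReferenceError",
    "intersect_keep",
    "subtract_drop",
    "merge",
    "distance_to_nearest_tss",
    "classify_distance",
    "assign_to_domain",
    "validate_non_overlapping",
]


class NoReferenceError(LookupError):
    """Raised when a distance query has no reference point on the chromosome."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Number of shared bases with ``other`` (0 if different chromosomes)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """A named, sorted collection of :class:`GenomicInterval`.

    Sorted by ``(chrom, start, end)`` on construction; overlaps between
    elements are allowed unless the set was produced by :func:`merge`.
    """

    __slots__ = ("intervals", "name", "_by_chrom")

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.intervals: tuple[GenomicInterval, ...] = tuple(sorted(intervals))
        self.name = name
        self._by_chrom: Optional[dict[str, list[GenomicInterval]]] = None

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        if self._by_chrom is None:
            d: dict[str, list[GenomicInterval]] = {}
            for iv in self.intervals:
                d.setdefault(iv.chrom, []).append(iv)
            self._by_chrom = d
        return self._by_chrom

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __hash__(self) -> int:
        return hash(self.intervals)

    def __repr__(self) -> str:
        label = f" {self.name!r}" if self.name else ""
        return f"<IntervalSet{label} n={len(self)}>"


@dataclass(frozen=True)
class DistanceBin:
    """One bin of the peak-to-TSS distance partition of ``[0, inf)``."""

    label: str
    lower: int
    upper: Optional[int]  # exclusive; None = unbounded

    def contains(self, d: int) -> bool:
        return d >= self.lower and (self.upper is None or d < self.upper)


#: Half-open distance bins with inclusive lower edges; together they
#: partition every non-negative distance exactly once.
DISTANCE_BINS: tuple[DistanceBin, ...] = (
    DistanceBin("0-5 kb", 0, 5_000),
    DistanceBin("5-50 kb", 5_000, 50_000),
    DistanceBin("50-500 kb", 50_000, 500_000),
    DistanceBin(">500 kb", 500_000, None),
)


def _max_overlap_with(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> int:
    """Largest per-element overlap of ``iv`` with any single element of ``others``.

    ``others`` must be sorted by start and on the same chromosome as ``iv``.
    Overlap is evaluated per element, never against the union: two abutting
    elements of ``others`` are not allowed to pool their bases.
    """
    best = 0
    starts = [o.start for o in others]
    # candidates: every element starting before iv.end
    hi = bisect.bisect_left(starts, iv.end)
    for o in others[:hi]:
        if o.end > iv.start:
            ov = min(iv.end, o.end) - max(iv.start, o.start)
            if ov > best:
                best = ov
    return best


def intersect_keep(a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    """Elements of *a* overlapping at least one element of *b* by >= ``min_overlap_bp``.

    Coordinates of the survivors are unmodified (no clipping), so the result
    is a subset of *a* under coordinate identity and the operation is
    idempotent in *b*.
    """
    if min_overlap_bp < 1:
        raise ValueError(f"min_overlap_bp must be >= 1, got {min_overlap_bp}")
    b_chrom = b.by_chrom()
    kept = [
        iv
        for iv in a
        if iv.chrom in b_chrom
        and _max_overlap_with(iv, b_chrom[iv.chrom]) >= min_overlap_bp
    ]
    return IntervalSet(kept, name=a.name)


def subtract_drop(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Elements of *a* sharing zero bases with every element of *b*.

    Whole-element removal: any overlap, however small, discards the entire
    element; surviving elements are never truncated.
    """
    b_chrom = b.by_chrom()
    kept = [
        iv
        for iv in a
        if iv.chrom not in b_chrom or _max_overlap_with(iv, b_chrom[iv.chrom]) == 0
    ]
    return IntervalSet(kept, name=a.name)


def merge(a: IntervalSet, max_gap_bp: int = 0) -> IntervalSet:
    """Union elements within ``max_gap_bp`` of each other on the same chromosome.

    With ``max_gap_bp=0`` only genuinely overlapping elements merge, the
    result is non-overlapping and the covered-base count is conserved.
    """
    if max_gap_bp < 0:
        raise ValueError(f"max_gap_bp must be >= 0, got {max_gap_bp}")
    out: list[GenomicInterval] = []
    for chrom, ivs in a.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + max_gap_bp:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(out, name=a.name)


def distance_to_nearest_tss(peak: GenomicInterval, genes: Iterable) -> int:
    """Distance from the peak center to the nearest TSS on the same chromosome.

    The anchor is the peak midpoint ``floor((start+end)/2)``; wide peaks are
    therefore measured unambiguously.  Raises :class:`NoReferenceError` when
    the chromosome carries no annotated gene (callers may treat that as the
    unbounded distance bin).
    """
    center = peak.midpoint
    tss_positions = [
        tss for g in genes if g.chrom == peak.chrom for tss in g.tss_list
    ]
    if not tss_positions:
        raise NoReferenceError(f"no TSS annotated on chromosome {peak.chrom!r}")
    return min(abs(center - t) for t in tss_positions)


def classify_distance(d: int) -> str:
    """Bin label for a non-negative peak-to-TSS distance."""
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    for b in DISTANCE_BINS:
        if b.contains(d):
            return b.label
    raise AssertionError("unreachable: bins partition [0, inf)")


def validate_non_overlapping(tads: IntervalSet) -> IntervalSet:
    """Assert that domains never overlap within a chromosome; returns the set."""
    for chrom, ivs in tads.by_chrom().items():
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping domains on {chrom}: {prev} and {cur}"
                )
    return tads


def assign_to_domain(region: GenomicInterval, tads: IntervalSet) -> Optional[int]:
    """Index (into the sorted TAD set) of the domain containing the region midpoint.

    A region is assigned to at most one domain; a midpoint falling between
    domains — or on a chromosome without domains — yields ``None``.
    Boundary-straddling regions follow their midpoint.
    """
    mid = region.midpoint
    for idx, tad in enumerate(tads):
        if tad.chrom == region.chrom and tad.start <= mid < tad.end:
            return idx
    return None
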