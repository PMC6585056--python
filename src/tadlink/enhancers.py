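"""Calling ARID1A-bound active enhancers from peak co-occupancy.

An enhancer here is operationally an ARID1A peak that (i) overlaps an
H3K27ac peak, (ii) overlaps an ATAC accessibility peak, and (iii) lies away
from every annotated TSS.  The called set keeps the original ARID1A peak
coordinates, so it is always a subset of the input ARID1A peaks and the
region count is directly comparable to the input peak count.

"Away from a TSS" means the peak shares no base with any TSS exclusion
window (each TSS expanded by ``tss_exclusion_flank_bp`` on both sides);
overlap removes the whole candidate, never a clipped fragment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .intervals import (
    DISTANCE_BINS,
    GenomicInterval,
    IntervalSet,
    NoReferenceError,
    assign_to_domain,
    classify_distance,
    distance_to_nearest_tss,
    intersect_keep,
    subtract_drop,
    validate_non_overlapping,
)
from .io import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "EnhancerRecord",
    "tss_exclusion_windows",
    "call_active_enhancers",
    "distance_histogram",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable windows of the enhancer pipeline.

    min_overlap_bp
        Minimum shared bases for two peaks to count as co-occupied (>= 1 bp).
    tss_exclusion_flank_bp
        Half-width of the promoter-proximal window subtracted around every
        TSS when calling enhancers (default 2 kb per side).
    tss_activity_flank_bp
        Half-width of the promoter window tested for H3K27ac overlap when
        flagging a gene as active (default 1 kb per side).
    """

    min_overlap_bp: int = 1
    tss_exclusion_flank_bp: int = 2_000
    tss_activity_flank_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if self.tss_exclusion_flank_bp < 0 or self.tss_activity_flank_bp < 0:
            raise ValueError("flanks must be >= 0")


@dataclass(frozen=True)
class EnhancerRecord:
    """A called enhancer: the original ARID1A peak plus its annotations."""

    enhancer_id: str
    interval: GenomicInterval
    has_k27ac: bool
    has_atac: bool
    tss_distance: Optional[int]
    tad_index: Optional[int]


def tss_exclusion_windows(genes: Iterable[GeneModel], flank_bp: int) -> IntervalSet:
    """Every TSS expanded by ``flank_bp`` on both sides (window covers the TSS base)."""
    windows = [
        GenomicInterval(g.chrom, max(0, tss - flank_bp), tss + flank_bp + 1)
        for g in genes
        for tss in g.tss_list
    ]
    return IntervalSet(windows, name="tss_windows")


def call_active_enhancers(
    arid1a: IntervalSet,
    k27ac: IntervalSet,
    atac: IntervalSet,
    genes: Sequence[GeneModel],
    cfg: PipelineConfig = PipelineConfig(),
    tads: Optional[IntervalSet] = None,
) -> list[EnhancerRecord]:
    """Call active enhancers by peak co-occupancy minus TSS-proximal regions.

    Pipeline: keep ARID1A peaks overlapping H3K27ac, of those keep the ones
    overlapping ATAC, then drop any survivor touching a TSS exclusion window.
    The two intersections commute; survivors are annotated with their
    center-to-TSS distance and (when ``tads`` is given) their containing TAD.
    """
    if len(arid1a) == 0:
        logger.warning("empty ARID1A peak set: no enhancers can be called")
        return []
    co_occupied = intersect_keep(
        intersect_keep(arid1a, k27ac, cfg.min_overlap_bp), atac, cfg.min_overlap_bp
    )
    windows = tss_exclusion_windows(genes, cfg.tss_exclusion_flank_bp)
    survivors = subtract_drop(co_occupied, windows)
    if tads is not None:
        validate_non_overlapping(tads)
    records = []
    for i, iv in enumerate(survivors):
        try:
            d = distance_to_nearest_tss(iv, genes)
        except NoReferenceError:
            d = None
        records.append(
            EnhancerRecord(
                enhancer_id=f"enh_{i + 1:05d}",
                interval=iv,
                has_k27ac=True,
                has_atac=True,
                tss_distance=d,
                tad_index=assign_to_domain(iv, tads) if tads is not None else None,
            )
        )
    return records


def distance_histogram(
    regions: Iterable[GenomicInterval], genes: Sequence[GeneModel]
) -> dict[str, int]:
    """Counts of regions per center-to-TSS distance bin.

    Regions on chromosomes without any annotated gene are counted in the
    unbounded ('>500 kb') bin and logged; the counts always sum to the number
    of input regions.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene collection must be non-empty")
    counts = {b.label: 0 for b in DISTANCE_BINS}
    n_unclassifiable = 0
    for iv in regions:
        try:
            counts[classify_distance(distance_to_nearest_tss(iv, genes))] += 1
        except NoReferenceError:
            counts[DISTANCE_BINS[-1].label] += 1
            n_unclassifiable += 1
    if n_unclassifiable:
        logger.warning(
            "%d region(s) on chromosomes without genes counted as %s",
            n_unclassifiable,
            DISTANCE_BINS[-1].label,
        )
    return counts
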