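"""TAD-constrained enhancer-to-gene assignment.

A candidate target of an enhancer is any *active* gene with at least one TSS
inside the same topologically associated domain (TAD) as the enhancer.  The
TAD boundary is a hard wall: an active gene in the adjacent domain is never
linked, and an enhancer whose midpoint falls outside every domain gets no
targets at all (no nearest-gene fallback by default).

Gene activity is promoter H3K27ac: a gene is active iff any of its TSSs,
expanded by the activity flank, overlaps an H3K27ac peak.  Activity is a
property of the gene, not of individual TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from statistics import median
from typing import Iterable, Optional, Sequence

from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect_keep,
    validate_non_overlapping,
)
from .io import GeneModel
from .enhancers import EnhancerRecord, PipelineConfig

__all__ = [
    "EnhancerGeneLink",
    "mark_active_genes",
    "link_enhancers",
    "genes_per_enhancer_summary",
]


@dataclass(frozen=True)
class EnhancerGeneLink:
    """One (enhancer, gene) association inside a shared TAD.

    ``link_distance`` is from the enhancer midpoint to the nearest of the
    gene's TSSs that lies inside the shared TAD.
    """

    enhancer_id: str
    gene_id: str
    tad_index: int
    link_distance: int


def mark_active_genes(
    genes: Iterable[GeneModel],
    k27ac: IntervalSet,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[GeneModel]:
    """Flag genes whose promoter carries H3K27ac.

    A gene is active iff any TSS in its ``tss_list``, expanded by
    ``tss_activity_flank_bp`` on both sides, overlaps an H3K27ac peak by at
    least 1 bp.  Returns new GeneModel instances carrying the flags.
    """
    flank = cfg.tss_activity_flank_bp
    out = []
    for g in genes:
        windows = IntervalSet(
            GenomicInterval(g.chrom, max(0, t - flank), t + flank + 1)
            for t in g.tss_list
        )
        active = len(intersect_keep(windows, k27ac, 1)) > 0
        out.append(replace(g, active=active))
    return out


def link_enhancers(
    enhancers: Sequence[EnhancerRecord],
    tads: IntervalSet,
    genes: Sequence[GeneModel],
) -> tuple[list[EnhancerGeneLink], list[str]]:
    """Link each enhancer to every active gene with a TSS in its TAD.

    Returns ``(links, target_gene_ids)`` where the gene set is the sorted
    deduplicated union over all links.  Enhancers without a TAD produce no
    links.  Links are sorted by (enhancer_id, gene_id).
    """
    validate_non_overlapping(tads)
    tad_list = list(tads)
    links: list[EnhancerGeneLink] = []
    for enh in enhancers:
        if enh.tad_index is None:
            continue
        tad = tad_list[enh.tad_index]
        mid = enh.interval.midpoint
        for g in genes:
            if not g.active or g.chrom != tad.chrom:
                continue
            in_tad = [t for t in g.tss_list if tad.start <= t < tad.end]
            if not in_tad:
                continue
            links.append(
                EnhancerGeneLink(
                    enhancer_id=enh.enhancer_id,
                    gene_id=g.gene_id,
                    tad_index=enh.tad_index,
                    link_distance=min(abs(mid - t) for t in in_tad),
                )
            )
    links.sort(key=lambda l: (l.enhancer_id, l.gene_id))
    gene_ids = sorted({l.gene_id for l in links})
    return links, gene_ids


def genes_per_enhancer_summary(links: Iterable[EnhancerGeneLink]) -> dict:
    """Distribution summary of the link table.

    Reports n_links, n_enhancers, n_genes and min/median/max of both genes
    per enhancer and enhancers per gene; all zeros for an empty table.
    """
    links = list(links)
    if not links:
        return {
            "n_links": 0,
            "n_enhancers": 0,
            "n_genes": 0,
            "genes_per_enhancer": {"min": 0, "median": 0, "max": 0},
            "enhancers_per_gene": {"min": 0, "median": 0, "max": 0},
        }
    per_enh: dict[str, int] = {}
    per_gene: dict[str, int] = {}
    for l in links:
        per_enh[l.enhancer_id] = per_enh.get(l.enhancer_id, 0) + 1
        per_gene[l.gene_id] = per_gene.get(l.gene_id, 0) + 1

    def stats(counts):
        vals = sorted(counts.values())
        return {"min": vals[0], "median": median(vals), "max": vals[-1]}

    return {
        "n_links": len(links),
        "n_enhancers": len(per_enh),
        "n_genes": len(per_gene),
        "genes_per_enhancer": stats(per_enh),
        "enhancers_per_gene": stats(per_gene),
    }
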