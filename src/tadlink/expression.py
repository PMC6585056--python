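"""Differential-expression classification and set integration.

Genes are classified against an FDR cutoff and an absolute log2 fold-change
cutoff, both edges inclusive exactly as printed in the thresholds they come
from (q <= q_max, |log2FC| >= lfc_min).  The per-cell-line thresholds used
throughout are q_max 0.05 with lfc_min 0.7 (HCT116) or 0.6 (DLD1,
COLO320DM).  Set operations (shared downregulated genes across lines,
overlap of enhancer-linked genes with downregulated genes) use exact string
identity of gene ids — no symbol/alias resolution.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import AbstractSet, Iterable, Mapping

from .io import ExpressionRecord

__all__ = ["DEConfig", "DEClassification", "classify_de", "common_down", "direct_enhancer_targets"]


@dataclass(frozen=True)
class DEConfig:
    """Significance (q_max) and effect-size (|log2FC| >= lfc_min) cutoffs."""

    q_max: float = 0.05
    lfc_min: float = 0.7

    def __post_init__(self) -> None:
        if not (0.0 < self.q_max <= 1.0):
            raise ValueError(f"q_max must be in (0, 1], got {self.q_max}")
        if self.lfc_min < 0:
            raise ValueError(f"lfc_min must be >= 0, got {self.lfc_min}")


@dataclass(frozen=True)
class DEClassification:
    """Disjoint up/down/unchanged gene-id sets partitioning the input."""

    up: frozenset[str]
    down: frozenset[str]
    unchanged: frozenset[str]

    @property
    def all_genes(self) -> frozenset[str]:
        return self.up | self.down | self.unchanged


def classify_de(records: Iterable[ExpressionRecord], cfg: DEConfig) -> DEClassification:
    """Partition genes into up / down / unchanged.

    down: q <= q_max and log2fc <= -lfc_min; up: q <= q_max and
    log2fc >= +lfc_min; both comparisons inclusive.  Everything else is
    unchanged.  Duplicate gene ids are an input error.
    """
    records = list(records)
    dup = [g for g, n in Counter(r.gene_id for r in records).items() if n > 1]
    if dup:
        raise ValueError(f"duplicate gene_id(s) in expression table: {sorted(dup)}")
    up, down, unchanged = set(), set(), set()
    for r in records:
        if r.q_value <= cfg.q_max and r.log2fc <= -cfg.lfc_min:
            down.add(r.gene_id)
        elif r.q_value <= cfg.q_max and r.log2fc >= cfg.lfc_min:
            up.add(r.gene_id)
        else:
            unchanged.add(r.gene_id)
    return DEClassification(frozenset(up), frozenset(down), frozenset(unchanged))


def common_down(classifications: Mapping[str, DEClassification]) -> list[str]:
    """Genes downregulated in every named classification (sorted).

    Used for cross-cell-line intersections; requires at least two inputs.
    """
    if len(classifications) < 2:
        raise ValueError("common_down requires >= 2 classifications")
    sets = [c.down for c in classifications.values()]
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return sorted(out)


def direct_enhancer_targets(
    linked_genes: AbstractSet[str] | Iterable[str], down: AbstractSet[str] | Iterable[str]
) -> list[str]:
    """Enhancer-linked genes that are also downregulated (sorted intersection)."""
    return sorted(set(linked_genes) & set(down))
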