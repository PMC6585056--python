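"""Synthetic desk-scale datasets with planted ground truth.

The generator emulates the *processed* level of the data the pipeline
consumes: three co-registered peak sets (ARID1A, H3K27ac, ATAC) on a single
toy chromosome, non-overlapping TADs tiling it, stranded gene TSSs with an
active subset, knockout-vs-parental expression tables for two cell lines,
and a coverage track.  Every planted structure is recorded in a
:class:`SyntheticTruth` so each pipeline stage can be scored exactly.

Planted classes:

* **true enhancers** — ARID1A, H3K27ac and ATAC peaks co-centered within a
  small jitter, placed clear of every TSS exclusion window;
* **decoys**, each violating exactly one calling criterion: ARID1A-only
  peaks (no H3K27ac, no ATAC), ARID1A+H3K27ac peaks without ATAC, and
  triple-marked peaks centered on the TSS of an active gene
  (promoter-overlapping, hence subtracted).

With the default configuration the planted structure is perfectly
separable: enhancer calling and TAD linking recover the truth with
precision and recall exactly 1.0.  The generator keeps inactive-gene
promoters at least one activity window plus one peak footprint away from
every H3K27ac peak, so the activity flags the pipeline computes coincide
with the planted active set.

Downregulation is planted in *both* cell lines for every enhancer-linked
gene (log2FC from a normal truncated above ``down_lfc_cap``, q uniform
below ``down_q_max``); all other genes carry independent null noise, so
cross-line intersections have a known expected set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .intervals import GenomicInterval, IntervalSet
from .io import ExpressionRecord, GeneModel, write_bed, write_expression_table, write_gene_models_bed6
from .linking import EnhancerGeneLink
from .profiles import SignalTrack, write_bedgraph

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticDataset", "GenerationError", "generate", "perturb"]


class GenerationError(RuntimeError):
    """Raised when peaks cannot be placed without violating the invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Scales are chosen to resemble a single human-chromosome-arm slice of a
    processed ChIP/ATAC experiment: ~500 kb TADs, 600 bp peaks, and a
    planted knockdown effect (log2FC mean -1.5, sd 0.3) that clears the
    downstream thresholds by construction.
    """

    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    n_tads: int = 20
    n_genes: int = 200
    active_gene_fraction: float = 0.4
    n_true_enhancers: int = 40
    n_decoys_per_class: int = 20
    peak_width_bp: int = 600
    jitter_bp: int = 100
    tss_exclusion_flank_bp: int = 2_000
    tss_activity_flank_bp: int = 1_000
    down_lfc_mean: float = -1.5
    down_lfc_sd: float = 0.3
    down_lfc_cap: float = -0.7  # planted effects never weaker than this
    null_lfc_sd: float = 0.2
    down_q_max: float = 0.01
    background_bin_bp: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chrom_length < self.n_tads or self.n_tads < 1:
            raise ValueError("chrom_length must exceed n_tads >= 1")
        if not (0.0 <= self.active_gene_fraction <= 1.0):
            raise ValueError("active_gene_fraction must be in [0, 1]")
        if self.peak_width_bp < 2 or self.jitter_bp < 0:
            raise ValueError("invalid peak geometry")
        if self.n_decoys_per_class > int(round(self.n_genes * self.active_gene_fraction)):
            raise ValueError(
                "promoter-overlapping decoys need one active gene each: "
                "reduce n_decoys_per_class or raise the active fraction"
            )


@dataclass
class SyntheticTruth:
    """Everything planted in one dataset, for scoring recovery.

    ``enhancer_ids`` follow coordinate-sorted order, matching the ids the
    calling pipeline assigns when recovery is exact.  Perturbations fill the
    ``unrecoverable_*`` fields with the planted items they are expected to
    break.
    """

    enhancers: IntervalSet
    enhancer_ids: list[str]
    links: list[EnhancerGeneLink]
    direct_targets: list[str]
    active_gene_ids: list[str]
    seed: int
    unrecoverable_enhancer_ids: list[str] = field(default_factory=list)
    unrecoverable_links: list[EnhancerGeneLink] = field(default_factory=list)

    @property
    def linked_gene_ids(self) -> list[str]:
        return sorted({l.gene_id for l in self.links})


@dataclass
class SyntheticDataset:
    """One generated dataset: all pipeline inputs plus the planted truth."""

    config: GeneratorConfig
    arid1a: IntervalSet
    k27ac: IntervalSet
    atac: IntervalSet
    tads: IntervalSet
    genes: list[GeneModel]
    expression: dict[str, list[ExpressionRecord]]  # "lineA", "lineB"
    track: SignalTrack
    truth: SyntheticTruth
    atac_by_enhancer: dict[str, GenomicInterval] = field(default_factory=dict)

    def write(self, outdir: Union[str, Path]) -> dict[str, Path]:
        """Write every input file plus ``truth.json``; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "arid1a": outdir / "arid1a.bed",
            "k27ac": outdir / "k27ac.bed",
            "atac": outdir / "atac.bed",
            "tads": outdir / "tads.bed",
            "genes": outdir / "genes.bed6",
            "expr_lineA": outdir / "expr_lineA.tsv",
            "expr_lineB": outdir / "expr_lineB.tsv",
            "signal": outdir / "signal.bedGraph",
            "truth": outdir / "truth.json",
        }
        write_bed(self.arid1a, paths["arid1a"])
        write_bed(self.k27ac, paths["k27ac"])
        write_bed(self.atac, paths["atac"])
        write_bed(self.tads, paths["tads"])
        write_gene_models_bed6(self.genes, paths["genes"])
        write_expression_table(self.expression["lineA"], paths["expr_lineA"])
        write_expression_table(self.expression["lineB"], paths["expr_lineB"])
        write_bedgraph(self.track, paths["signal"])
        truth_doc = {
            "seed": self.truth.seed,
            "enhancers": [
                [iv.chrom, iv.start, iv.end] for iv in self.truth.enhancers
            ],
            "enhancer_ids": self.truth.enhancer_ids,
            "links": [
                [l.enhancer_id, l.gene_id, l.tad_index, l.link_distance]
                for l in self.truth.links
            ],
            "direct_targets": self.truth.direct_targets,
            "active_gene_ids": self.truth.active_gene_ids,
        }
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            json.dump(truth_doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _overlaps_any(start: int, end: int, blocked: list[tuple[int, int]]) -> bool:
    return any(s < end and start < e for s, e in blocked)


def _place_centers(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    footprint_half: int,
    blocked: list[tuple[int, int]],
    max_tries: int,
) -> list[int]:
    """Rejection-sample ``n`` centers whose padded footprints avoid ``blocked``.

    Each accepted footprint is appended to ``blocked`` so later placements
    (of any class) stay disjoint from it.
    """
    centers = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise GenerationError(
                "could not place all peaks without overlap; "
                "increase chrom_length or reduce peak counts"
            )
        tries += 1
        c = int(rng.integers(lo, hi))
        if _overlaps_any(c - footprint_half, c + footprint_half, blocked):
            continue
        centers.append(c)
        blocked.append((c - footprint_half, c + footprint_half))
    return sorted(centers)


def _peak_at(chrom: str, center: int, width: int) -> GenomicInterval:
    half = width // 2
    return GenomicInterval(chrom, center - half, center - half + width)


def generate(cfg: GeneratorConfig = GeneratorConfig()) -> SyntheticDataset:
    """Generate one dataset; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    chrom, L = cfg.chrom, cfg.chrom_length
    half = cfg.peak_width_bp // 2
    pad = half + cfg.jitter_bp  # reach of any jittered mark from its center

    # --- TADs: equal-width, non-overlapping, tiling the chromosome
    w = L // cfg.n_tads
    tads = IntervalSet(
        (
            GenomicInterval(chrom, i * w, (i + 1) * w if i < cfg.n_tads - 1 else L)
            for i in range(cfg.n_tads)
        ),
        name="tads",
    )

    # --- genes: uniform TSSs kept far enough apart that promoter H3K27ac of
    # one gene can never spill into another gene's activity window
    min_tss_sep = 2 * (cfg.tss_activity_flank_bp + pad) + 2
    margin = cfg.tss_exclusion_flank_bp + pad + 1
    tss_positions: list[int] = []
    tries = 0
    while len(tss_positions) < cfg.n_genes:
        if tries > 1000 * cfg.n_genes:
            raise GenerationError(
                "could not place all TSSs; increase chrom_length or reduce n_genes"
            )
        tries += 1
        t = int(rng.integers(margin, L - margin))
        if all(abs(t - u) >= min_tss_sep for u in tss_positions):
            tss_positions.append(t)
    tss_positions.sort()
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    genes = [
        GeneModel(f"g{i + 1:04d}", chrom, str(strands[i]), [tss_positions[i]])
        for i in range(cfg.n_genes)
    ]
    n_active = int(round(cfg.n_genes * cfg.active_gene_fraction))
    active_idx = sorted(rng.choice(cfg.n_genes, size=n_active, replace=False).tolist())
    active_set = set(active_idx)
    for i in active_idx:
        genes[i] = dataclasses.replace(genes[i], active=True)

    # --- peak placement, all classes mutually disjoint and TSS-distal
    blocked: list[tuple[int, int]] = [
        (t - cfg.tss_exclusion_flank_bp, t + cfg.tss_exclusion_flank_bp + 1)
        for t in tss_positions
    ]
    lo, hi = pad + 1, L - pad - 1
    max_tries = 1000 * (cfg.n_true_enhancers + 2 * cfg.n_decoys_per_class + 1)
    enh_centers = _place_centers(rng, cfg.n_true_enhancers, lo, hi, pad, blocked, max_tries)
    aonly_centers = _place_centers(rng, cfg.n_decoys_per_class, lo, hi, pad, blocked, max_tries)
    ak_centers = _place_centers(rng, cfg.n_decoys_per_class, lo, hi, pad, blocked, max_tries)
    promoter_idx = sorted(
        rng.choice(active_idx, size=cfg.n_decoys_per_class, replace=False).tolist()
    )

    def jittered(center: int) -> int:
        return center + int(rng.integers(-cfg.jitter_bp, cfg.jitter_bp + 1))

    arid1a_peaks: list[GenomicInterval] = []
    k27ac_peaks: list[GenomicInterval] = []
    atac_peaks: list[GenomicInterval] = []
    atac_of_enhancer: list[GenomicInterval] = []

    for c in enh_centers:  # true enhancers: triple-marked, TSS-distal
        arid1a_peaks.append(_peak_at(chrom, c, cfg.peak_width_bp))
        k27ac_peaks.append(_peak_at(chrom, jittered(c), cfg.peak_width_bp))
        a = _peak_at(chrom, jittered(c), cfg.peak_width_bp)
        atac_peaks.append(a)
        atac_of_enhancer.append(a)
    for c in aonly_centers:  # decoys violating both mark criteria
        arid1a_peaks.append(_peak_at(chrom, c, cfg.peak_width_bp))
    for c in ak_centers:  # decoys violating only the ATAC criterion
        arid1a_peaks.append(_peak_at(chrom, c, cfg.peak_width_bp))
        k27ac_peaks.append(_peak_at(chrom, jittered(c), cfg.peak_width_bp))
    for i in promoter_idx:  # decoys violating only the TSS-distal criterion
        t = genes[i].tss_list[0]
        arid1a_peaks.append(_peak_at(chrom, t, cfg.peak_width_bp))
        k27ac_peaks.append(_peak_at(chrom, jittered(t), cfg.peak_width_bp))
        atac_peaks.append(_peak_at(chrom, jittered(t), cfg.peak_width_bp))
    for i in active_idx:  # promoter H3K27ac defining gene activity
        k27ac_peaks.append(_peak_at(chrom, genes[i].tss_list[0], cfg.peak_width_bp))

    arid1a = IntervalSet(arid1a_peaks, name="arid1a")
    k27ac = IntervalSet(k27ac_peaks, name="k27ac")
    atac = IntervalSet(atac_peaks, name="atac")

    # --- planted truth: enhancer ids in coordinate-sorted order; links by
    # the TAD-containment-and-activity rule, built directly here
    true_enh = sorted(_peak_at(chrom, c, cfg.peak_width_bp) for c in enh_centers)
    enhancer_ids = [f"enh_{i + 1:05d}" for i in range(len(true_enh))]
    atac_by_enhancer = {
        enhancer_ids[i]: a
        for i, (c, a) in enumerate(
            sorted(zip(enh_centers, atac_of_enhancer), key=lambda p: p[0])
        )
    }
    tad_list = list(tads)
    links: list[EnhancerGeneLink] = []
    for eid, iv in zip(enhancer_ids, true_enh):
        mid = iv.midpoint
        tad_idx = next(
            i for i, t in enumerate(tad_list) if t.start <= mid < t.end
        )
        tad = tad_list[tad_idx]
        for g in genes:
            if not g.active:
                continue
            in_tad = [t for t in g.tss_list if tad.start <= t < tad.end]
            if in_tad:
                links.append(
                    EnhancerGeneLink(eid, g.gene_id, tad_idx, min(abs(mid - t) for t in in_tad))
                )
    links.sort(key=lambda l: (l.enhancer_id, l.gene_id))
    direct_targets = sorted({l.gene_id for l in links})

    # --- expression tables: planted downregulation in both lines for every
    # linked gene; independent null noise everywhere else
    expression: dict[str, list[ExpressionRecord]] = {}
    target_set = set(direct_targets)
    for line in ("lineA", "lineB"):
        records = []
        for g in genes:
            if g.gene_id in target_set:
                lfc = float(rng.normal(cfg.down_lfc_mean, cfg.down_lfc_sd))
                while lfc > cfg.down_lfc_cap:  # truncate: planted effects stay strong
                    lfc = float(rng.normal(cfg.down_lfc_mean, cfg.down_lfc_sd))
                q = float(rng.uniform(0.0, cfg.down_q_max))
            else:
                lfc = float(rng.normal(0.0, cfg.null_lfc_sd))
                q = float(rng.uniform(0.0, 1.0))
            records.append(ExpressionRecord(g.gene_id, lfc, q))
        expression[line] = records

    # --- coverage track: noisy background bins, elevated over true enhancers
    n_bins = (L + cfg.background_bin_bp - 1) // cfg.background_bin_bp
    bg = np.abs(rng.normal(0.1, 0.05, size=n_bins))
    heights = rng.uniform(3.0, 10.0, size=len(true_enh))
    steps = []
    enh_sorted = true_enh  # already sorted
    for b in range(n_bins):
        s = b * cfg.background_bin_bp
        e = min(L, s + cfg.background_bin_bp)
        v = float(bg[b])
        for iv, h in zip(enh_sorted, heights):
            if iv.start < e and s < iv.end:
                v += float(h)
                break
        steps.append((GenomicInterval(chrom, s, e), v))
    track = SignalTrack(steps)

    truth = SyntheticTruth(
        enhancers=IntervalSet(true_enh, name="planted_enhancers"),
        enhancer_ids=enhancer_ids,
        links=links,
        direct_targets=direct_targets,
        active_gene_ids=sorted(genes[i].gene_id for i in active_idx),
        seed=cfg.seed,
    )
    return SyntheticDataset(
        config=cfg,
        arid1a=arid1a,
        k27ac=k27ac,
        atac=atac,
        tads=tads,
        genes=genes,
        expression=expression,
        track=track,
        truth=truth,
        atac_by_enhancer=atac_by_enhancer,
    )


_PERTURBATIONS = ("drop_atac_fraction", "shift_tad_boundaries_bp", "inflate_null_q")


def perturb(
    dataset: SyntheticDataset,
    operation: str,
    amount: float,
    seed: Optional[int] = None,
) -> SyntheticDataset:
    """Apply a named perturbation; the returned truth is annotated with the
    planted items expected to become unrecoverable.

    drop_atac_fraction
        Remove the ATAC peak of ``round(amount * n_true)`` planted enhancers
        (amount in [0,1]); those enhancers and their links become
        unrecoverable.
    shift_tad_boundaries_bp
        Shift every interior TAD boundary by ``amount`` bp (signed); links
        whose enhancer and TSS no longer share a domain become unrecoverable.
    inflate_null_q
        Multiply the q-values of non-planted genes by ``amount`` (clipped to
        [0,1]); planted items stay recoverable.
    """
    if operation not in _PERTURBATIONS:
        raise ValueError(f"unknown perturbation {operation!r}; expected one of {_PERTURBATIONS}")
    rng = np.random.default_rng(dataset.config.seed + 1 if seed is None else seed)
    truth = dataset.truth

    if operation == "drop_atac_fraction":
        if not (0.0 <= amount <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        n_drop = int(round(amount * len(truth.enhancer_ids)))
        dropped_ids = sorted(
            rng.choice(truth.enhancer_ids, size=n_drop, replace=False).tolist()
        )
        dropped_peaks = {dataset.atac_by_enhancer[e] for e in dropped_ids}
        new_atac = IntervalSet(
            (iv for iv in dataset.atac if iv not in dropped_peaks), name=dataset.atac.name
        )
        lost_links = [l for l in truth.links if l.enhancer_id in dropped_ids]
        new_truth = dataclasses.replace(
            truth,
            unrecoverable_enhancer_ids=dropped_ids,
            unrecoverable_links=lost_links,
        )
        return dataclasses.replace(dataset, atac=new_atac, truth=new_truth)

    if operation == "shift_tad_boundaries_bp":
        delta = int(amount)
        old = list(dataset.tads)
        bounds = [iv.start for iv in old] + [old[-1].end]
        new_bounds = [bounds[0]] + [
            min(max(b + delta, bounds[0] + 1), bounds[-1] - 1) for b in bounds[1:-1]
        ] + [bounds[-1]]
        if any(b2 <= b1 for b1, b2 in zip(new_bounds, new_bounds[1:])):
            raise ValueError("shift collapses a TAD; use a smaller amount")
        chrom = old[0].chrom
        new_tads = IntervalSet(
            (GenomicInterval(chrom, s, e) for s, e in zip(new_bounds, new_bounds[1:])),
            name=dataset.tads.name,
        )
        tad_list = list(new_tads)

        def tad_of(pos: int) -> Optional[int]:
            for i, t in enumerate(tad_list):
                if t.start <= pos < t.end:
                    return i
            return None

        enh_by_id = dict(zip(truth.enhancer_ids, truth.enhancers))
        gene_by_id = {g.gene_id: g for g in dataset.genes}
        lost = []
        for l in truth.links:
            e_tad = tad_of(enh_by_id[l.enhancer_id].midpoint)
            g = gene_by_id[l.gene_id]
            if e_tad is None or all(tad_of(t) != e_tad for t in g.tss_list):
                lost.append(l)
        new_truth = dataclasses.replace(truth, unrecoverable_links=lost)
        return dataclasses.replace(dataset, tads=new_tads, truth=new_truth)

    # inflate_null_q
    if amount < 0:
        raise ValueError("q multiplier must be >= 0")
    target_set = set(truth.direct_targets)
    new_expression = {}
    for line, records in dataset.expression.items():
        new_expression[line] = [
            r
            if r.gene_id in target_set
            else ExpressionRecord(r.gene_id, r.log2fc, float(min(1.0, r.q_value * amount)))
            for r in records
        ]
    return dataclasses.replace(dataset, expression=new_expression)
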