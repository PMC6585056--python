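"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — per-base boolean masks, exhaustive
all-pairs loops, full hypergeometric enumeration — and shares no code with
the library paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np

from tadlink import GenomicInterval, IntervalSet


def random_interval_set(rng, n, chrom_len, chroms=("c1",), max_width=None, name=""):
    max_width = max_width or max(2, chrom_len // 20)
    ivs = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 1))
        width = int(rng.integers(1, max_width))
        ivs.append(GenomicInterval(chrom, start, min(chrom_len, start + width)))
    return IntervalSet(ivs, name=name)


def coverage_mask(intervals, chrom, chrom_len):
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def intersect_keep_oracle(a, b, min_overlap, chrom_len):
    """Per-element check: count of bases shared with any single b element."""
    kept = []
    for iv in a:
        best = 0
        for other in b:
            if other.chrom != iv.chrom:
                continue
            ov = max(0, min(iv.end, other.end) - max(iv.start, other.start))
            best = max(best, ov)
        if best >= min_overlap:
            kept.append(iv)
    return IntervalSet(kept)


def intersect_keep_mask_oracle(a, b, chrom_len):
    """min_overlap=1 via per-base membership masks (spec's stated oracle)."""
    masks = {}
    kept = []
    for iv in a:
        if iv.chrom not in masks:
            masks[iv.chrom] = coverage_mask(b, iv.chrom, chrom_len)
        if masks[iv.chrom][iv.start : iv.end].any():
            kept.append(iv)
    return IntervalSet(kept)


def covered_bases_oracle(intervals, chroms, chrom_len):
    return sum(int(coverage_mask(intervals, c, chrom_len).sum()) for c in chroms)


def nearest_tss_oracle(peak, genes):
    center = (peak.start + peak.end) // 2
    best = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        for t in g.tss_list:
            d = abs(center - t)
            best = d if best is None else min(best, d)
    return best


def matrix_cell_oracle(track, region, flank, bin_bp):
    """Per-base window fill, then per-bin mean."""
    center = (region.start + region.end) // 2
    w0 = center - flank
    window = np.zeros(2 * flank, dtype=float)
    starts, ends, vals = track.steps(region.chrom)
    for s, e, v in zip(starts, ends, vals):
        lo = max(int(s) - w0, 0)
        hi = min(int(e) - w0, 2 * flank)
        if lo < hi and lo < 2 * flank and hi > 0:
            window[lo:hi] = v
    return window.reshape(-1, bin_bp).mean(axis=1)


def fisher_enumeration_oracle(both, a_only, b_only, neither, sided):
    """Exact hypergeometric p by full enumeration of the support."""
    r1, r2 = both + a_only, b_only + neither
    c1 = both + b_only
    total = r1 + r2
    denom = comb(total, c1)
    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    probs = {k: comb(r1, k) * comb(r2, c1 - k) / denom for k in support}
    if sided == "one_sided_less":
        return sum(p for k, p in probs.items() if k <= both)
    observed = probs[both]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-7)))
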