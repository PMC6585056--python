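"""Peak-centered signal matrices and aggregate profiles.

A :class:`SignalTrack` is a sparse step function per chromosome (bedGraph
semantics: positions not covered by a step have value 0).  For each input
region, :func:`compute_matrix` evaluates the length-weighted mean signal in
fixed-width bins across the window ``[center - flank, center + flank)`` —
the standard reference-point heatmap computation.  Rows can then be ordered
by descending window occupancy (row mean), optionally taken from a reference
matrix so several tracks can share one row order for side-by-side heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet

__all__ = [
    "SignalTrack",
    "ProfileMatrix",
    "read_bedgraph",
    "write_bedgraph",
    "compute_matrix",
    "order_rows_by_occupancy",
    "aggregate_profile",
]


class SignalTrack:
    """A chromosome-addressed step function; uncovered positions are 0.

    Steps must be non-overlapping within a chromosome (validated); they are
    stored per chromosome as sorted (starts, ends, values) arrays.
    """

    def __init__(self, steps: Iterable[tuple[GenomicInterval, float]]):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for iv, val in steps:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, float(val)))
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            vals = np.array([t[2] for t in triples], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping signal steps on {chrom}")
            self._data[chrom] = (starts, ends, vals)

    def steps(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted (starts, ends, values) arrays for one chromosome."""
        return self._data.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64)),
        )

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def __iter__(self):
        for chrom in self.chroms:
            starts, ends, vals = self._data[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield GenomicInterval(chrom, int(s), int(e)), float(v)


def read_bedgraph(path: Union[str, Path]) -> SignalTrack:
    """Read a bedGraph file into a step-function track (absent positions 0)."""
    steps = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            steps.append(
                (GenomicInterval(fields[0], int(fields[1]), int(fields[2])), float(fields[3]))
            )
    return SignalTrack(steps)


def write_bedgraph(track: SignalTrack, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv, val in track:
            # repr round-trips float64 exactly, so read(write(t)) == t
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val!r}\n")


@dataclass
class ProfileMatrix:
    """Per-region binned signal: rows = regions, columns = window bins.

    ``data`` is indexed by region id ("chrom:start-end"); columns are bin
    start offsets relative to the region center.
    """

    data: pd.DataFrame
    flank_bp: int
    bin_bp: int

    @property
    def region_ids(self) -> list[str]:
        return list(self.data.index)

    def row_means(self) -> pd.Series:
        """Mean signal per region over the full window ('occupancy')."""
        return self.data.mean(axis=1)


def region_id(iv: GenomicInterval) -> str:
    return str(iv)


def compute_matrix(
    track: SignalTrack,
    regions: IntervalSet,
    flank_bp: int = 5_000,
    bin_bp: int = 50,
) -> ProfileMatrix:
    """Binned signal around each region center, window = center +/- flank.

    Each bin holds the length-weighted mean of the step function over the
    bin's span; bases outside the chromosome (windows truncated at position
    0) and bases not covered by any step contribute 0.
    """
    if flank_bp <= 0 or bin_bp <= 0:
        raise ValueError("flank_bp and bin_bp must be positive")
    if flank_bp % bin_bp != 0:
        raise ValueError(f"flank_bp ({flank_bp}) must be divisible by bin_bp ({bin_bp})")
    n_bins = 2 * flank_bp // bin_bp
    ivs = sorted(regions)
    rows = np.zeros((len(ivs), n_bins), dtype=np.float64)
    for i, iv in enumerate(ivs):
        w0 = iv.midpoint - flank_bp
        w1 = iv.midpoint + flank_bp
        starts, ends, vals = track.steps(iv.chrom)
        lo = int(np.searchsorted(ends, w0, side="right"))
        hi = int(np.searchsorted(starts, w1, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
            s = max(int(s), w0)
            e = min(int(e), w1)
            if s >= e:
                continue
            b0 = (s - w0) // bin_bp
            b1 = (e - 1 - w0) // bin_bp
            for b in range(b0, b1 + 1):
                bin_start = w0 + b * bin_bp
                ov = min(e, bin_start + bin_bp) - max(s, bin_start)
                rows[i, b] += v * ov
    rows /= bin_bp
    offsets = [-flank_bp + b * bin_bp for b in range(n_bins)]
    df = pd.DataFrame(rows, index=[region_id(iv) for iv in ivs], columns=offsets)
    return ProfileMatrix(df, flank_bp, bin_bp)


def order_rows_by_occupancy(
    matrix: ProfileMatrix, reference: Optional[ProfileMatrix] = None
) -> ProfileMatrix:
    """Sort rows by descending occupancy (row mean), ties by region id.

    When ``reference`` is given its row means define the order — the usual
    way to display several marks under one track's ordering — and it must
    contain exactly the same region ids.
    """
    ref = reference if reference is not None else matrix
    if set(ref.data.index) != set(matrix.data.index):
        raise ValueError("reference matrix has different region ids")
    means = ref.row_means()
    order = sorted(matrix.data.index, key=lambda rid: (-means[rid], rid))
    return ProfileMatrix(matrix.data.loc[order], matrix.flank_bp, matrix.bin_bp)


def aggregate_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column means across regions — the aggregate (meta) profile."""
    if matrix.data.empty:
        raise ValueError("cannot aggregate an empty matrix")
    return matrix.data.to_numpy().mean(axis=0)
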