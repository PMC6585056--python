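"""Readers and writers for the plain-text genomics formats the pipeline touches.

Supported dialects: BED3/BED6, narrowPeak, broadPeak, bedGraph, minimal GTF
(``gene`` feature lines only) and headered TSV expression tables.  Everything
is tab-separated UTF-8; all readers return sorted containers (intervals by
coordinate, genes and expression records by gene id) so downstream results
are order-independent by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "ExpressionRecord",
    "ParseError",
    "SchemaError",
    "INTERVAL_DIALECTS",
    "read_intervals",
    "write_bed",
    "read_gene_models",
    "write_gene_models_bed6",
    "read_expression_table",
    "write_expression_table",
]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


@dataclass
class GeneModel:
    """A gene with strand, one or more TSS coordinates and an activity flag.

    The TSS is strand-dependent: for ``+`` genes the first transcribed base is
    the interval start, for ``-`` genes it is ``end - 1`` (the last covered
    base in half-open coordinates).  ``active`` is set later from promoter
    H3K27ac evidence; it defaults to False.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int] = field(default_factory=list)
    active: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id!r} has no TSS")
        if any(t < 0 for t in self.tss_list):
            raise ValueError(f"gene {self.gene_id!r} has a negative TSS")
        self.tss_list = sorted(set(self.tss_list))


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's knockout-vs-parental log2 fold change and FDR q-value."""

    gene_id: str
    log2fc: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(
                f"q_value for {self.gene_id!r} outside [0,1]: {self.q_value}"
            )
        if not math.isfinite(self.log2fc):
            raise ValueError(f"non-finite log2fc for {self.gene_id!r}")


#: dialect -> minimum number of tab-separated columns
INTERVAL_DIALECTS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "broadPeak": 9}

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: Union[str, Path]):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_intervals(path: Union[str, Path], dialect: str = "bed3") -> IntervalSet:
    """Read peak/region intervals from a BED-family file.

    Columns beyond the dialect's required count are ignored; ``track``,
    ``browser`` and ``#`` lines are skipped.  Coordinates are validated
    (``start < end``) and the returned set is coordinate-sorted.
    """
    try:
        min_cols = INTERVAL_DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; expected one of {sorted(INTERVAL_DIALECTS)}"
        ) from None
    intervals = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < min_cols:
            raise ParseError(
                f"{path}: line {lineno}: expected >= {min_cols} columns "
                f"for {dialect}, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ParseError(
                f"{path}: line {lineno}: non-integer coordinates"
            ) from None
        if start < 0 or start >= end:
            raise ParseError(
                f"{path}: line {lineno}: invalid interval {fields[0]}:{start}-{end}"
            )
        intervals.append(GenomicInterval(fields[0], start, end))
    return IntervalSet(intervals, name=Path(path).stem)


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: Union[str, Path],
    names: Iterable[str] = None,
    scores: Iterable[float] = None,
    strands: Iterable[str] = None,
) -> None:
    """Write intervals as BED3, or BED6 when names/scores/strands are given."""
    ivs = sorted(intervals)
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    strands = list(strands) if strands is not None else None
    with open(path, "w", encoding="utf-8") as fh:
        for i, iv in enumerate(ivs):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None or scores is not None or strands is not None:
                cols.append(names[i] if names is not None else f"region_{i}")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(strands[i] if strands is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_gene_models(path: Union[str, Path], dialect: str = "bed6") -> list[GeneModel]:
    """Read gene models; TSS is computed strand-aware from the feature span.

    bed6: the name column holds the gene id.  gtf_minimal: only ``gene``
    feature lines are used and the gene id comes from the ``gene_id``
    attribute; GTF coordinates are 1-based inclusive and are converted.
    Duplicate gene ids merge their TSSs into one model; output sorted by id.
    """
    collected: dict[str, GeneModel] = {}

    def add(gene_id: str, chrom: str, start: int, end: int, strand: str, lineno: int):
        if strand not in ("+", "-"):
            raise ParseError(f"{path}: line {lineno}: unknown strand {strand!r}")
        tss = start if strand == "+" else end - 1
        if gene_id in collected:
            g = collected[gene_id]
            if g.chrom != chrom or g.strand != strand:
                raise ParseError(
                    f"{path}: line {lineno}: gene {gene_id!r} re-annotated on a "
                    "different chromosome or strand"
                )
            g.tss_list = sorted(set(g.tss_list) | {tss})
        else:
            collected[gene_id] = GeneModel(gene_id, chrom, strand, [tss])

    if dialect == "bed6":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns")
            add(fields[3], fields[0], int(fields[1]), int(fields[2]), fields[5], lineno)
    elif dialect == "gtf_minimal":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(
                item.strip().split(" ", 1)
                for item in fields[8].rstrip(";").split(";")
                if item.strip()
            )
            gene_id = attrs.get("gene_id", "").strip('"')
            if not gene_id:
                raise ParseError(f"{path}: line {lineno}: missing gene_id attribute")
            # GTF is 1-based inclusive -> half-open 0-based
            add(gene_id, fields[0], int(fields[3]) - 1, int(fields[4]), fields[6], lineno)
    else:
        raise ValueError(f"unknown gene dialect {dialect!r}")
    return [collected[k] for k in sorted(collected)]


def write_gene_models_bed6(genes: Iterable[GeneModel], path: Union[str, Path]) -> None:
    """Write one BED6 line per TSS; the span is the single TSS base."""
    rows = []
    for g in genes:
        for tss in g.tss_list:
            # the span is the single TSS base regardless of strand
            rows.append((g.chrom, tss, tss + 1, g.gene_id, 0, g.strand))
    rows.sort(key=lambda r: (r[3], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


_EXPR_COLUMNS = ("gene_id", "log2fc", "q_value")


def read_expression_table(path: Union[str, Path]) -> list[ExpressionRecord]:
    """Read a headered TSV of per-gene log2FC and q-value.

    Column matching is case-insensitive and order-free.  Rows whose log2fc is
    non-finite (infinite fold-change encodings from the upstream caller) are
    excluded with a logged count rather than failing the whole table.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in _EXPR_COLUMNS if c not in colmap]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    records = []
    n_dropped = 0
    for _, row in df.iterrows():
        lfc = float(row[colmap["log2fc"]])
        if not math.isfinite(lfc):
            n_dropped += 1
            continue
        records.append(
            ExpressionRecord(
                gene_id=str(row[colmap["gene_id"]]),
                log2fc=lfc,
                q_value=float(row[colmap["q_value"]]),
            )
        )
    if n_dropped:
        logger.warning("%s: excluded %d rows with non-finite log2fc", path, n_dropped)
    records.sort(key=lambda r: r.gene_id)
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: Union[str, Path]) -> None:
    rows = sorted(records, key=lambda r: r.gene_id)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tlog2fc\tq_value\n")
        for r in rows:
            fh.write(f"{r.gene_id}\t{r.log2fc:.6g}\t{r.q_value:.6g}\n")
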