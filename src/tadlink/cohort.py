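"""Cohort-level summaries: IHC staining percentages and 2x2 mutual exclusivity.

Immunohistochemistry cohorts are summarized as percentages of strongly
positive (++), weakly positive (+) and negative tumors, rounded half-up to
one decimal as such tables are conventionally printed.

Mutation mutual exclusivity between two genes is tested on the 2x2 patient
table (both / A-only / B-only / neither) with Fisher's exact test.  The
directional claim — a *deficit* of double-mutant patients — is the
one-sided "less" alternative and is the default; the two-sided test is also
available.  Results carry -log10(p) for plotting alongside an odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats

__all__ = ["IhcCounts", "MutationTable2x2", "FisherResult", "ihc_percentages", "fisher_exact"]


@dataclass(frozen=True)
class IhcCounts:
    """Patient counts per IHC staining category."""

    strong_pos: int
    weak_pos: int
    negative: int

    def __post_init__(self) -> None:
        if min(self.strong_pos, self.weak_pos, self.negative) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.strong_pos + self.weak_pos + self.negative


@dataclass(frozen=True)
class MutationTable2x2:
    """2x2 patient table for two genes A and B."""

    both: int
    a_only: int
    b_only: int
    neither: int

    def __post_init__(self) -> None:
        if min(self.both, self.a_only, self.b_only, self.neither) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    minus_log10_p: float
    haldane_corrected: bool  # True when 0.5 was added to every cell for the OR


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def ihc_percentages(counts: IhcCounts) -> dict:
    """Category percentages of the cohort, rounded half-up to one decimal.

    Returns both the rounded values (as printed) and the raw unrounded ones.
    """
    if counts.total <= 0:
        raise ValueError("cannot compute percentages of an empty cohort")
    raw = {
        "strong_pos": 100.0 * counts.strong_pos / counts.total,
        "weak_pos": 100.0 * counts.weak_pos / counts.total,
        "negative": 100.0 * counts.negative / counts.total,
    }
    return {
        "rounded": {k: _round_half_up_1dp(v) for k, v in raw.items()},
        "raw": raw,
        "total": counts.total,
    }


def fisher_exact(table: MutationTable2x2, sided: str = "one_sided_less") -> FisherResult:
    """Fisher's exact test on a 2x2 mutation table.

    ``one_sided_less`` (default) tests for a deficit of double mutants —
    mutual exclusivity; ``two_sided`` sums all tables whose point probability
    does not exceed the observed one.  The odds ratio is the cross product
    (both*neither)/(a_only*b_only), with 0.5 added to every cell when any
    cell is zero (flagged in the result).
    """
    if table.total <= 0:
        raise ValueError("table total must be > 0")
    alternatives = {"two_sided": "two-sided", "one_sided_less": "less"}
    if sided not in alternatives:
        raise ValueError(f"sided must be one of {sorted(alternatives)}")
    ctab = [[table.both, table.a_only], [table.b_only, table.neither]]
    p = float(stats.fisher_exact(ctab, alternative=alternatives[sided]).pvalue)
    p = min(p, 1.0)
    b, ao, bo, n = table.both, table.a_only, table.b_only, table.neither
    corrected = 0 in (b, ao, bo, n)
    if corrected:
        b, ao, bo, n = b + 0.5, ao + 0.5, bo + 0.5, n + 0.5
    odds_ratio = (b * n) / (ao * bo)
    return FisherResult(
        p_value=p,
        odds_ratio=odds_ratio,
        minus_log10_p=-math.log10(p) if p > 0 else math.inf,
        haldane_corrected=corrected,
    )
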