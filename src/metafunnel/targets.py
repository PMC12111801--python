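"""Target-fishing aggregation: prediction frequencies and half-max selection.

Per-metabolite target predictions (SwissTargetPrediction-style exports) are
tallied into cumulative frequencies per gene, the carbonic-anhydrase family is
excluded, and the genes whose frequency exceeds half the maximum frequency are
selected. Two prediction models (e.g. a database-derived and a
literature-derived metabolite inventory) are compared by set intersection.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

DEFAULT_BLACKLIST = (r"^CA\d+[A-Z]?$",)  # carbonic anhydrases


class NoPredictionsError(ValueError):
    pass


class AllExcludedError(ValueError):
    pass


@dataclass(frozen=True)
class TargetPrediction:
    metabolite_id: str
    gene_symbol: str
    uniprot: str | None = None
    probability: float | None = None


@dataclass
class TargetFrequencyTable:
    """Gene -> number of distinct metabolites predicted to hit it."""

    counts: dict[str, int]
    max_count: int = 0
    threshold: float | None = None
    selected: set[str] = field(default_factory=set)
    excluded_families: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene": g,
                "count": c,
                "selected": g in self.selected,
                "excluded": False,
            }
            for g, c in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        rows += [
            {"gene": g, "count": 0, "selected": False, "excluded": True}
            for g in sorted(self.excluded_families)
        ]
        return pd.DataFrame(rows, columns=["gene", "count", "selected", "excluded"])


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def aggregate_frequencies(
    predictions: Iterable[TargetPrediction] | pd.DataFrame,
) -> TargetFrequencyTable:
    """Tally distinct (metabolite, gene) pairs into per-gene counts.

    Counting is binary per metabolite: a metabolite listed twice against the
    same gene contributes one.
    """
    if isinstance(predictions, pd.DataFrame):
        pairs = {
            (str(m), normalize_symbol(str(g)))
            for m, g in zip(predictions["metabolite_id"], predictions["gene_symbol"])
        }
    else:
        pairs = {
            (p.metabolite_id, normalize_symbol(p.gene_symbol)) for p in predictions
        }
    if not pairs:
        raise NoPredictionsError("no predictions supplied")
    counts: dict[str, int] = {}
    for _, gene in pairs:
        counts[gene] = counts.get(gene, 0) + 1
    return TargetFrequencyTable(counts=counts, max_count=max(counts.values()))


def exclude_families(
    table: TargetFrequencyTable,
    blacklist_patterns: Sequence[str] = DEFAULT_BLACKLIST,
) -> TargetFrequencyTable:
    """Drop genes matching any pattern and recompute the maximum frequency."""
    if not blacklist_patterns:
        return table
    compiled = [re.compile(p) for p in blacklist_patterns]
    excluded = {g for g in table.counts if any(rx.match(g) for rx in compiled)}
    counts = {g: c for g, c in table.counts.items() if g not in excluded}
    return TargetFrequencyTable(
        counts=counts,
        max_count=max(counts.values()) if counts else 0,
        excluded_families=set(table.excluded_families) | excluded,
    )


def select_above_half_max(
    table: TargetFrequencyTable, inclusive: bool = False
) -> TargetFrequencyTable:
    """Select genes whose count exceeds half the maximum count.

    ``inclusive=True`` keeps exact ties with the half-max threshold; the
    default is the strict reading of "above 50% of the maximum frequency".
    """
    if not table.counts:
        raise AllExcludedError("no genes left to select from")
    threshold = 0.5 * table.max_count
    if inclusive:
        selected = {g for g, c in table.counts.items() if c >= threshold}
    else:
        selected = {g for g, c in table.counts.items() if c > threshold}
    return TargetFrequencyTable(
        counts=dict(table.counts),
        max_count=table.max_count,
        threshold=threshold,
        selected=selected,
        excluded_families=set(table.excluded_families),
    )


def intersect_models(selected_a: Iterable[str], selected_b: Iterable[str]) -> list[str]:
    """Sorted intersection of two models' selected gene sets."""
    a = {normalize_symbol(g) for g in selected_a}
    b = {normalize_symbol(g) for g in selected_b}
    return sorted(a & b)


def run_target_selection(
    predictions: Iterable[TargetPrediction] | pd.DataFrame,
    blacklist_patterns: Sequence[str] = DEFAULT_BLACKLIST,
    inclusive: bool = False,
    exclude_first: bool = True,
) -> TargetFrequencyTable:
    """Full stage: aggregate, blacklist the CA family, threshold.

    ``exclude_first`` controls whether family exclusion happens before the
    half-max rule (the narrative order) or after it.
    """
    table = aggregate_frequencies(predictions)
    if exclude_first:
        table = exclude_families(table, blacklist_patterns)
        return select_above_half_max(table, inclusive=inclusive)
    thresholded = select_above_half_max(table, inclusive=inclusive)
    reduced = exclude_families(thresholded, blacklist_patterns)
    reduced.threshold = thresholded.threshold
    reduced.selected = {g for g in thresholded.selected if g in reduced.counts}
    return reduced
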