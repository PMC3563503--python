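"""Evaluation against a gold standard: recall, cumulative-TF curve,
set overlaps.

The gold standard is a list of TF gene symbols compiled from published
expression studies of the target tissue.  Because gene symbols drift
across species and databases, matching is done on a normalized form
(uppercase, hyphens stripped — so "c-fos" matches CFOS), and a printed
alias pair like "ASCL2/MASH2" forms one alias group counted as retrieved
if any alias is predicted.  Recall is the only headline metric: the
pipeline is a recall-oriented candidate screen, and precision against an
open-ended literature is not measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip hyphens/whitespace: the matching form."""
    return symbol.upper().replace("-", "").strip()


@dataclass
class GoldStandard:
    """Reference TF symbols; '/'-joined aliases form one entry."""

    entries: list[frozenset[str]]  # normalized alias groups
    labels: list[str]  # display label per entry (first printed form)
    source: str = "gold-standard"

    @staticmethod
    def from_symbols(symbols: Iterable[str], source: str = "gold-standard") -> "GoldStandard":
        entries, labels = [], []
        seen = set()
        for raw in sorted(set(symbols)):
            aliases = frozenset(
                normalize_symbol(part) for part in raw.split("/") if part.strip()
            )
            if not aliases or aliases in seen:
                continue
            seen.add(aliases)
            entries.append(aliases)
            labels.append(raw.split("/")[0].strip().upper())
        if not entries:
            raise ValueError("gold standard is empty")
        return GoldStandard(entries=entries, labels=labels, source=source)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class EvaluationReport:
    """Recall plus the supporting detail (missed genes, curve, overlaps)."""

    recall_percent: float
    retrieved: set[str]
    missed: list[str]
    gold_size: int
    curve: Optional[list[tuple[int, int]]] = None
    overlaps: Optional[dict[str, int]] = None


def _round1(value: Decimal) -> float:
    return float(value.quantize(Decimal("0.1"), ROUND_HALF_UP))


def recall(predicted: Iterable[str], gold: GoldStandard) -> EvaluationReport:
    """Fraction of gold entries retrieved, as a one-decimal percentage.

    An alias group counts as retrieved if any alias is predicted; missed
    entries are reported sorted by display label.  Rounding is half-up to
    one decimal (61/64 -> 95.3).
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    predicted_norm = {normalize_symbol(s) for s in predicted}
    retrieved, missed = set(), []
    for aliases, label in zip(gold.entries, gold.labels):
        if aliases & predicted_norm:
            retrieved.add(label)
        else:
            missed.append(label)
    percent = _round1(Decimal(100) * len(retrieved) / len(gold))
    return EvaluationReport(
        recall_percent=percent,
        retrieved=retrieved,
        missed=sorted(missed),
        gold_size=len(gold),
    )


def cumulative_tf_curve(
    ranked: Sequence[str], tf_set: Iterable[str]
) -> list[tuple[int, int]]:
    """Cumulated TF count along a ranked gene list.

    Point r is |{first r genes} ∩ TF set|; the curve is non-decreasing
    with unit steps exactly at TF positions.  The ranked list must be
    duplicate-free.
    """
    if len(set(ranked)) != len(ranked):
        raise ValueError("ranked list contains duplicates")
    tf_norm = {normalize_symbol(s) for s in tf_set}
    curve, count = [], 0
    for r, gene in enumerate(ranked, start=1):
        if normalize_symbol(gene) in tf_norm:
            count += 1
        curve.append((r, count))
    return curve


def overlap_counts(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Inclusion-exclusion region counts for 2 or 3 named sets.

    Region labels join member-set names with '&' in input order; every
    element of the union lands in exactly one region, so region counts
    sum to |union|.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_counts supports exactly 2 or 3 sets")
    materialized = {name: set(sets[name]) for name in names}
    regions: dict[str, int] = {}
    for size in range(1, len(names) + 1):
        for combo in combinations(names, size):
            inside = set.intersection(*(materialized[n] for n in combo))
            outside = set.union(
                *(materialized[n] for n in names if n not in combo), set()
            )
            regions["&".join(combo)] = len(inside - outside)
    return regions
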