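"""Cross-tabulations of the RI corpus by type, confidence, and category.

Category reflects the sources of the full evidence set (binding and
function): experimental categories dominate, so computational or other
nonexperimental codes never demote an RI that also has experimental
support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from riconf import confidence_engine as ce
from riconf.evidence_catalog import (
    Category as CodeCategory,
    ConfidenceLevel,
    EvidenceCatalog,
)
from riconf.riset_io import Category, RIType, RegulatoryInteraction

__all__ = [
    "ArchitectureSummary",
    "assign_category",
    "combination_counts",
    "summarize",
]


def assign_category(
    ri: RegulatoryInteraction, catalog: EvidenceCatalog
) -> Category:
    """Category over binding plus function evidence.

    classical only -> classical; HT only -> ht; both -> classical_and_ht;
    no experimental code at all -> nonexperimental.
    """
    has_classical = has_ht = False
    for code in ri.binding_evidence | ri.function_evidence:
        entry = catalog.get(code)
        if entry is None:
            continue
        if entry.category is CodeCategory.CLASSICAL:
            has_classical = True
        elif entry.category is CodeCategory.HT:
            has_ht = True
    if has_classical and has_ht:
        return Category.CLASSICAL_AND_HT
    if has_classical:
        return Category.CLASSICAL
    if has_ht:
        return Category.HT
    return Category.NONEXPERIMENTAL


@dataclass
class ArchitectureSummary:
    """Deterministic tabulation of (RI type, confidence, category) counts."""

    counts: Counter = field(default_factory=Counter)
    combination_counts: dict[ConfidenceLevel, Counter] = field(default_factory=dict)
    n_total: int = 0

    def count(
        self,
        ri_type: RIType | None = None,
        confidence: ConfidenceLevel | None = None,
        category: Category | None = None,
    ) -> int:
        return sum(
            n
            for (t, lvl, cat), n in self.counts.items()
            if (ri_type is None or t is ri_type)
            and (confidence is None or lvl is confidence)
            and (category is None or cat is category)
        )

    def percent(
        self, ri_type: RIType, confidence: ConfidenceLevel | None = None
    ) -> float:
        """Percent relative to the RI-type total, rounded to one decimal."""
        total = self.count(ri_type=ri_type)
        if total == 0:
            return 0.0
        return round(100.0 * self.count(ri_type=ri_type, confidence=confidence) / total, 1)

    def to_rows(self) -> list[list[str]]:
        rows = [["ri_type", "confidence", "category", "count", "percent_of_type"]]
        for (t, lvl, cat), n in sorted(
            self.counts.items(), key=lambda kv: (kv[0][0].value, kv[0][1].rank, kv[0][2].value)
        ):
            type_total = self.count(ri_type=t)
            rows.append(
                [
                    t.value,
                    lvl.value,
                    cat.value,
                    str(n),
                    f"{100.0 * n / type_total:.1f}",
                ]
            )
        return rows


def summarize(
    ris: Sequence[RegulatoryInteraction],
    catalog: EvidenceCatalog,
    ruleset: ce.RuleSet = ce.DEFAULT_RULES,
) -> ArchitectureSummary:
    """Tabulate the corpus; confidence and category are recomputed here."""
    summary = ArchitectureSummary(n_total=len(ris))
    for ri in ris:
        level = ce.assign_confidence(ri, catalog, ruleset)
        category = assign_category(ri, catalog)
        summary.counts[(ri.ri_type, level, category)] += 1
        summary.combination_counts.setdefault(level, Counter())[
            frozenset(ri.binding_evidence)
        ] += 1
    return summary


def combination_counts(
    ris: Sequence[RegulatoryInteraction],
    level: ConfidenceLevel,
    catalog: EvidenceCatalog,
    ruleset: ce.RuleSet = ce.DEFAULT_RULES,
    display_map: Mapping[str, str] | None = None,
) -> Counter:
    """Upset-style counts of exact binding-evidence combinations at a level.

    Keys are frozensets of display labels (per ``display_map``, defaulting
    to raw codes); values are RI counts.  The sum over keys equals the
    number of RIs at the level.
    """
    counter: Counter = Counter()
    for ri in ris:
        if ce.assign_confidence(ri, catalog, ruleset) is not level:
            continue
        if display_map:
            key = frozenset(display_map.get(c, c) for c in ri.binding_evidence)
        else:
            key = frozenset(ri.binding_evidence)
        counter[key] += 1
    return counter


def combination_rows(counter: Counter) -> list[list[str]]:
    """Plot-ready long table: one row per combination, codes sorted and joined."""
    rows = [["combination", "n_codes", "count"]]
    for key, n in sorted(counter.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        rows.append(["+".join(sorted(key)) if key else "(none)", str(len(key)), str(n)])
    return rows
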