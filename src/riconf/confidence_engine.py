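"""Additive-evidence confidence assignment for regulatory interactions.

Each RI starts at the base level of its binding evidence (strong iff any
code sits in group 1 or 2, weak otherwise).  Combinations of evidence from
*independent* groups upgrade the level, gated on the presence of functional
(expression) evidence.  The default rule set:

  1. two distinct weak groups (4-7)              -> strong
  2. two distinct strong groups (1-2)            -> confirmed
  3. two distinct weak groups + one strong group -> confirmed
  4. four distinct weak groups                   -> confirmed

Distinctness is always counted over independence groups, never over raw
codes: two group-4 codes (e.g. ChIP-seq and ChIP-exo) count once.  Rules
are data — alternative rule sets can be supplied for flexible gold-standard
definitions.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import yaml

from riconf.evidence_catalog import (
    Category,
    ConfidenceLevel,
    EvidenceCatalog,
    STRONG_GROUPS,
    UPGRADE_WEAK_GROUPS,
)
from riconf.riset_io import RegulatoryInteraction

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceRule",
    "RuleSet",
    "DEFAULT_RULES",
    "ExclusionResult",
    "assign_confidence",
    "base_level",
    "recompute_with_exclusions",
    "resolve_exclusions",
]


@dataclass(frozen=True)
class ConfidenceRule:
    """Antecedent counts of distinct groups -> consequent level.

    Weak groups are counted over groups 4-7, strong groups over 1-2.
    """

    min_distinct_weak_groups: int = 0
    min_distinct_strong_groups: int = 0
    requires_function_evidence: bool = True
    consequent: ConfidenceLevel = ConfidenceLevel.STRONG

    def __post_init__(self) -> None:
        if self.min_distinct_weak_groups < 0 or self.min_distinct_strong_groups < 0:
            raise ValueError("rule antecedent counts must be >= 0")
        if self.consequent is ConfidenceLevel.WEAK:
            raise ValueError("rules only upgrade; consequent must exceed weak")

    def satisfied(
        self, n_weak_groups: int, n_strong_groups: int, has_function: bool
    ) -> bool:
        if self.requires_function_evidence and not has_function:
            return False
        return (
            n_weak_groups >= self.min_distinct_weak_groups
            and n_strong_groups >= self.min_distinct_strong_groups
        )


@dataclass(frozen=True)
class RuleSet:
    """Ordered rules; evaluation takes the maximum consequent among those satisfied."""

    rules: tuple[ConfidenceRule, ...]

    def __iter__(self):
        return iter(self.rules)

    def evaluate(
        self, n_weak_groups: int, n_strong_groups: int, has_function: bool
    ) -> ConfidenceLevel | None:
        satisfied = [
            r.consequent
            for r in self.rules
            if r.satisfied(n_weak_groups, n_strong_groups, has_function)
        ]
        return max(satisfied) if satisfied else None

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as handle:
            spec = yaml.safe_load(handle)
        rules = tuple(
            ConfidenceRule(
                min_distinct_weak_groups=int(r.get("min_distinct_weak_groups", 0)),
                min_distinct_strong_groups=int(r.get("min_distinct_strong_groups", 0)),
                requires_function_evidence=bool(
                    r.get("requires_function_evidence", True)
                ),
                consequent=ConfidenceLevel.parse(r["consequent"]),
            )
            for r in spec["rules"]
        )
        return cls(rules)


DEFAULT_RULES = RuleSet(
    rules=(
        ConfidenceRule(2, 0, True, ConfidenceLevel.STRONG),
        ConfidenceRule(0, 2, True, ConfidenceLevel.CONFIRMED),
        ConfidenceRule(2, 1, True, ConfidenceLevel.CONFIRMED),
        ConfidenceRule(4, 0, True, ConfidenceLevel.CONFIRMED),
    )
)


def _known(codes: Iterable[str], catalog: EvidenceCatalog) -> set[str]:
    known = set()
    for code in codes:
        if code in catalog:
            known.add(code)
        else:
            logger.warning("ignoring unknown evidence code %r", code)
    return known


def base_level(
    binding_evidence: Iterable[str], catalog: EvidenceCatalog
) -> ConfidenceLevel:
    """Strong iff any binding code sits in group 1 or 2; weak otherwise."""
    for code in _known(binding_evidence, catalog):
        group = catalog.group_of(code)
        if group in STRONG_GROUPS:
            return ConfidenceLevel.STRONG
    return ConfidenceLevel.WEAK


def _distinct_groups(
    codes: Iterable[str], catalog: EvidenceCatalog
) -> tuple[set[int], set[int]]:
    weak_groups: set[int] = set()
    strong_groups: set[int] = set()
    for code in codes:
        group = catalog.group_of(code)
        if group in UPGRADE_WEAK_GROUPS:
            weak_groups.add(group)
        elif group in STRONG_GROUPS:
            strong_groups.add(group)
    return weak_groups, strong_groups


def assign_confidence(
    ri: RegulatoryInteraction,
    catalog: EvidenceCatalog,
    ruleset: RuleSet = DEFAULT_RULES,
    excluded: frozenset[str] | set[str] = frozenset(),
) -> ConfidenceLevel:
    """Level of one RI from its effective (non-excluded) evidence."""
    binding = _known(ri.binding_evidence, catalog) - set(excluded)
    function = _known(ri.function_evidence, catalog) - set(excluded)
    level = base_level(binding, catalog)
    weak_groups, strong_groups = _distinct_groups(binding, catalog)
    upgraded = ruleset.evaluate(len(weak_groups), len(strong_groups), bool(function))
    if upgraded is not None and upgraded > level:
        level = upgraded
    return level


def resolve_exclusions(
    catalog: EvidenceCatalog,
    codes: Iterable[str] = (),
    categories: Iterable[str | Category] = (),
    groups: Iterable[int] = (),
) -> frozenset[str]:
    """Expand code/category/group selectors to a concrete code set.

    A selector matching nothing logs a warning rather than failing, so that
    exclusion recipes stay portable across catalogs.
    """
    excluded: set[str] = set()
    for code in codes:
        if code not in catalog:
            logger.warning("exclusion selector matched no codes: code=%r", code)
        excluded.add(code)
    for category in categories:
        matched = catalog.codes_in_category(Category(category))
        if not matched:
            logger.warning("exclusion selector matched no codes: category=%r", category)
        excluded |= matched
    for group in groups:
        matched = catalog.codes_in_group(int(group))
        if not matched:
            logger.warning("exclusion selector matched no codes: group=%r", group)
        excluded |= matched
    return frozenset(excluded)


def _histogram(ris: Sequence[RegulatoryInteraction]) -> Counter:
    return Counter(
        ri.confidence.value if ri.confidence else "unassigned" for ri in ris
    )


@dataclass
class ExclusionResult:
    """Refreshed interactions plus before/after confidence histograms."""

    interactions: list[RegulatoryInteraction]
    excluded_codes: frozenset[str]
    histogram_before: Counter = field(default_factory=Counter)
    histogram_after: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.interactions)

    def __len__(self) -> int:
        return len(self.interactions)


def recompute_with_exclusions(
    ris: Sequence[RegulatoryInteraction],
    catalog: EvidenceCatalog,
    ruleset: RuleSet = DEFAULT_RULES,
    excluded_codes: Iterable[str] = (),
    excluded_categories: Iterable[str | Category] = (),
    excluded_groups: Iterable[int] = (),
) -> ExclusionResult:
    """Recalculate every RI's confidence with evidence selectors removed.

    Pure function of its inputs; the excluded codes are dropped from the
    stored evidence sets so downstream filters see the effective evidence.
    """
    excluded = resolve_exclusions(
        catalog,
        codes=excluded_codes,
        categories=excluded_categories,
        groups=excluded_groups,
    )
    before = Counter(
        assign_confidence(ri, catalog, ruleset).value for ri in ris
    )
    refreshed = []
    for ri in ris:
        level = assign_confidence(ri, catalog, ruleset, excluded=excluded)
        refreshed.append(
            replace(
                ri,
                binding_evidence=ri.binding_evidence - excluded,
                function_evidence=ri.function_evidence - excluded,
                confidence=level,
            )
        )
    return ExclusionResult(
        interactions=refreshed,
        excluded_codes=excluded,
        histogram_before=before,
        histogram_after=_histogram(refreshed),
    )
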