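"""Independent brute-force confidence evaluator.

Deliberately shares no code path with the engine: it literally enumerates
candidate code combinations for each upgrade rule and checks the group
independence of every pair by hand.  Used as the ground-truth side of the
oracle-equivalence tests.
"""

from __future__ import annotations

import itertools

from riconf.evidence_catalog import ConfidenceLevel

WEAK_UPGRADE_GROUPS = {4, 5, 6, 7}
STRONG_GROUPS = {1, 2}


def brute_force_level(binding, function, catalog) -> ConfidenceLevel:
    binding = [c for c in binding if c in catalog]
    function = [c for c in function if c in catalog]
    groups = {c: catalog[c].group for c in binding}

    base = ConfidenceLevel.WEAK
    for code in binding:
        if groups[code] in STRONG_GROUPS:
            base = ConfidenceLevel.STRONG

    if not function:
        return base

    def all_pairwise_independent(codes) -> bool:
        return all(
            groups[a] is not None
            and groups[b] is not None
            and groups[a] != groups[b]
            for a, b in itertools.combinations(codes, 2)
        )

    upgraded = base
    # rule 1: two independent weak codes (groups 4-7) -> strong
    for pair in itertools.combinations(binding, 2):
        if all(groups[c] in WEAK_UPGRADE_GROUPS for c in pair) and \
                all_pairwise_independent(pair):
            upgraded = max(upgraded, ConfidenceLevel.STRONG)
    # rule 2: two independent strong codes (groups 1-2) -> confirmed
    for pair in itertools.combinations(binding, 2):
        if all(groups[c] in STRONG_GROUPS for c in pair) and \
                all_pairwise_independent(pair):
            upgraded = max(upgraded, ConfidenceLevel.CONFIRMED)
    # rule 3: two independent weak codes plus one strong code -> confirmed
    for triple in itertools.combinations(binding, 3):
        weak = [c for c in triple if groups[c] in WEAK_UPGRADE_GROUPS]
        strong = [c for c in triple if groups[c] in STRONG_GROUPS]
        if len(weak) == 2 and len(strong) == 1 and all_pairwise_independent(weak):
            upgraded = max(upgraded, ConfidenceLevel.CONFIRMED)
    # rule 4: four mutually independent weak codes -> confirmed
    for quad in itertools.combinations(binding, 4):
        if all(groups[c] in WEAK_UPGRADE_GROUPS for c in quad) and \
                all_pairwise_independent(quad):
            upgraded = max(upgraded, ConfidenceLevel.CONFIRMED)
    return upgraded
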