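"""Recovery of classically supported regulatory sites by HT binding methods.

For each HT method, recovery is measured over the TFs that have both at
least one usable dataset of that method and at least one site in the
filtered RI subset.  A site is recovered when it is fully contained in at
least one same-TF peak.  Sites are counted at the granularity of distinct
coordinate pairs, not RIs.  Methods are compared with a tie-corrected
Kruskal-Wallis test and Bonferroni-adjusted pairwise Mann-Whitney tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from riconf import confidence_engine as ce
from riconf import peak_mapping as pm
from riconf.evidence_catalog import Category, ConfidenceLevel, EvidenceCatalog
from riconf.riset_io import HTMethod, PeakDataset, RegulatoryInteraction

__all__ = [
    "MethodComparison",
    "MethodSummary",
    "PairwiseTest",
    "RecoveryReport",
    "TFRecovery",
    "compare_methods",
    "filter_classical",
    "filter_classical_confirmed",
    "recovery",
]


def filter_classical(
    ris: Sequence[RegulatoryInteraction], catalog: EvidenceCatalog
) -> list[RegulatoryInteraction]:
    """RIs with at least one classical binding-evidence code and a site."""
    classical = catalog.codes_in_category(Category.CLASSICAL)
    return [
        ri
        for ri in ris
        if ri.site is not None and (ri.binding_evidence & classical)
    ]


def filter_classical_confirmed(
    ris: Sequence[RegulatoryInteraction],
    catalog: EvidenceCatalog,
    ruleset: ce.RuleSet = ce.DEFAULT_RULES,
) -> list[RegulatoryInteraction]:
    """Confirmed-without-HT RIs that still carry classical binding evidence.

    Confidence is recomputed with every HT code excluded before filtering,
    so the subset owes nothing to the methods being benchmarked.
    """
    refreshed = ce.recompute_with_exclusions(
        ris, catalog, ruleset=ruleset, excluded_categories=[Category.HT]
    )
    classical = catalog.codes_in_category(Category.CLASSICAL)
    return [
        ri
        for ri in refreshed.interactions
        if ri.site is not None
        and ri.confidence is ConfidenceLevel.CONFIRMED
        and (ri.binding_evidence & classical)
    ]


@dataclass(frozen=True)
class TFRecovery:
    n_sites: int
    n_recovered: int

    @property
    def fraction(self) -> float:
        """Percent of this TF's sites recovered."""
        return 100.0 * self.n_recovered / self.n_sites


@dataclass(frozen=True)
class MethodSummary:
    mean: float  # unweighted mean percent over eligible TFs
    sd: float  # sample (n-1) standard deviation
    pooled: float  # count-weighted percent over all sites
    n_tfs: int
    n_sites: int
    n_recovered: int


@dataclass
class RecoveryReport:
    per_tf: dict[tuple[HTMethod, str], TFRecovery] = field(default_factory=dict)
    per_method: dict[HTMethod, MethodSummary] = field(default_factory=dict)
    policy_mode: pm.PolicyMode = pm.PolicyMode.AS_REPORTED

    def fractions(self, method: HTMethod) -> list[float]:
        return [
            rec.fraction for (m, _), rec in sorted(self.per_tf.items()) if m is method
        ]


def _sites_by_tf(
    ris: Sequence[RegulatoryInteraction],
) -> dict[str, set[tuple[int, int]]]:
    sites: dict[str, set[tuple[int, int]]] = {}
    for ri in ris:
        if ri.site is not None:
            sites.setdefault(ri.tf_name.casefold(), set()).add(
                (ri.site.left, ri.site.right)
            )
    return sites


def recovery(
    ris_subset: Sequence[RegulatoryInteraction],
    datasets: Sequence[PeakDataset],
    policy: pm.PeakPolicy,
) -> RecoveryReport:
    """Per-TF and per-method recovery fractions of distinct sites.

    Methods with zero eligible TFs are absent from the report, not zero.
    """
    from riconf.riset_io import GenomicInterval

    sites_by_tf = _sites_by_tf(ris_subset)
    report = RecoveryReport(policy_mode=policy.mode)

    peaks_by_method_tf: dict[tuple[HTMethod, str], list] = {}
    tfs_with_data: dict[HTMethod, set[str]] = {}
    for ds in datasets:
        if ds.no_cutoff:
            continue
        for peak in ds.peaks:
            key = (ds.method, peak.tf_name.casefold())
            peaks_by_method_tf.setdefault(key, []).append(
                pm.normalize_peak(peak, policy)
            )
            tfs_with_data.setdefault(ds.method, set()).add(peak.tf_name.casefold())

    for method, tfs in sorted(tfs_with_data.items(), key=lambda kv: kv[0].value):
        fractions = []
        total_sites = total_recovered = 0
        for tf in sorted(tfs):
            tf_sites = sites_by_tf.get(tf)
            if not tf_sites:
                continue  # TF has a dataset but no site in the filtered set
            intervals = peaks_by_method_tf.get((method, tf), [])
            n_recovered = sum(
                1
                for (left, right) in tf_sites
                if any(
                    iv.contains(GenomicInterval(left=left, right=right))
                    for iv in intervals
                )
            )
            rec = TFRecovery(n_sites=len(tf_sites), n_recovered=n_recovered)
            report.per_tf[(method, tf)] = rec
            fractions.append(rec.fraction)
            total_sites += rec.n_sites
            total_recovered += rec.n_recovered
        if not fractions:
            continue
        arr = np.asarray(fractions)
        report.per_method[method] = MethodSummary(
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)) if len(fractions) > 1 else 0.0,
            pooled=100.0 * total_recovered / total_sites,
            n_tfs=len(fractions),
            n_sites=total_sites,
            n_recovered=total_recovered,
        )
    return report


@dataclass(frozen=True)
class PairwiseTest:
    method_a: HTMethod
    method_b: HTMethod
    u_statistic: float
    p_raw: float
    p_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_adjusted < 0.05


@dataclass
class MethodComparison:
    kw_statistic: float
    kw_pvalue: float
    pairwise: list[PairwiseTest] = field(default_factory=list)


def compare_methods(report: RecoveryReport) -> MethodComparison:
    """Kruskal-Wallis over per-TF fractions plus Bonferroni pairwise tests."""
    groups = {
        method: report.fractions(method)
        for method in report.per_method
        if report.fractions(method)
    }
    if len(groups) < 2:
        raise ValueError("need at least two methods with data to compare")
    ordered = sorted(groups, key=lambda m: m.value)
    samples = [groups[m] for m in ordered]

    flat = list(itertools.chain.from_iterable(samples))
    if len(set(flat)) == 1:
        # degenerate: every observation identical; H = 0 by definition
        kw_stat, kw_p = 0.0, 1.0
    else:
        kw_stat, kw_p = stats.kruskal(*samples)

    pairs = list(itertools.combinations(ordered, 2))
    comparison = MethodComparison(kw_statistic=float(kw_stat), kw_pvalue=float(kw_p))
    for a, b in pairs:
        if set(groups[a]) == set(groups[b]) and len(set(groups[a])) == 1:
            u, p = len(groups[a]) * len(groups[b]) / 2.0, 1.0
        else:
            u, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        comparison.pairwise.append(
            PairwiseTest(
                method_a=a,
                method_b=b,
                u_statistic=float(u),
                p_raw=float(p),
                p_adjusted=min(1.0, float(p) * len(pairs)),
            )
        )
    return comparison
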