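from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from _oracle import brute_force_level
from conftest import (
    BPP,
    CHIP_SEQ,
    COMP,
    EXPRESSION,
    EXTRACT,
    GSELEX,
    MUT,
    make_ri,
)
from riconf import peak_mapping as pm
from riconf import recovery_benchmark as rb
from riconf.evidence_catalog import ConfidenceLevel
from riconf.riset_io import HTMethod, Peak, PeakDataset


def peak(tf, left, right, method=HTMethod.CHIP_SEQ, dataset_id="d1"):
    return Peak(tf_name=tf, method=method, left=left, right=right,
                dataset_id=dataset_id, genome_version="U00096.3")


def dataset(peaks, method=HTMethod.CHIP_SEQ, dataset_id="d1", no_cutoff=False):
    return PeakDataset(dataset_id=dataset_id, method=method,
                       genome_version="U00096.3", no_cutoff=no_cutoff,
                       peaks=list(peaks))


class TestFilters:
    def test_classical_kept(self, catalog):
        ri = make_ri({BPP, CHIP_SEQ}, site=(100, 120))
        assert rb.filter_classical([ri], catalog) == [ri]

    def test_ht_only_dropped(self, catalog):
        ri = make_ri({CHIP_SEQ}, site=(100, 120))
        assert rb.filter_classical([ri], catalog) == []

    def test_siteless_dropped(self, catalog):
        ri = make_ri({BPP})
        assert rb.filter_classical([ri], catalog) == []

    def test_ten_ri_hand_tally(self, catalog):
        ris = [
            make_ri({BPP}, ri_id="1", site=(100, 110)),           # kept
            make_ri({MUT}, ri_id="2", site=(200, 210)),           # kept
            make_ri({EXTRACT}, ri_id="3", site=(300, 310)),       # kept (classical)
            make_ri({CHIP_SEQ}, ri_id="4", site=(400, 410)),      # dropped (ht)
            make_ri({COMP}, ri_id="5", site=(500, 510)),          # dropped (nonexp)
            make_ri({BPP, CHIP_SEQ}, ri_id="6", site=(600, 610)), # kept
            make_ri({BPP}, ri_id="7"),                            # dropped (no site)
            make_ri(set(), ri_id="8", site=(800, 810)),           # dropped (no codes)
            make_ri({GSELEX, COMP}, ri_id="9", site=(900, 910)),  # dropped
            make_ri({MUT, COMP}, ri_id="10", site=(950, 960)),    # kept
        ]
        kept = {ri.ri_id for ri in rb.filter_classical(ris, catalog)}
        assert kept == {"1", "2", "3", "6", "10"}

    def test_classical_confirmed_without_ht(self, catalog):
        ri = make_ri({BPP, MUT}, {EXPRESSION}, site=(100, 120))
        assert len(rb.filter_classical_confirmed([ri], catalog)) == 1

    def test_ht_dependent_confirmed_dropped(self, catalog):
        # confirmed only via strong + two HT groups; gone once HT is excluded
        ri = make_ri({BPP, CHIP_SEQ, GSELEX}, {EXPRESSION}, site=(100, 120))
        assert rb.filter_classical_confirmed([ri], catalog) == []

    def test_against_brute_force_filter(self, catalog):
        """Subset equals an independent recompute-and-filter pass."""
        import itertools

        codes = [BPP, MUT, EXTRACT, CHIP_SEQ, GSELEX, COMP]
        ht = {c for c in codes if catalog[c].category.value == "ht"}
        classical = {c for c in codes if catalog[c].category.value == "classical"}
        ris = [
            make_ri(set(combo), {EXPRESSION}, ri_id=str(i), target=str(i),
                    site=(10 * i + 1, 10 * i + 5))
            for i, combo in enumerate(
                itertools.chain.from_iterable(
                    itertools.combinations(codes, n) for n in range(len(codes) + 1)
                )
            )
        ]
        got = {ri.ri_id for ri in rb.filter_classical_confirmed(ris, catalog)}
        expected = {
            ri.ri_id
            for ri in ris
            if brute_force_level(ri.binding_evidence - ht, {EXPRESSION}, catalog)
            is ConfidenceLevel.CONFIRMED
            and (ri.binding_evidence & classical)
        }
        assert got == expected and got  # nonempty check


class TestRecovery:
    def test_three_of_four_sites(self, catalog):
        ris = [make_ri({BPP}, ri_id=str(i), tf="AraC", target=str(i),
                       site=(1000 * i, 1000 * i + 20)) for i in range(1, 5)]
        peaks = [peak("AraC", 1000 * i - 50, 1000 * i + 70) for i in range(1, 4)]
        report = rb.recovery(ris, [dataset(peaks)], pm.PeakPolicy())
        rec = report.per_tf[(HTMethod.CHIP_SEQ, "arac")]
        assert (rec.n_sites, rec.n_recovered) == (4, 3)
        assert rec.fraction == pytest.approx(75.0)

    def test_mean_and_sd_hand_arithmetic(self, catalog):
        # TF a: 2/2 recovered = 100 %; TF b: 1/2 = 50 %
        ris = [
            make_ri({BPP}, ri_id="a1", tf="A", target="1", site=(100, 120)),
            make_ri({BPP}, ri_id="a2", tf="A", target="2", site=(500, 520)),
            make_ri({BPP}, ri_id="b1", tf="B", target="3", site=(100, 120)),
            make_ri({BPP}, ri_id="b2", tf="B", target="4", site=(500, 520)),
        ]
        peaks = [peak("A", 50, 200), peak("A", 450, 600), peak("B", 50, 200)]
        report = rb.recovery(ris, [dataset(peaks)], pm.PeakPolicy())
        summary = report.per_method[HTMethod.CHIP_SEQ]
        assert summary.mean == pytest.approx(75.0)
        assert summary.sd == pytest.approx(35.36, abs=0.01)
        assert summary.pooled == pytest.approx(75.0)

    def test_sites_counted_once_across_ris(self, catalog):
        """RIs sharing a site coordinate pair count as one site."""
        ris = [
            make_ri({BPP}, ri_id="1", tf="A", target="p1", site=(100, 120)),
            make_ri({BPP}, ri_id="2", tf="A", target="p2", site=(100, 120)),
        ]
        report = rb.recovery(ris, [dataset([peak("A", 50, 200)])], pm.PeakPolicy())
        assert report.per_tf[(HTMethod.CHIP_SEQ, "a")].n_sites == 1

    def test_method_without_eligible_tfs_absent(self, catalog):
        ris = [make_ri({BPP}, tf="A", site=(100, 120))]
        ds = dataset([peak("OtherTF", 50, 200, method=HTMethod.GSELEX)],
                     method=HTMethod.GSELEX)
        report = rb.recovery(ris, [ds], pm.PeakPolicy())
        assert HTMethod.GSELEX not in report.per_method

    def test_pooled_is_count_weighted(self, catalog):
        # TF a: 1 site recovered (100 %); TF b: 1 of 3 (33.3 %)
        ris = [make_ri({BPP}, ri_id="a1", tf="A", target="1", site=(100, 120))] + [
            make_ri({BPP}, ri_id=f"b{i}", tf="B", target=str(i),
                    site=(1000 * i, 1000 * i + 20))
            for i in range(1, 4)
        ]
        peaks = [peak("A", 50, 200), peak("B", 950, 1100)]
        summary = rb.recovery(ris, [dataset(peaks)], pm.PeakPolicy()).per_method[
            HTMethod.CHIP_SEQ
        ]
        assert summary.mean == pytest.approx((100 + 100 / 3) / 2)
        assert summary.pooled == pytest.approx(100.0 * 2 / 4)

    def test_identical_widths_policy_invariance(self, catalog):
        """With every peak exactly 200 nt and centered, both policies agree."""
        ris = [make_ri({BPP}, ri_id=str(i), tf="A", target=str(i),
                       site=(1000 * i, 1000 * i + 20)) for i in range(1, 6)]
        peaks = [peak("A", 1000 * i - 90, 1000 * i + 109) for i in range(1, 5)]
        as_reported = rb.recovery(ris, [dataset(peaks)], pm.PeakPolicy())
        uniform = rb.recovery(
            ris, [dataset(peaks)],
            pm.PeakPolicy(mode=pm.PolicyMode.UNIFORM_200),
        )
        assert as_reported.per_tf == uniform.per_tf


class TestCompareMethods:
    def make_report(self, groups):
        report = rb.RecoveryReport()
        for method, fractions in groups.items():
            for i, f in enumerate(fractions):
                report.per_tf[(method, f"tf{i}")] = rb.TFRecovery(
                    n_sites=100, n_recovered=int(f)
                )
            report.per_method[method] = rb.MethodSummary(
                mean=float(np.mean(fractions)), sd=0.0, pooled=0.0,
                n_tfs=len(fractions), n_sites=0, n_recovered=0,
            )
        return report

    def test_identical_groups_h_zero(self):
        report = self.make_report({
            HTMethod.CHIP_SEQ: [50, 50, 50],
            HTMethod.CHIP_EXO: [50, 50, 50],
            HTMethod.GSELEX: [50, 50, 50],
            HTMethod.DAP_SEQ: [50, 50, 50],
        })
        comparison = rb.compare_methods(report)
        assert comparison.kw_statistic == pytest.approx(0.0)
        assert comparison.kw_pvalue == pytest.approx(1.0)

    def test_separated_groups_exact_u(self):
        report = self.make_report({
            HTMethod.CHIP_EXO: [1, 2, 3],
            HTMethod.CHIP_SEQ: [10, 11, 12],
        })
        comparison = rb.compare_methods(report)
        pw = comparison.pairwise[0]
        # methods ordered alphabetically: chip_exo first, all smaller -> U1 = 0
        assert pw.u_statistic == 0.0
        # exact two-sided p for n=m=3, complete separation: 2 / C(6,3) = 0.1
        assert pw.p_raw == pytest.approx(0.1)
        assert pw.p_adjusted == pytest.approx(0.1)  # single pair, factor 1

    def test_kw_matches_textbook_formula(self):
        groups = {
            HTMethod.CHIP_SEQ: [88.0, 75.0, 99.0],
            HTMethod.GSELEX: [60.0, 42.0, 71.0, 55.0],
            HTMethod.CHIP_EXO: [10.0, 25.0, 33.0],
        }
        report = self.make_report(groups)
        comparison = rb.compare_methods(report)
        # H = 12/(N(N+1)) * sum n_i (rbar_i - rbar)^2, no ties
        values = [v for vs in groups.values() for v in vs]
        ranks = sps.rankdata(values)
        offsets, h = 0, 0.0
        n_total = len(values)
        rbar = (n_total + 1) / 2
        for vs in groups.values():
            group_ranks = ranks[offsets:offsets + len(vs)]
            h += len(vs) * (group_ranks.mean() - rbar) ** 2
            offsets += len(vs)
        h *= 12 / (n_total * (n_total + 1))
        assert comparison.kw_statistic == pytest.approx(h)

    def test_bonferroni_factor_is_number_of_pairs(self):
        report = self.make_report({
            HTMethod.CHIP_SEQ: [90, 91, 92, 93],
            HTMethod.CHIP_EXO: [10, 11, 12, 13],
            HTMethod.GSELEX: [50, 51, 52, 53],
        })
        comparison = rb.compare_methods(report)
        assert len(comparison.pairwise) == 3
        for pw in comparison.pairwise:
            assert pw.p_adjusted == pytest.approx(min(1.0, pw.p_raw * 3))

    def test_single_method_raises(self):
        report = self.make_report({HTMethod.CHIP_SEQ: [50, 60]})
        with pytest.raises(ValueError, match="two methods"):
            rb.compare_methods(report)


class TestGoldStandardDenominator:
    def test_excluding_method_never_grows_denominator(self, catalog):
        ris = [
            make_ri({BPP, CHIP_SEQ}, {EXPRESSION}, ri_id="1", tf="A",
                    target="1", site=(100, 120)),
            make_ri({CHIP_SEQ}, {EXPRESSION}, ri_id="2", tf="A",
                    target="2", site=(300, 320)),
            make_ri({BPP, MUT}, {EXPRESSION}, ri_id="3", tf="A",
                    target="3", site=(500, 520)),
        ]
        full = rb.filter_classical(ris, catalog)
        gold = rb.filter_classical_confirmed(ris, catalog)
        assert len(gold) <= len(full)
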