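"""Peak normalization, coordinate lifting, and RI-site-to-peak mapping.

A site matches a peak when both site coordinates fall inside the peak region
of the same TF.  On a match, the binding-evidence code of the peak's method
is added to the RI (once per method, regardless of peak count) and the
confidence level is recomputed.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from riconf import confidence_engine as ce
from riconf.evidence_catalog import EvidenceCatalog
from riconf.riset_io import (
    GenomicInterval,
    HTMethod,
    Peak,
    PeakDataset,
    RegulatoryInteraction,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_METHOD_CODES",
    "GenomeVersionError",
    "LiftedInterval",
    "MapResult",
    "MatchRecord",
    "OffsetTable",
    "PeakPolicy",
    "PolicyMode",
    "average_peak_size",
    "lift_interval",
    "map_riset",
    "normalize_peak",
]

#: Method -> binding-evidence code added on a match (default-catalog codes).
DEFAULT_METHOD_CODES: dict[HTMethod, str] = {
    HTMethod.CHIP_SEQ: "HT-EXP-IDA-CHIP-SEQ",
    HTMethod.CHIP_EXO: "HT-EXP-IDA-CHIP-EXO",
    HTMethod.CHIP_CHIP: "HT-EXP-IDA-CHIP-CHIP",
    HTMethod.GSELEX: "HT-EXP-IDA-GSELEX",
    HTMethod.DAP_SEQ: "HT-EXP-IDA-DAP-SEQ",
}


class GenomeVersionError(ValueError):
    """Sites and peaks are on different genome versions; lift first."""


class PolicyMode(str, enum.Enum):
    AS_REPORTED = "as_reported"
    UNIFORM_200 = "uniform_200"


@dataclass(frozen=True)
class PeakPolicy:
    """How to turn a reported peak into a concrete interval.

    ``as_reported`` keeps author-reported ends and expands center-only peaks
    to ``2 * center_halfwidth`` nt; ``uniform_200`` replaces every peak by a
    fixed-width window around its center.  A center at ``c`` expands to
    ``[c - hw, c + hw - 1]`` so the window is exactly ``2 * hw`` nt wide;
    set ``inclusive_flank`` for the ``[c - hw, c + hw]`` (odd-width) variant.
    """

    mode: PolicyMode = PolicyMode.AS_REPORTED
    center_halfwidth: int = 100
    uniform_width: int = 200
    inclusive_flank: bool = False

    def __post_init__(self) -> None:
        if self.center_halfwidth <= 0 or self.uniform_width <= 0:
            raise ValueError("policy widths must be positive")


def _centered(center: int, halfwidth: int, inclusive: bool) -> tuple[int, int]:
    right = center + halfwidth if inclusive else center + halfwidth - 1
    return center - halfwidth, right


def normalize_peak(peak: Peak, policy: PeakPolicy) -> GenomicInterval:
    """Concrete interval for a peak under the given policy.

    A normalized left end below coordinate 1 is clamped to 1 with a warning.
    """
    if policy.mode is PolicyMode.AS_REPORTED and peak.has_ends:
        left, right = peak.left, peak.right
    else:
        if policy.mode is PolicyMode.AS_REPORTED:
            center = peak.center
            halfwidth = policy.center_halfwidth
        else:
            center = (
                (peak.left + peak.right) // 2 if peak.has_ends else peak.center
            )
            halfwidth = policy.uniform_width // 2
        left, right = _centered(center, halfwidth, policy.inclusive_flank)
    if left < 1:
        logger.warning(
            "peak %s/%s normalized to left=%d; clamped to 1",
            peak.dataset_id,
            peak.tf_name,
            left,
        )
        left = 1
    return GenomicInterval(left=left, right=right, genome_version=peak.genome_version)


class OffsetTable:
    """Piecewise-constant coordinate shifts between genome versions.

    Entries are ``(threshold, shift)`` pairs; a coordinate ``c`` is shifted
    by the entry with the largest threshold ``<= c`` (zero if none).
    """

    def __init__(
        self,
        entries: Iterable[tuple[int, int]] = (),
        source_version: str = "",
        target_version: str = "",
    ):
        self.entries = sorted((int(t), int(s)) for t, s in entries)
        self.source_version = source_version
        self.target_version = target_version

    def shift_for(self, coordinate: int) -> int:
        shift = 0
        for threshold, entry_shift in self.entries:
            if threshold <= coordinate:
                shift = entry_shift
            else:
                break
        return shift

    def inverse(self) -> "OffsetTable":
        return OffsetTable(
            ((t + s, -s) for t, s in self.entries),
            source_version=self.target_version,
            target_version=self.source_version,
        )

    @classmethod
    def from_tsv(cls, path, source_version: str = "", target_version: str = ""):
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            threshold, shift = line.split("\t")[:2]
            if threshold.lower() == "threshold":
                continue
            entries.append((int(threshold), int(shift)))
        return cls(entries, source_version, target_version)


@dataclass(frozen=True)
class LiftedInterval:
    interval: GenomicInterval
    needs_review: bool = False


def lift_interval(iv: GenomicInterval, offsets: OffsetTable) -> LiftedInterval:
    """Shift both ends by the offset table; flag breakpoint-spanning intervals.

    If the two ends fall in different offset segments the lifted interval is
    still returned but marked for manual review.
    """
    left_shift = offsets.shift_for(iv.left)
    right_shift = offsets.shift_for(iv.right)
    lifted = GenomicInterval(
        left=iv.left + left_shift,
        right=iv.right + right_shift,
        strand=iv.strand,
        genome_version=offsets.target_version or iv.genome_version,
    )
    spans = left_shift != right_shift
    if spans:
        logger.warning(
            "interval [%d, %d] spans an offset breakpoint; flagged for review",
            iv.left,
            iv.right,
        )
    return LiftedInterval(interval=lifted, needs_review=spans)


@dataclass(frozen=True)
class MatchRecord:
    """Audit record for one (RI, peak) containment match."""

    ri_id: str
    dataset_id: str
    method: HTMethod
    peak_interval: GenomicInterval
    policy_mode: PolicyMode


@dataclass
class MapResult:
    interactions: list[RegulatoryInteraction]
    matches: list[MatchRecord] = field(default_factory=list)
    n_skipped_no_site: int = 0
    n_enriched: int = 0

    def __iter__(self):
        return iter(self.interactions)

    def __len__(self) -> int:
        return len(self.interactions)


def _check_versions(
    ris: Sequence[RegulatoryInteraction], datasets: Sequence[PeakDataset]
) -> None:
    site_versions = {
        ri.site.genome_version for ri in ris if ri.site and ri.site.genome_version
    }
    peak_versions = {d.genome_version for d in datasets if d.genome_version}
    if site_versions and peak_versions and site_versions != peak_versions:
        raise GenomeVersionError(
            f"RI sites are on {sorted(site_versions)} but peaks on "
            f"{sorted(peak_versions)}; lift coordinates to one version first"
        )


def map_riset(
    ris: Sequence[RegulatoryInteraction],
    datasets: Sequence[PeakDataset],
    policy: PeakPolicy,
    catalog: EvidenceCatalog,
    ruleset: ce.RuleSet = ce.DEFAULT_RULES,
    method_codes: dict[HTMethod, str] | None = None,
) -> MapResult:
    """Enrich RIs with HT evidence from containing same-TF peaks.

    TF names compare case-insensitively.  Datasets flagged ``no_cutoff``
    (e.g. gSELEX 0 %-cutoff or top-intensity lists) are skipped.  RIs with
    no site pass through unchanged and are counted.
    """
    method_codes = dict(DEFAULT_METHOD_CODES if method_codes is None else method_codes)
    usable = [d for d in datasets if not d.no_cutoff]
    _check_versions(ris, usable)

    # per-TF index of normalized peak intervals
    by_tf: dict[str, list[tuple[GenomicInterval, PeakDataset]]] = {}
    for ds in usable:
        for peak in ds.peaks:
            by_tf.setdefault(peak.tf_name.casefold(), []).append(
                (normalize_peak(peak, policy), ds)
            )

    result = MapResult(interactions=[])
    for ri in ris:
        if ri.site is None:
            result.n_skipped_no_site += 1
            result.interactions.append(ri)
            continue
        added: set[str] = set()
        for interval, ds in by_tf.get(ri.tf_name.casefold(), ()):
            if interval.contains(ri.site):
                code = method_codes[ds.method]
                added.add(code)
                result.matches.append(
                    MatchRecord(
                        ri_id=ri.ri_id,
                        dataset_id=ds.dataset_id,
                        method=ds.method,
                        peak_interval=interval,
                        policy_mode=policy.mode,
                    )
                )
        binding = ri.binding_evidence | added
        if binding != ri.binding_evidence:
            result.n_enriched += 1
        enriched = replace(
            ri,
            binding_evidence=frozenset(binding),
            confidence=ce.assign_confidence(
                replace(ri, binding_evidence=frozenset(binding)), catalog, ruleset
            ),
        )
        result.interactions.append(enriched)
    return result


@dataclass(frozen=True)
class PeakSizeStats:
    mean: float
    sd: float
    n_peaks: int


def average_peak_size(dataset: PeakDataset) -> PeakSizeStats | None:
    """Mean +/- sample sd of reported widths; ``None`` if all center-only."""
    widths = [p.right - p.left + 1 for p in dataset.peaks if p.has_ends]
    if not widths:
        return None
    arr = np.asarray(widths, dtype=float)
    sd = float(arr.std(ddof=1)) if len(widths) > 1 else 0.0
    return PeakSizeStats(mean=float(arr.mean()), sd=sd, n_peaks=len(widths))
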