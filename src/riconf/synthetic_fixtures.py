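"""Synthetic corpora with planted ground truth.

Generates an RI set, peak datasets, and a truth table so the mapping and
recovery machinery can be exercised end-to-end with known answers: each
method covers each site with its planted probability, decoy peaks never
cover a site, and evidence sets are drawn from a finite mix whose exact
confidence distribution can be enumerated in closed form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from riconf import confidence_engine as ce
from riconf.evidence_catalog import ConfidenceLevel, EvidenceCatalog, default_catalog
from riconf.riset_io import (
    Effect,
    GenomicInterval,
    HTMethod,
    Peak,
    PeakDataset,
    RIType,
    RegulatoryInteraction,
    Strand,
    write_peaks,
    write_riset,
)

__all__ = [
    "Corpus",
    "CorpusConfig",
    "EvidenceMixEntry",
    "MethodConfig",
    "TruthRecord",
    "expected_confidence_distribution",
    "generate_corpus",
    "write_corpus",
]

GENOME_VERSION = "U00096.3"


@dataclass(frozen=True)
class EvidenceMixEntry:
    binding: frozenset[str]
    function: frozenset[str]
    probability: float


@dataclass(frozen=True)
class MethodConfig:
    """Per-method generation knobs."""

    recovery_probability: float
    peak_width: tuple[int, int] = (150, 600)  # uniform, clipped to cover the site
    center_only_fraction: float = 0.0
    n_decoys: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.recovery_probability <= 1.0:
            raise ValueError("recovery_probability must be in [0, 1]")
        if not 0.0 <= self.center_only_fraction <= 1.0:
            raise ValueError("center_only_fraction must be in [0, 1]")


DEFAULT_MIX = (
    EvidenceMixEntry(
        frozenset({"EXP-IDA-BINDING-OF-PURIFIED-PROTEINS", "EXP-SITE-MUTATION"}),
        frozenset({"EXP-GENE-EXPRESSION-ANALYSIS"}),
        0.25,
    ),
    EvidenceMixEntry(
        frozenset({"EXP-IDA-BINDING-OF-PURIFIED-PROTEINS", "COMP-ANALYSIS"}),
        frozenset({"EXP-GENE-EXPRESSION-ANALYSIS"}),
        0.25,
    ),
    EvidenceMixEntry(
        frozenset({"COMP-ANALYSIS"}),
        frozenset({"EXP-GENE-EXPRESSION-ANALYSIS"}),
        0.25,
    ),
    EvidenceMixEntry(frozenset({"HT-EXP-IDA-CHIP-SEQ"}), frozenset(), 0.25),
)


@dataclass
class CorpusConfig:
    seed: int = 0
    genome_length: int = 4_641_652
    n_tfs: int = 20
    targets_per_tf: int | tuple[str, float, int] = 10  # int or ("powerlaw", a, max)
    site_width: tuple[int, int] = (16, 24)  # uniform inclusive
    evidence_mix: tuple[EvidenceMixEntry, ...] = DEFAULT_MIX
    methods: Mapping[HTMethod, MethodConfig] = field(
        default_factory=lambda: {
            HTMethod.CHIP_SEQ: MethodConfig(0.8),
            HTMethod.GSELEX: MethodConfig(0.65, center_only_fraction=1.0),
            HTMethod.DAP_SEQ: MethodConfig(0.5, peak_width=(46, 64)),
            HTMethod.CHIP_EXO: MethodConfig(0.3, peak_width=(24, 44)),
        }
    )
    ri_type_weights: tuple[float, float, float] = (0.72, 0.05, 0.23)

    def __post_init__(self) -> None:
        total = sum(e.probability for e in self.evidence_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"evidence_mix probabilities sum to {total}, not 1")
        if self.site_width[0] < 1 or self.site_width[0] > self.site_width[1]:
            raise ValueError("invalid site_width range")
        if self.genome_length < 10 * self.site_width[1]:
            raise ValueError("genome too short for requested site placement")

    @classmethod
    def from_yaml(cls, path) -> "CorpusConfig":
        with open(path) as handle:
            spec = yaml.safe_load(handle)
        methods = {
            HTMethod(name): MethodConfig(
                recovery_probability=float(m["recovery_probability"]),
                peak_width=tuple(m.get("peak_width", (150, 600))),
                center_only_fraction=float(m.get("center_only_fraction", 0.0)),
                n_decoys=int(m.get("n_decoys", 20)),
            )
            for name, m in spec.get("methods", {}).items()
        }
        mix = tuple(
            EvidenceMixEntry(
                frozenset(e.get("binding", ())),
                frozenset(e.get("function", ())),
                float(e["probability"]),
            )
            for e in spec.get("evidence_mix", ())
        )
        kwargs = {
            k: spec[k]
            for k in ("seed", "genome_length", "n_tfs", "targets_per_tf")
            if k in spec
        }
        if "site_width" in spec:
            kwargs["site_width"] = tuple(spec["site_width"])
        if methods:
            kwargs["methods"] = methods
        if mix:
            kwargs["evidence_mix"] = mix
        return cls(**kwargs)


@dataclass(frozen=True)
class TruthRecord:
    method: HTMethod
    tf_name: str
    site_left: int
    site_right: int
    covered: bool


@dataclass
class Corpus:
    riset: list[RegulatoryInteraction]
    catalog: EvidenceCatalog
    datasets: list[PeakDataset]
    truth: list[TruthRecord]

    def truth_by_method(self, method: HTMethod) -> list[TruthRecord]:
        return [t for t in self.truth if t.method is method]


def _n_targets(config: CorpusConfig, rng: np.random.Generator) -> int:
    spec = config.targets_per_tf
    if isinstance(spec, int):
        return spec
    kind, exponent, maximum = spec
    if kind != "powerlaw":
        raise ValueError(f"unknown targets_per_tf spec {spec!r}")
    # discrete power law on 1..maximum, P(k) ~ k^-exponent
    ks = np.arange(1, maximum + 1)
    probs = ks.astype(float) ** -float(exponent)
    probs /= probs.sum()
    return int(rng.choice(ks, p=probs))


def _place_sites(
    n: int, width_range: tuple[int, int], genome_length: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Non-overlapping site placement by rejection sampling."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("infeasible site placement: genome too short")
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        left = int(rng.integers(1, genome_length - width + 1))
        right = left + width - 1
        if any(l <= right and left <= r for l, r in placed):
            continue
        placed.append((left, right))
    return sorted(placed)


def _covering_peak(
    site: tuple[int, int],
    method: HTMethod,
    mcfg: MethodConfig,
    dataset_id: str,
    rng: np.random.Generator,
) -> Peak:
    left, right = site
    site_width = right - left + 1
    if rng.random() < mcfg.center_only_fraction:
        # choose a center whose 200 nt window [c-100, c+99] contains the site
        lo, hi = right - 99, left + 100
        if lo > hi:
            raise ValueError(f"site width {site_width} exceeds 200 nt window")
        center = int(rng.integers(lo, hi + 1))
        return Peak(
            tf_name="",
            method=method,
            center=center,
            dataset_id=dataset_id,
            genome_version=GENOME_VERSION,
        )
    width = int(rng.integers(mcfg.peak_width[0], mcfg.peak_width[1] + 1))
    width = max(width, site_width)
    slack = width - site_width
    left_margin = int(rng.integers(0, slack + 1)) if slack else 0
    peak_left = max(1, left - left_margin)
    return Peak(
        tf_name="",
        method=method,
        left=peak_left,
        right=peak_left + width - 1,
        dataset_id=dataset_id,
        genome_version=GENOME_VERSION,
    )


def _decoy_peak(
    sites: Sequence[tuple[int, int]],
    method: HTMethod,
    mcfg: MethodConfig,
    dataset_id: str,
    genome_length: int,
    rng: np.random.Generator,
) -> Peak | None:
    """A peak that covers none of the TF's sites; None if not found quickly."""
    for _ in range(50):
        if mcfg.center_only_fraction >= 1.0:
            center = int(rng.integers(101, genome_length - 100))
            left, right = center - 100, center + 99
            candidate = Peak(
                tf_name="",
                method=method,
                center=center,
                dataset_id=dataset_id,
                genome_version=GENOME_VERSION,
            )
        else:
            width = int(rng.integers(mcfg.peak_width[0], mcfg.peak_width[1] + 1))
            left = int(rng.integers(1, genome_length - width + 1))
            right = left + width - 1
            candidate = Peak(
                tf_name="",
                method=method,
                left=left,
                right=right,
                dataset_id=dataset_id,
                genome_version=GENOME_VERSION,
            )
        if not any(left <= l and r <= right for l, r in sites):
            return candidate
    return None


def generate_corpus(
    config: CorpusConfig, catalog: EvidenceCatalog | None = None
) -> Corpus:
    """Deterministic corpus with planted per-method site coverage."""
    rng = np.random.default_rng(config.seed)
    catalog = catalog or default_catalog()
    mix_probs = np.array([e.probability for e in config.evidence_mix])

    riset: list[RegulatoryInteraction] = []
    truth: list[TruthRecord] = []
    datasets: dict[HTMethod, PeakDataset] = {
        method: PeakDataset(
            dataset_id=f"DS-{method.value.upper()}",
            method=method,
            genome_version=GENOME_VERSION,
        )
        for method in config.methods
    }

    ri_serial = 0
    for tf_index in range(config.n_tfs):
        tf_name = f"TF{tf_index:03d}"
        n_sites = _n_targets(config, rng)
        sites = _place_sites(n_sites, config.site_width, config.genome_length, rng)

        for site_index, (left, right) in enumerate(sites):
            ri_serial += 1
            mix = config.evidence_mix[
                int(rng.choice(len(config.evidence_mix), p=mix_probs))
            ]
            ri_type = (
                RIType.TF_PROMOTER,
                RIType.TF_TU,
                RIType.TF_GENE,
            )[int(rng.choice(3, p=np.array(config.ri_type_weights)))]
            riset.append(
                RegulatoryInteraction(
                    ri_id=f"RI{ri_serial:05d}",
                    tf_name=tf_name,
                    ri_type=ri_type,
                    target_id=f"{tf_name}-target{site_index:02d}",
                    effect=Effect.ACTIVATION
                    if rng.random() < 0.5
                    else Effect.REPRESSION,
                    site=GenomicInterval(
                        left=left,
                        right=right,
                        strand=Strand.FORWARD,
                        genome_version=GENOME_VERSION,
                    ),
                    binding_evidence=mix.binding,
                    function_evidence=mix.function,
                )
            )

        for method, mcfg in config.methods.items():
            ds = datasets[method]
            for left, right in sites:
                covered = bool(rng.random() < mcfg.recovery_probability)
                truth.append(TruthRecord(method, tf_name, left, right, covered))
                if covered:
                    peak = _covering_peak(
                        (left, right), method, mcfg, ds.dataset_id, rng
                    )
                    ds.peaks.append(
                        Peak(
                            tf_name=tf_name,
                            method=peak.method,
                            left=peak.left,
                            right=peak.right,
                            center=peak.center,
                            dataset_id=peak.dataset_id,
                            genome_version=peak.genome_version,
                        )
                    )
            for _ in range(mcfg.n_decoys):
                decoy = _decoy_peak(
                    sites, method, mcfg, ds.dataset_id, config.genome_length, rng
                )
                if decoy is not None:
                    ds.peaks.append(
                        Peak(
                            tf_name=tf_name,
                            method=decoy.method,
                            left=decoy.left,
                            right=decoy.right,
                            center=decoy.center,
                            dataset_id=decoy.dataset_id,
                            genome_version=decoy.genome_version,
                        )
                    )

    return Corpus(
        riset=riset, catalog=catalog, datasets=list(datasets.values()), truth=truth
    )


def expected_confidence_distribution(
    evidence_mix: Iterable[EvidenceMixEntry],
    ruleset: ce.RuleSet = ce.DEFAULT_RULES,
    catalog: EvidenceCatalog | None = None,
) -> dict[ConfidenceLevel, float]:
    """Exact level distribution implied by a finite evidence mix."""
    catalog = catalog or default_catalog()
    distribution = {level: 0.0 for level in ConfidenceLevel}
    for entry in evidence_mix:
        probe = RegulatoryInteraction(
            ri_id="probe",
            tf_name="probe",
            ri_type=RIType.TF_GENE,
            target_id="probe",
            binding_evidence=entry.binding,
            function_evidence=entry.function,
        )
        level = ce.assign_confidence(probe, catalog, ruleset)
        distribution[level] += entry.probability
    return distribution


def write_corpus(corpus: Corpus, outdir: str | Path) -> dict[str, Path]:
    """Write riset/peaks/catalog/truth as TSVs; returns the paths."""
    from riconf.evidence_catalog import write_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "riset": outdir / "riset.tsv",
        "peaks": outdir / "peaks.tsv",
        "catalog": outdir / "catalog.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_riset(corpus.riset, paths["riset"])
    write_peaks(corpus.datasets, paths["peaks"])
    write_catalog(corpus.catalog, paths["catalog"])
    with paths["truth"].open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["method", "tf_name", "site_left", "site_right", "covered"])
        for t in corpus.truth:
            writer.writerow(
                [t.method.value, t.tf_name, t.site_left, t.site_right, int(t.covered)]
            )
    return paths
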