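"""Readers and writers for RI-set tables and BED-like peak tables.

The RI-set dialect mirrors curated-database exports: one row per regulatory
interaction, tab-separated, with delimiter-separated evidence-code lists for
binding and function in fixed columns (21 and 22, 1-based, in the default
layout).  Coordinates are 1-based inclusive at every interface.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from riconf.evidence_catalog import ConfidenceLevel, EvidenceCatalog

__all__ = [
    "Dialect",
    "Effect",
    "GenomicInterval",
    "HTMethod",
    "Peak",
    "PeakCollection",
    "PeakDataset",
    "RIType",
    "RegulatoryInteraction",
    "RISetParseError",
    "ParseIssue",
    "RISet",
    "DEFAULT_DIALECT",
    "read_peaks",
    "read_riset",
    "write_gold_standard",
    "write_peaks",
    "write_riset",
]


class RISetParseError(ValueError):
    """Fatal parse problem (raised in strict mode or for file-level issues)."""


@dataclass(frozen=True)
class ParseIssue:
    line: int
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.message}"


class Strand(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    UNKNOWN = "unknown"


_STRAND_LABELS = {
    "forward": Strand.FORWARD,
    "+": Strand.FORWARD,
    "reverse": Strand.REVERSE,
    "-": Strand.REVERSE,
    "unknown": Strand.UNKNOWN,
    "": Strand.UNKNOWN,
}


@dataclass(frozen=True)
class GenomicInterval:
    """Closed interval on a genome, 1-based inclusive on both ends."""

    left: int
    right: int
    strand: Strand = Strand.UNKNOWN
    genome_version: str = ""

    def __post_init__(self) -> None:
        if self.left < 1:
            raise ValueError(f"coordinates are 1-based; got left={self.left}")
        if self.left > self.right:
            raise ValueError(f"left must not exceed right: [{self.left}, {self.right}]")

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    def contains(self, other: "GenomicInterval") -> bool:
        """Both ends of ``other`` fall inside this interval."""
        return self.left <= other.left and other.right <= self.right


class RIType(str, enum.Enum):
    TF_PROMOTER = "tf_promoter"
    TF_TU = "tf_tu"
    TF_GENE = "tf_gene"


_RI_TYPE_LABELS = {
    "tf_promoter": RIType.TF_PROMOTER,
    "tf-promoter": RIType.TF_PROMOTER,
    "tf_tu": RIType.TF_TU,
    "tf-tu": RIType.TF_TU,
    "tf_gene": RIType.TF_GENE,
    "tf-gene": RIType.TF_GENE,
}


class Effect(str, enum.Enum):
    ACTIVATION = "activation"
    REPRESSION = "repression"
    DUAL = "dual"
    UNKNOWN = "unknown"


_EFFECT_LABELS = {
    "activation": Effect.ACTIVATION,
    "+": Effect.ACTIVATION,
    "repression": Effect.REPRESSION,
    "-": Effect.REPRESSION,
    "dual": Effect.DUAL,
    "+-": Effect.DUAL,
    "-+": Effect.DUAL,
    "unknown": Effect.UNKNOWN,
    "": Effect.UNKNOWN,
}


class Category(str, enum.Enum):
    """Derived RI category over its full evidence set."""

    CLASSICAL = "classical"
    HT = "ht"
    CLASSICAL_AND_HT = "classical_and_ht"
    NONEXPERIMENTAL = "nonexperimental"


@dataclass(frozen=True)
class RegulatoryInteraction:
    """A TF / effect / target triplet with its supporting evidence.

    ``confidence`` and ``category`` are derived fields, refreshed by the
    confidence engine and the architecture summarizer; they are carried here
    so files round-trip.  ``extras`` holds opaque pass-through cells.
    """

    ri_id: str
    tf_name: str
    ri_type: RIType
    target_id: str
    effect: Effect = Effect.UNKNOWN
    site: GenomicInterval | None = None
    binding_evidence: frozenset[str] = frozenset()
    function_evidence: frozenset[str] = frozenset()
    confidence: ConfidenceLevel | None = None
    category: Category | None = None
    extras: Mapping[int, str] = field(default_factory=dict)

    def with_confidence(self, level: ConfidenceLevel) -> "RegulatoryInteraction":
        return replace(self, confidence=level)

    def with_binding(self, codes: Iterable[str]) -> "RegulatoryInteraction":
        return replace(self, binding_evidence=frozenset(codes))


class HTMethod(str, enum.Enum):
    CHIP_SEQ = "chip_seq"
    CHIP_EXO = "chip_exo"
    CHIP_CHIP = "chip_chip"
    GSELEX = "gselex"
    DAP_SEQ = "dap_seq"


_METHOD_LABELS = {m.value: m for m in HTMethod}
_METHOD_LABELS.update({m.value.replace("_", "-"): m for m in HTMethod})


@dataclass(frozen=True)
class Peak:
    """One HT binding region; either both ends or a center must be present."""

    tf_name: str
    method: HTMethod
    left: int | None = None
    right: int | None = None
    center: int | None = None
    dataset_id: str = ""
    genome_version: str = ""

    def __post_init__(self) -> None:
        has_ends = self.left is not None and self.right is not None
        if not has_ends and self.center is None:
            raise ValueError("peak needs either both ends or a center")
        if has_ends and self.left > self.right:  # type: ignore[operator]
            raise ValueError(f"left must not exceed right: [{self.left}, {self.right}]")

    @property
    def has_ends(self) -> bool:
        return self.left is not None and self.right is not None


@dataclass
class PeakDataset:
    dataset_id: str
    method: HTMethod
    genome_version: str = ""
    no_cutoff: bool = False
    peaks: list[Peak] = field(default_factory=list)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class PeakCollection(Sequence):
    datasets: list[PeakDataset] = field(default_factory=list)
    errors: list[ParseIssue] = field(default_factory=list)

    def __getitem__(self, i):  # type: ignore[override]
        return self.datasets[i]

    def __len__(self) -> int:
        return len(self.datasets)

    def by_method(self, method: HTMethod) -> list[PeakDataset]:
        return [d for d in self.datasets if d.method is method]


@dataclass(frozen=True)
class Dialect:
    """Column map for the RI-set TSV layout (0-based indices).

    The default layout has 22 columns with binding/function evidence in
    columns 21/22 (1-based); unmapped columns pass through opaquely.
    """

    n_columns: int = 22
    ri_id: int = 0
    tf_name: int = 1
    ri_type: int = 2
    target_id: int = 3
    effect: int = 4
    site_left: int = 5
    site_right: int = 6
    strand: int = 7
    genome_version: int = 8
    confidence: int = 9
    category: int = 10
    binding_evidence: int = 20
    function_evidence: int = 21
    evidence_delimiter: str = ","

    def mapped_indices(self) -> frozenset[int]:
        return frozenset(
            getattr(self, name)
            for name in (
                "ri_id",
                "tf_name",
                "ri_type",
                "target_id",
                "effect",
                "site_left",
                "site_right",
                "strand",
                "genome_version",
                "confidence",
                "category",
                "binding_evidence",
                "function_evidence",
            )
        )


DEFAULT_DIALECT = Dialect()

_RISET_HEADER_NAMES = {
    "ri_id": "riId",
    "tf_name": "regulatorName",
    "ri_type": "riType",
    "target_id": "targetId",
    "effect": "function",
    "site_left": "siteLeft",
    "site_right": "siteRight",
    "strand": "strand",
    "genome_version": "genomeVersion",
    "confidence": "confidenceLevel",
    "category": "evidenceCategory",
    "binding_evidence": "bindingEvidence",
    "function_evidence": "functionEvidence",
}


def _default_header(dialect: Dialect) -> list[str]:
    cells = [f"col{i + 1}" for i in range(dialect.n_columns)]
    for attr, label in _RISET_HEADER_NAMES.items():
        cells[getattr(dialect, attr)] = label
    return cells


@dataclass
class RISet(Sequence):
    """Parse result: the interactions plus every row-level issue.

    Rows are never silently dropped: ``rows_in == len(self) + len(errors)``.
    """

    interactions: list[RegulatoryInteraction] = field(default_factory=list)
    errors: list[ParseIssue] = field(default_factory=list)
    warnings: list[ParseIssue] = field(default_factory=list)
    header: list[str] | None = None

    def __getitem__(self, i):  # type: ignore[override]
        return self.interactions[i]

    def __len__(self) -> int:
        return len(self.interactions)


def _split_codes(cell: str, delimiter: str) -> frozenset[str]:
    return frozenset(c.strip() for c in cell.split(delimiter) if c.strip())


def _parse_ri_row(
    cells: list[str],
    line_no: int,
    dialect: Dialect,
    catalog: EvidenceCatalog | None,
    warnings_out: list[ParseIssue],
) -> RegulatoryInteraction:
    def cell(idx: int) -> str:
        return cells[idx].strip() if idx < len(cells) else ""

    type_label = cell(dialect.ri_type).lower()
    if type_label not in _RI_TYPE_LABELS:
        raise RISetParseError(
            f"unknown ri_type {type_label!r}; accepted: "
            + ", ".join(sorted(set(_RI_TYPE_LABELS)))
        )
    effect_label = cell(dialect.effect).lower()
    if effect_label not in _EFFECT_LABELS:
        raise RISetParseError(f"unknown effect label {effect_label!r}")

    left_cell, right_cell = cell(dialect.site_left), cell(dialect.site_right)
    site: GenomicInterval | None = None
    if left_cell or right_cell:
        if not (left_cell and right_cell):
            raise RISetParseError(
                f"malformed coordinate pair ({left_cell!r}, {right_cell!r})"
            )
        try:
            site = GenomicInterval(
                left=int(left_cell),
                right=int(right_cell),
                strand=_STRAND_LABELS.get(cell(dialect.strand).lower(), Strand.UNKNOWN),
                genome_version=cell(dialect.genome_version),
            )
        except ValueError as exc:
            raise RISetParseError(f"malformed coordinate pair: {exc}") from exc

    binding = _split_codes(cell(dialect.binding_evidence), dialect.evidence_delimiter)
    function = _split_codes(cell(dialect.function_evidence), dialect.evidence_delimiter)
    if catalog is not None:
        for code in sorted((binding | function) - set(catalog.codes)):
            warnings_out.append(
                ParseIssue(line_no, f"unknown evidence code {code!r} (retained)")
            )

    conf_cell = cell(dialect.confidence).lower()
    cat_cell = cell(dialect.category).lower()
    extras = {
        i: cells[i]
        for i in range(len(cells))
        if i not in dialect.mapped_indices() and cells[i]
    }
    return RegulatoryInteraction(
        ri_id=cell(dialect.ri_id),
        tf_name=cell(dialect.tf_name),
        ri_type=_RI_TYPE_LABELS[type_label],
        target_id=cell(dialect.target_id),
        effect=_EFFECT_LABELS[effect_label],
        site=site,
        binding_evidence=binding,
        function_evidence=function,
        confidence=ConfidenceLevel.parse(conf_cell) if conf_cell else None,
        category=Category(cat_cell) if cat_cell else None,
        extras=extras,
    )


def read_riset(
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    catalog: EvidenceCatalog | None = None,
    strict: bool = False,
) -> RISet:
    """Read an RI set; row-level problems are collected, not silently dropped.

    In strict mode the first error (or unknown-code warning) raises
    :class:`RISetParseError` with the offending line number.
    """
    path = Path(path)
    result = RISet()
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            result.header = next(reader)
        except StopIteration:
            raise RISetParseError(f"{path}: empty file (header required)") from None
        for line_no, cells in enumerate(reader, start=2):
            if not any(c.strip() for c in cells):
                continue
            try:
                ri = _parse_ri_row(cells, line_no, dialect, catalog, result.warnings)
            except RISetParseError as exc:
                if strict:
                    raise RISetParseError(f"{path}:{line_no}: {exc}") from None
                result.errors.append(ParseIssue(line_no, str(exc)))
                continue
            result.interactions.append(ri)
    if strict and result.warnings:
        raise RISetParseError(f"{path}: {result.warnings[0]}")
    return result


def _format_ri_row(ri: RegulatoryInteraction, dialect: Dialect) -> list[str]:
    cells = [""] * dialect.n_columns
    for idx, value in ri.extras.items():
        if idx < dialect.n_columns:
            cells[idx] = value
    cells[dialect.ri_id] = ri.ri_id
    cells[dialect.tf_name] = ri.tf_name
    cells[dialect.ri_type] = ri.ri_type.value
    cells[dialect.target_id] = ri.target_id
    cells[dialect.effect] = ri.effect.value
    if ri.site is not None:
        cells[dialect.site_left] = str(ri.site.left)
        cells[dialect.site_right] = str(ri.site.right)
        cells[dialect.strand] = ri.site.strand.value
        cells[dialect.genome_version] = ri.site.genome_version
    cells[dialect.confidence] = ri.confidence.value if ri.confidence else ""
    cells[dialect.category] = ri.category.value if ri.category else ""
    delim = dialect.evidence_delimiter
    cells[dialect.binding_evidence] = delim.join(sorted(ri.binding_evidence))
    cells[dialect.function_evidence] = delim.join(sorted(ri.function_evidence))
    return cells


def write_riset(
    ris: Iterable[RegulatoryInteraction],
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
    header: list[str] | None = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(header if header is not None else _default_header(dialect))
        for ri in ris:
            writer.writerow(_format_ri_row(ri, dialect))


PEAK_COLUMNS = (
    "dataset_id",
    "tf_name",
    "method",
    "left",
    "right",
    "center",
    "genome_version",
    "no_cutoff",
)


def read_peaks(path: str | Path, strict: bool = False) -> PeakCollection:
    """Read a BED-like peak TSV, grouping rows into datasets by dataset id."""
    path = Path(path)
    collection = PeakCollection()
    by_id: dict[str, PeakDataset] = {}
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise RISetParseError(f"{path}: empty peak file")
        missing = set(PEAK_COLUMNS[:6]) - set(reader.fieldnames)
        if missing:
            raise RISetParseError(f"{path}: missing peak columns {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                method_label = (row["method"] or "").strip().lower()
                if method_label not in _METHOD_LABELS:
                    raise ValueError(f"unknown method {method_label!r}")
                peak = Peak(
                    tf_name=(row["tf_name"] or "").strip(),
                    method=_METHOD_LABELS[method_label],
                    left=int(row["left"]) if (row["left"] or "").strip() else None,
                    right=int(row["right"]) if (row["right"] or "").strip() else None,
                    center=int(row["center"]) if (row["center"] or "").strip() else None,
                    dataset_id=(row["dataset_id"] or "").strip(),
                    genome_version=(row.get("genome_version") or "").strip(),
                )
            except ValueError as exc:
                if strict:
                    raise RISetParseError(f"{path}:{line_no}: {exc}") from None
                collection.errors.append(ParseIssue(line_no, str(exc)))
                continue
            no_cutoff = (row.get("no_cutoff") or "").strip().lower() in {
                "1", "true", "yes",
            }
            ds = by_id.get(peak.dataset_id)
            if ds is None:
                ds = PeakDataset(
                    dataset_id=peak.dataset_id,
                    method=peak.method,
                    genome_version=peak.genome_version,
                    no_cutoff=no_cutoff,
                )
                by_id[peak.dataset_id] = ds
                collection.datasets.append(ds)
            ds.no_cutoff = ds.no_cutoff or no_cutoff
            ds.peaks.append(peak)
    return collection


def write_peaks(datasets: Iterable[PeakDataset], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PEAK_COLUMNS)
        for ds in datasets:
            for p in ds.peaks:
                writer.writerow(
                    [
                        ds.dataset_id,
                        p.tf_name,
                        p.method.value,
                        "" if p.left is None else p.left,
                        "" if p.right is None else p.right,
                        "" if p.center is None else p.center,
                        p.genome_version or ds.genome_version,
                        "1" if ds.no_cutoff else "",
                    ]
                )


def write_gold_standard(
    ris: Sequence[RegulatoryInteraction],
    path: str | Path,
    catalog: EvidenceCatalog,
    min_confidence: ConfidenceLevel | None = None,
    excluded_codes: Iterable[str] = (),
    excluded_categories: Iterable[str] = (),
    excluded_groups: Iterable[int] = (),
    require_classical_binding: bool = False,
    dialect: Dialect = DEFAULT_DIALECT,
) -> list[RegulatoryInteraction]:
    """Write a filtered RI subset plus a YAML provenance sidecar.

    Confidence is recomputed after removing the excluded evidence, then the
    confidence filter is applied — so a benchmark set never owes its levels
    to the method under evaluation (anti-circularity).  The sidecar at
    ``<path>.provenance.yaml`` records the filter expression and the concrete
    excluded codes.
    """
    import yaml

    from riconf import confidence_engine as ce
    from riconf.evidence_catalog import Category as CatalogCategory

    excluded = ce.resolve_exclusions(
        catalog,
        codes=excluded_codes,
        categories=excluded_categories,
        groups=excluded_groups,
    )
    refreshed = ce.recompute_with_exclusions(ris, catalog, excluded_codes=excluded)
    classical_codes = catalog.codes_in_category(CatalogCategory.CLASSICAL)
    selected = []
    for ri in refreshed.interactions:
        if min_confidence is not None and ri.confidence < min_confidence:
            continue
        if require_classical_binding and not (ri.binding_evidence & classical_codes):
            continue
        selected.append(ri)
    write_riset(selected, path, dialect=dialect)
    provenance = {
        "n_input": len(ris),
        "n_selected": len(selected),
        "min_confidence": min_confidence.value if min_confidence else None,
        "excluded_codes": sorted(excluded),
        "require_classical_binding": require_classical_binding,
    }
    Path(f"{path}.provenance.yaml").write_text(
        yaml.safe_dump(provenance, sort_keys=True)
    )
    return selected
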