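"""Evidence-type catalog and independence-group structure.

Binding-evidence methods are partitioned into seven independence groups.
Methods within a group share methodological bias and never combine; methods
from different groups are independent and may combine to upgrade the
confidence of a regulatory interaction.  Groups 1-2 carry a strong base
level, groups 3-7 a weak one.  Codes without a group (author statements,
curator inferences) are excluded from the confidence algebra altogether.
"""

from __future__ import annotations

import csv
import enum
import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Aspect",
    "AssayContext",
    "BaseLevel",
    "Category",
    "CatalogError",
    "ConfidenceLevel",
    "EvidenceCatalog",
    "EvidenceType",
    "STRONG_GROUPS",
    "WEAK_GROUPS",
    "UPGRADE_WEAK_GROUPS",
    "default_catalog",
    "load_catalog",
    "write_catalog",
]

#: Groups whose members carry a strong base level.
STRONG_GROUPS = frozenset({1, 2})
#: Groups whose members carry a weak base level.
WEAK_GROUPS = frozenset({3, 4, 5, 6, 7})
#: Weak groups that participate in upgrade-rule antecedents.  Group 3
#: (binding of cellular extracts) is cataloged but never counted.
UPGRADE_WEAK_GROUPS = frozenset({4, 5, 6, 7})

CATALOG_COLUMNS = (
    "code",
    "name",
    "category",
    "group",
    "base_level",
    "aspect",
    "assay_context",
)


class CatalogError(ValueError):
    """Raised when a catalog violates a structural invariant."""


class Category(str, enum.Enum):
    CLASSICAL = "classical"
    HT = "ht"
    NONEXPERIMENTAL = "nonexperimental"


class BaseLevel(str, enum.Enum):
    WEAK = "weak"
    STRONG = "strong"


class Aspect(str, enum.Enum):
    BINDING = "binding"
    FUNCTION = "function"


class AssayContext(str, enum.Enum):
    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"
    NA = "na"


@functools.total_ordering
class ConfidenceLevel(enum.Enum):
    """Totally ordered confidence: weak < strong < confirmed.

    No single evidence type maps to confirmed; the level is only reachable
    through combinations of independent evidence.
    """

    WEAK = "weak"
    STRONG = "strong"
    CONFIRMED = "confirmed"

    @property
    def rank(self) -> int:
        return _LEVEL_RANK[self]

    def __lt__(self, other: "ConfidenceLevel") -> bool:
        if not isinstance(other, ConfidenceLevel):
            return NotImplemented
        return self.rank < other.rank

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def parse(cls, label: str) -> "ConfidenceLevel":
        return cls(label.strip().lower())


_LEVEL_RANK = {
    ConfidenceLevel.WEAK: 0,
    ConfidenceLevel.STRONG: 1,
    ConfidenceLevel.CONFIRMED: 2,
}


@dataclass(frozen=True)
class EvidenceType:
    """One catalog entry.

    ``group`` is an integer 1..7 or ``None``; ``None`` means the code is
    excluded from the confidence algebra (e.g., author statements).
    """

    code: str
    name: str
    category: Category
    group: int | None
    base_level: BaseLevel
    aspect: Aspect
    assay_context: AssayContext = AssayContext.NA

    def __post_init__(self) -> None:
        if self.group is not None:
            if self.group not in range(1, 8):
                raise CatalogError(
                    f"{self.code}: group must be 1..7 or empty, got {self.group}"
                )
            expected = (
                BaseLevel.STRONG if self.group in STRONG_GROUPS else BaseLevel.WEAK
            )
            if self.base_level is not expected:
                raise CatalogError(
                    f"{self.code}: group {self.group} requires base_level "
                    f"{expected.value!r}, got {self.base_level.value!r}"
                )
            expected_cat = _GROUP_CATEGORY[self.group]
            if self.category is not expected_cat:
                raise CatalogError(
                    f"{self.code}: group {self.group} requires category "
                    f"{expected_cat.value!r}, got {self.category.value!r}"
                )

    @property
    def is_experimental(self) -> bool:
        return self.category is not Category.NONEXPERIMENTAL

    @property
    def in_algebra(self) -> bool:
        """Whether this code participates in confidence assignment at all."""
        return self.group is not None


_GROUP_CATEGORY: Mapping[int, Category] = {
    1: Category.CLASSICAL,
    2: Category.CLASSICAL,
    3: Category.CLASSICAL,
    4: Category.HT,
    5: Category.HT,
    6: Category.HT,
    7: Category.NONEXPERIMENTAL,
}


class EvidenceCatalog:
    """Immutable mapping of evidence codes to :class:`EvidenceType`."""

    def __init__(self, entries: Iterable[EvidenceType]):
        self._by_code: dict[str, EvidenceType] = {}
        for entry in entries:
            if entry.code in self._by_code:
                raise CatalogError(f"duplicate evidence code: {entry.code!r}")
            self._by_code[entry.code] = entry

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> EvidenceType:
        return self._by_code[code]

    def __iter__(self) -> Iterator[EvidenceType]:
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    def get(self, code: str) -> EvidenceType | None:
        return self._by_code.get(code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._by_code)

    def group_of(self, code: str) -> int | None:
        entry = self.get(code)
        return entry.group if entry is not None else None

    def independent(self, code_a: str, code_b: str) -> bool:
        """Two codes are independent iff both are grouped and groups differ."""
        ga, gb = self.group_of(code_a), self.group_of(code_b)
        return ga is not None and gb is not None and ga != gb

    def codes_in_category(self, category: Category) -> frozenset[str]:
        return frozenset(
            e.code for e in self if e.category is category
        )

    def codes_in_group(self, group: int) -> frozenset[str]:
        return frozenset(e.code for e in self if e.group == group)

    def binding_codes(self) -> frozenset[str]:
        return frozenset(e.code for e in self if e.aspect is Aspect.BINDING)

    def function_codes(self) -> frozenset[str]:
        return frozenset(e.code for e in self if e.aspect is Aspect.FUNCTION)


def _parse_row(row: Mapping[str, str], line_no: int) -> EvidenceType:
    try:
        group_cell = (row["group"] or "").strip()
        return EvidenceType(
            code=row["code"].strip(),
            name=row["name"].strip(),
            category=Category(row["category"].strip().lower()),
            group=int(group_cell) if group_cell else None,
            base_level=BaseLevel(row["base_level"].strip().lower()),
            aspect=Aspect(row["aspect"].strip().lower()),
            assay_context=AssayContext((row.get("assay_context") or "na").strip().lower()),
        )
    except (KeyError, ValueError) as exc:
        if isinstance(exc, CatalogError):
            raise
        raise CatalogError(f"catalog line {line_no}: {exc}") from exc


def load_catalog(path: str | Path) -> EvidenceCatalog:
    """Load an evidence catalog from a TSV file with the canonical header."""
    path = Path(path)
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise CatalogError(f"{path}: empty catalog file")
        missing = set(CATALOG_COLUMNS[:6]) - set(reader.fieldnames)
        if missing:
            raise CatalogError(f"{path}: missing columns {sorted(missing)}")
        entries = [_parse_row(row, i) for i, row in enumerate(reader, start=2)]
    return EvidenceCatalog(entries)


def write_catalog(catalog: EvidenceCatalog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CATALOG_COLUMNS)
        for e in catalog:
            writer.writerow(
                [
                    e.code,
                    e.name,
                    e.category.value,
                    "" if e.group is None else e.group,
                    e.base_level.value,
                    e.aspect.value,
                    e.assay_context.value,
                ]
            )


@functools.lru_cache(maxsize=1)
def default_catalog() -> EvidenceCatalog:
    """The built-in catalog shipped as a package resource.

    Twelve codes: one per group 1-3 and 5-7, three ChIP variants in group 4,
    two function-aspect codes, and one ungrouped author-statement code.
    """
    ref = resources.files("riconf.data").joinpath("default_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)
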