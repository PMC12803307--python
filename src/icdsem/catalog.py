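"""ICD code catalogues and Phecode-style phenotype definitions.

The catalogue is the searchable universe: every entry is a (vocabulary,
code) pair with a free-text description.  Vocabulary is part of the key —
``("ICD9CM", "250.0")`` and any ICD-10-CM code are distinct entities even
when the code strings collide.  Code strings are stored verbatim (dots
kept); matching is exact string equality after trimming.

Phenotype definitions are named reference sets of catalogue keys, with a
category label and an optional parent link forming an acyclic hierarchy.
The hierarchy is what makes a retrieved code "out-of-hierarchy": absent
from the phenotype's own reference set and from every ancestor's.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

VOCABULARIES = frozenset({"ICD9CM", "ICD10CM"})

#: A catalogue key: (vocabulary, code), both verbatim strings.
Key = tuple[str, str]

#: Non-trivial phenotypes are those with strictly more than this many codes.
TRIVIAL_SIZE_MAX = 10

CATALOG_DIALECT = {"vocabulary": "vocabulary", "code": "code", "description": "description"}
DEFINITION_DIALECT = {
    "phenotype_id": "phecode",
    "name": "phecode_string",
    "category": "category",
    "parent_id": "parent",
    "vocabulary": "vocabulary",
    "code": "code",
}


@dataclass(frozen=True)
class IcdCode:
    """One diagnosis code with its text description."""

    vocabulary: str
    code: str
    description: str

    def __post_init__(self) -> None:
        if self.vocabulary not in VOCABULARIES:
            raise DataError(f"unknown vocabulary {self.vocabulary!r}")
        if not self.code.strip():
            raise DataError("empty code string")
        desc = " ".join(self.description.split())
        if not desc:
            raise DataError(f"empty description for {self.vocabulary} {self.code}")
        object.__setattr__(self, "code", self.code.strip())
        object.__setattr__(self, "description", desc)

    @property
    def key(self) -> Key:
        return (self.vocabulary, self.code)


class IcdCatalog:
    """Ordered, key-unique collection of :class:`IcdCode`.

    Iteration order is insertion order and is what embedding-matrix rows
    align to; ``sorted_keys`` gives the lexicographic ordering used as the
    canonical ranking universe (deterministic tie-breaking).
    """

    def __init__(self, entries: Iterable[IcdCode]):
        self._entries: list[IcdCode] = []
        self._index: dict[Key, int] = {}
        for entry in entries:
            if entry.key in self._index:
                raise DataError(f"duplicate catalogue key {entry.key}")
            self._index[entry.key] = len(self._entries)
            self._entries.append(entry)
        if not self._entries:
            raise DataError("empty catalogue")
        self._sorted_keys: tuple[Key, ...] | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[IcdCode]:
        return iter(self._entries)

    def __contains__(self, key: Key) -> bool:
        return key in self._index

    def lookup(self, vocabulary: str, code: str) -> IcdCode:
        try:
            return self._entries[self._index[(vocabulary, code)]]
        except KeyError:
            raise KeyError(f"({vocabulary}, {code}) not in catalogue") from None

    @property
    def keys(self) -> list[Key]:
        return [e.key for e in self._entries]

    @property
    def descriptions(self) -> list[str]:
        return [e.description for e in self._entries]

    @property
    def sorted_keys(self) -> tuple[Key, ...]:
        """Catalogue keys in lexicographic (vocabulary, code) order."""
        if self._sorted_keys is None:
            self._sorted_keys = tuple(sorted(self._index))
        return self._sorted_keys

    def description_of(self, key: Key) -> str:
        return self._entries[self._index[key]].description

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "vocabulary": [e.vocabulary for e in self._entries],
                "code": [e.code for e in self._entries],
                "description": [e.description for e in self._entries],
            }
        )


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A named phenotype and its reference set of catalogue keys."""

    phenotype_id: str
    name: str
    category: str
    icd_set: frozenset[Key]
    parent_id: str | None = None
    unevaluable: bool = False
    removed_from_catalog: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if not self.icd_set and not self.unevaluable:
            raise DataError(f"phenotype {self.phenotype_id} has an empty ICD set")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _resolve_columns(frame: pd.DataFrame, dialect: Mapping[str, str], needed: list[str]) -> dict[str, str]:
    resolved = {}
    for logical in needed:
        column = dialect.get(logical, logical)
        if column not in frame.columns:
            raise ConfigurationError(
                f"column {column!r} (for {logical!r}) not found; available: {list(frame.columns)}"
            )
        resolved[logical] = column
    return resolved


def read_icd_catalog(path: str | Path, dialect: Mapping[str, str] | None = None) -> IcdCatalog:
    """Read a catalogue from CSV/TSV.

    Duplicate (vocabulary, code) rows collapse to the first occurrence with
    a warning; rows with blank descriptions are rejected and logged.
    """
    frame = _read_table(path)
    if frame.empty:
        raise DataError(f"catalogue file {path} contains no rows")
    cols = _resolve_columns(frame, {**CATALOG_DIALECT, **(dialect or {})}, ["vocabulary", "code", "description"])

    entries: list[IcdCode] = []
    seen: set[Key] = set()
    n_dup = n_blank = 0
    for row in frame.itertuples(index=False):
        vocab = str(getattr(row, cols["vocabulary"])).strip()
        code = str(getattr(row, cols["code"])).strip()
        desc = " ".join(str(getattr(row, cols["description"])).split())
        if not desc:
            n_blank += 1
            logger.warning("dropping (%s, %s): blank description", vocab, code)
            continue
        if (vocab, code) in seen:
            n_dup += 1
            logger.warning("duplicate catalogue row (%s, %s): keeping first occurrence", vocab, code)
            continue
        seen.add((vocab, code))
        entries.append(IcdCode(vocab, code, desc))
    if n_dup or n_blank:
        logger.warning("catalogue read: dropped %d duplicate and %d blank-description rows", n_dup, n_blank)
    if not entries:
        raise DataError(f"catalogue file {path} has no usable rows")
    return IcdCatalog(entries)


def read_phenotype_definitions(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[PhenotypeDefinition]:
    """Read long-format phenotype definitions (one row per phenotype × code).

    Rows are grouped by phenotype id; member sets are deduplicated; category
    and name are taken from the first row of each group.
    """
    frame = _read_table(path)
    if frame.empty:
        raise DataError(f"definition file {path} contains no rows")
    merged = {**DEFINITION_DIALECT, **(dialect or {})}
    cols = _resolve_columns(frame, merged, ["phenotype_id", "name", "vocabulary", "code"])
    cat_col = merged.get("category", "category")
    parent_col = merged.get("parent_id", "parent")

    defs: list[PhenotypeDefinition] = []
    for pid, group in frame.groupby(cols["phenotype_id"], sort=False):
        icd_set = frozenset(
            (str(v).strip(), str(c).strip())
            for v, c in zip(group[cols["vocabulary"]], group[cols["code"]])
            if str(c).strip()
        )
        if not icd_set:
            logger.warning("phenotype %s has no usable member rows; excluded", pid)
            continue
        first = group.iloc[0]
        parent = str(first[parent_col]).strip() if parent_col in group.columns else ""
        defs.append(
            PhenotypeDefinition(
                phenotype_id=str(pid),
                name=str(first[cols["name"]]).strip(),
                category=str(first[cat_col]).strip() if cat_col in group.columns else "",
                parent_id=parent or None,
                icd_set=icd_set,
            )
        )
    if not defs:
        raise DataError(f"definition file {path} yielded no phenotypes")
    return defs


def validate_definitions(definitions: list[PhenotypeDefinition]) -> list[str]:
    """Structural validation pass: unknown parents, duplicate ids, cycles.

    Returns human-readable issue strings; unknown parents are flagged but
    the definitions are kept.
    """
    issues: list[str] = []
    ids = [d.phenotype_id for d in definitions]
    known = set(ids)
    if len(known) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        issues.append(f"duplicate phenotype ids: {dupes}")
    for d in definitions:
        if d.parent_id is not None and d.parent_id not in known:
            issues.append(f"{d.phenotype_id}: parent {d.parent_id!r} not among definitions")
    by_id = {d.phenotype_id: d for d in definitions}
    for d in definitions:
        seen: list[str] = []
        cur: PhenotypeDefinition | None = d
        while cur is not None:
            if cur.phenotype_id in seen:
                issues.append(f"parent cycle: {' -> '.join(seen + [cur.phenotype_id])}")
                break
            seen.append(cur.phenotype_id)
            cur = by_id.get(cur.parent_id) if cur.parent_id else None
    return issues


def restrict_to_catalog(defn: PhenotypeDefinition, catalog: IcdCatalog) -> PhenotypeDefinition:
    """Intersect the reference set with the catalogue keys.

    This ensures every reference code is retrievable.  A definition whose
    set becomes empty is marked unevaluable (excluded from benchmarks)
    rather than raising.
    """
    kept = frozenset(k for k in defn.icd_set if k in catalog)
    removed = len(defn.icd_set) - len(kept)
    if removed:
        logger.info("phenotype %s: %d reference codes absent from catalogue", defn.phenotype_id, removed)
    return replace(
        defn,
        icd_set=kept,
        unevaluable=not kept,
        removed_from_catalog=defn.removed_from_catalog + removed,
    )


def is_trivial(defn: PhenotypeDefinition) -> bool:
    """True when the (restricted) reference set has at most 10 codes.

    Small sets are dominated by lexical overlap with the query and are
    excluded from semantic-retrieval benchmarks.
    """
    return len(defn.icd_set) <= TRIVIAL_SIZE_MAX


def ancestor_icd_union(
    defn: PhenotypeDefinition, all_definitions: Iterable[PhenotypeDefinition]
) -> frozenset[Key]:
    """Union of the reference set over the phenotype and its ancestors.

    A retrieved code absent from this union is "out-of-hierarchy": it could
    not have been found by walking parent phenotype mappings.
    """
    by_id = {d.phenotype_id: d for d in all_definitions}
    by_id.setdefault(defn.phenotype_id, defn)
    union: set[Key] = set()
    seen: list[str] = []
    cur: PhenotypeDefinition | None = defn
    while cur is not None:
        if cur.phenotype_id in seen:
            raise DataError(f"parent cycle: {' -> '.join(seen + [cur.phenotype_id])}")
        seen.append(cur.phenotype_id)
        union |= cur.icd_set
        cur = by_id.get(cur.parent_id) if cur.parent_id else None
    return frozenset(union)
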