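"""Expert-review shortlists and reviewer-derived phenotype sets.

Workflow: each ranking producer's shortlist is truncated at its own PPV
cutoff (positive predictive value against the existing reference set,
threshold 50% by default), the truncations are pooled, the reference set
is added back so no known mapping is omitted, and the deduplicated list
is shuffled deterministically before being handed to a blinded reviewer.
The reviewer labels each code on a 0/1/2 ordinal scale; label 2 defines
the *strict* phenotype set and labels {1, 2} the *extended* set.  Codes in
those sets but absent from the reference — and from every hierarchical
ancestor's reference — are the "out-of-hierarchy" discoveries that manual
curation via parent mappings could not have surfaced.

Cutoff convention: the cutoff rank is the largest rank ≤ k whose PPV is
still ≥ the threshold (0 if none qualifies).  This is monotone in the
threshold and keeps the whole list when PPV never drops below it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import IcdCatalog, Key, PhenotypeDefinition, ancestor_icd_union
from .exceptions import ConfigurationError, DataError
from .retrieval import Ranking

DEFAULT_PPV_THRESHOLD = 0.5

REFERENCE_FLAG = "REFERENCE"


@dataclass
class PpvCurve:
    """PPV per rank 1..k against a reference set, with the threshold cutoff."""

    ppv: np.ndarray
    cutoff_rank: int
    threshold: float

    @property
    def k(self) -> int:
        return len(self.ppv)


@dataclass
class ReviewSheet:
    """Blinded, shuffled candidate list for one phenotype.

    ``rows`` carry only (vocabulary, code, description); provenance (which
    producers retrieved each code, and whether it is a reference code) is
    kept separately so the exported sheet stays blinded.
    """

    phenotype_id: str
    rows: list[tuple[str, str, str]]
    provenance: dict[Key, frozenset[str]]
    shuffle_seed: int

    @property
    def keys(self) -> list[Key]:
        return [(v, c) for v, c, _ in self.rows]

    def to_frame(self, blinded: bool = True) -> pd.DataFrame:
        frame = pd.DataFrame(self.rows, columns=["vocabulary", "code", "description"])
        if not blinded:
            frame["provenance"] = [
                ";".join(sorted(self.provenance[k])) for k in self.keys
            ]
        return frame


@dataclass
class PhenotypeSets:
    """Reference set plus reviewer-derived strict/extended sets."""

    reference: frozenset[Key]
    strict: frozenset[Key]
    extended: frozenset[Key]

    def __post_init__(self) -> None:
        if not self.strict <= self.extended:
            raise DataError("strict set must be a subset of the extended set")


@dataclass
class AuditReport:
    """Additional-code discovery report for one phenotype."""

    phenotype_id: str
    additional_strict: frozenset[Key]
    additional_extended: frozenset[Key]
    out_of_hierarchy_strict: frozenset[Key]
    out_of_hierarchy_extended: frozenset[Key]
    cumulative: pd.DataFrame | None = field(default=None, repr=False)

    def counts(self) -> dict[str, int]:
        return {
            "additional_strict": len(self.additional_strict),
            "additional_extended": len(self.additional_extended),
            "out_of_hierarchy_strict": len(self.out_of_hierarchy_strict),
            "out_of_hierarchy_extended": len(self.out_of_hierarchy_extended),
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "phenotype_id": self.phenotype_id,
            "counts": self.counts(),
            "additional_strict": sorted(map(list, self.additional_strict)),
            "additional_extended": sorted(map(list, self.additional_extended)),
            "out_of_hierarchy_strict": sorted(map(list, self.out_of_hierarchy_strict)),
            "out_of_hierarchy_extended": sorted(map(list, self.out_of_hierarchy_extended)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def ppv_curve(
    items: Sequence[Key],
    reference: Iterable[Key],
    k: int,
    threshold: float = DEFAULT_PPV_THRESHOLD,
) -> PpvCurve:
    """Running precision against the reference over ranks 1..min(k, N)."""
    reference = set(reference)
    if not reference:
        raise DataError("empty reference set")
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    prefix = items[:k]
    hits = np.cumsum([item in reference for item in prefix])
    ranks = np.arange(1, len(prefix) + 1)
    ppv = hits / ranks
    qualifying = np.flatnonzero(ppv >= threshold)
    cutoff = int(qualifying[-1] + 1) if qualifying.size else 0
    return PpvCurve(ppv=ppv, cutoff_rank=cutoff, threshold=threshold)


def build_review_sheet(
    producer_rankings: Sequence[Ranking],
    reference: Iterable[Key],
    catalog: IcdCatalog,
    k: int,
    ppv_threshold: float = DEFAULT_PPV_THRESHOLD,
    shuffle_seed: int = 0,
    phenotype_id: str | None = None,
) -> ReviewSheet:
    """Pool PPV-truncated shortlists, add the reference, dedupe and shuffle.

    Each producer is truncated at its own PPV cutoff before pooling; the
    sheet set is therefore invariant to producer order, and only the row
    order depends on the shuffle seed.
    """
    reference = set(reference)
    if not producer_rankings:
        raise ConfigurationError("need at least one producer ranking")
    if not reference:
        raise DataError("empty reference set")
    provenance: dict[Key, set[str]] = {key: {REFERENCE_FLAG} for key in reference}
    for ranking in producer_rankings:
        items = ranking.items
        cutoff = ppv_curve(items, reference, k, ppv_threshold).cutoff_rank
        for key in items[:cutoff]:
            provenance.setdefault(key, set()).add(ranking.model_id)

    keys = sorted(provenance)
    rng = np.random.default_rng(shuffle_seed)
    order = rng.permutation(len(keys))
    rows = []
    for i in order:
        vocab, code = keys[i]
        desc = catalog.description_of((vocab, code)) if (vocab, code) in catalog else ""
        rows.append((vocab, code, desc))
    return ReviewSheet(
        phenotype_id=phenotype_id or producer_rankings[0].query_id,
        rows=rows,
        provenance={key: frozenset(val) for key, val in provenance.items()},
        shuffle_seed=shuffle_seed,
    )


def read_annotations(path: str | Path) -> dict[Key, int]:
    """Read reviewer labels from CSV (vocabulary, code, label)."""
    frame = pd.read_csv(path, dtype={"vocabulary": str, "code": str})
    for col in ("vocabulary", "code", "label"):
        if col not in frame.columns:
            raise ConfigurationError(f"annotation file missing column {col!r}")
    return {
        (str(v), str(c)): int(lab)
        for v, c, lab in zip(frame["vocabulary"], frame["code"], frame["label"])
    }


def derive_sets(
    sheet: ReviewSheet,
    annotations: Mapping[Key, int],
    reference: Iterable[Key],
) -> PhenotypeSets:
    """Apply 0/1/2 labels: strict = {2}, extended = {1, 2}.

    Every sheet row must be annotated with a label in {0, 1, 2}; unknown
    codes in the annotations are an error, not silently ignored.
    """
    sheet_keys = set(sheet.keys)
    missing = sorted(sheet_keys - set(annotations))
    if missing:
        raise DataError(f"unannotated sheet rows: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    unknown = sorted(set(annotations) - sheet_keys)
    if unknown:
        raise DataError(f"annotations for codes not on the sheet: {unknown[:5]}")
    bad = sorted(k for k in sheet_keys if annotations[k] not in (0, 1, 2))
    if bad:
        raise DataError(f"labels outside {{0,1,2}} for: {bad[:5]}")
    strict = frozenset(k for k in sheet_keys if annotations[k] == 2)
    extended = frozenset(k for k in sheet_keys if annotations[k] >= 1)
    return PhenotypeSets(reference=frozenset(reference), strict=strict, extended=extended)


def classify_new_codes(
    sets: PhenotypeSets,
    defn: PhenotypeDefinition,
    all_definitions: Sequence[PhenotypeDefinition],
    ranking_items: Sequence[Key] | None = None,
    k: int | None = None,
) -> AuditReport:
    """Report reviewer-confirmed codes beyond the reference set.

    A code is out-of-hierarchy when it is absent from the union of the
    phenotype's own reference set and all transitive ancestors' sets.
    When ``ranking_items`` is given, cumulative-by-rank discovery series
    (additional and out-of-hierarchy counts at each rank) are attached.
    """
    hierarchy = ancestor_icd_union(defn, all_definitions)
    additional_strict = sets.strict - sets.reference
    additional_extended = sets.extended - sets.reference
    ooh_strict = frozenset(key for key in additional_strict if key not in hierarchy)
    ooh_extended = frozenset(key for key in additional_extended if key not in hierarchy)

    cumulative = None
    if ranking_items is not None:
        prefix = list(ranking_items[: (k or len(ranking_items))])
        add_s = np.cumsum([item in additional_strict for item in prefix])
        add_e = np.cumsum([item in additional_extended for item in prefix])
        ooh_s = np.cumsum([item in ooh_strict for item in prefix])
        ooh_e = np.cumsum([item in ooh_extended for item in prefix])
        cumulative = pd.DataFrame(
            {
                "rank": np.arange(1, len(prefix) + 1),
                "cum_additional_strict": add_s,
                "cum_additional_extended": add_e,
                "cum_out_of_hierarchy_strict": ooh_s,
                "cum_out_of_hierarchy_extended": ooh_e,
            }
        )
    return AuditReport(
        phenotype_id=defn.phenotype_id,
        additional_strict=frozenset(additional_strict),
        additional_extended=frozenset(additional_extended),
        out_of_hierarchy_strict=ooh_strict,
        out_of_hierarchy_extended=ooh_extended,
        cumulative=cumulative,
    )
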