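"""Retrieval evaluation against reference phenotype definitions.

Primary measure is recall at depth k (R@k): the fraction of a phenotype's
reference codes recovered in the top k — missing codes mean
under-ascertained cohorts.  AP@k complements it by rewarding early
placement of reference codes.  Model agreement is measured with the
Jaccard index of top-k sets (J@k), split into ground-truth overlap and
candidate (beyond-reference) overlap; 1 minus the mean of the two median
J@k matrices is the model distance matrix used for clustering encoders.

Benchmarks are summarised with the *median* across phenotypes because
reference-set sizes are strongly right-skewed; the evaluation depth
defaults to k = 100, large enough for recall to reach 1.0 for nearly all
phenotypes while staying reviewable by a human.

AP@k convention: denominator min(|relevant|, k), so AP@k can attain 1.0
exactly when R@k can.  This choice is recorded in benchmark metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import IcdCatalog, Key, PhenotypeDefinition, is_trivial
from .exceptions import ConfigurationError, DataError
from .retrieval import DEFAULT_K

AP_CONVENTION = "ap_denominator=min(n_relevant,k)"

OVERALL = "__overall__"

JACCARD_GROUND_TRUTH = "GROUND_TRUTH"
JACCARD_CANDIDATE = "CANDIDATE"


def _check(relevant: set, k: int) -> None:
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if not relevant:
        raise DataError("empty relevant set: definition is unevaluable")


def recall_at_k(items: Sequence[Key], relevant: Iterable[Key], k: int) -> float:
    """|relevant ∩ top-k| / |relevant|."""
    relevant = set(relevant)
    _check(relevant, k)
    return len(relevant.intersection(items[:k])) / len(relevant)


def average_precision_at_k(items: Sequence[Key], relevant: Iterable[Key], k: int) -> float:
    """Mean of precision-at-hit over the top k, normalised by min(|relevant|, k)."""
    relevant = set(relevant)
    _check(relevant, k)
    hits = 0
    total = 0.0
    for i, item in enumerate(items[:k], start=1):
        if item in relevant:
            hits += 1
            total += hits / i
    return total / min(len(relevant), k)


def jaccard_at_k(
    items_a: Sequence[Key],
    items_b: Sequence[Key],
    relevant: Iterable[Key],
    k: int,
    mode: str = JACCARD_GROUND_TRUTH,
) -> float | None:
    """Top-k set overlap of two rankings, restricted to or excluding the reference.

    Returns None (excluded from medians) when both restricted sets are
    empty — coercing to 0 or 1 would bias model-similarity summaries.
    """
    relevant = set(relevant)
    _check(relevant, k)
    a, b = set(items_a[:k]), set(items_b[:k])
    if mode == JACCARD_GROUND_TRUTH:
        a, b = a & relevant, b & relevant
    elif mode == JACCARD_CANDIDATE:
        a, b = a - relevant, b - relevant
    else:
        raise ConfigurationError(f"unknown Jaccard mode {mode!r}")
    union = a | b
    if not union:
        return None
    return len(a & b) / len(union)


def model_distance_matrix(
    j_ground: np.ndarray | pd.DataFrame, j_candidate: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """D = 1 − (J_ground + J_candidate)/2, with an exact zero diagonal."""
    jg = np.asarray(j_ground, dtype=np.float64)
    jc = np.asarray(j_candidate, dtype=np.float64)
    if jg.shape != jc.shape or jg.ndim != 2 or jg.shape[0] != jg.shape[1]:
        raise DataError(f"Jaccard matrices must be square and congruent: {jg.shape} vs {jc.shape}")
    dist = 1.0 - (jg + jc) / 2.0
    np.fill_diagonal(dist, 0.0)
    return dist


def median_jaccard_matrix(
    items_by_model: Mapping[str, Mapping[str, Sequence[Key]]],
    relevant_by_phenotype: Mapping[str, Iterable[Key]],
    k: int = DEFAULT_K,
    mode: str = JACCARD_GROUND_TRUTH,
) -> pd.DataFrame:
    """Median-across-phenotypes pairwise J@k matrix for a set of models."""
    models = list(items_by_model)
    out = pd.DataFrame(np.ones((len(models), len(models))), index=models, columns=models)
    for i, ma in enumerate(models):
        for mb in models[i + 1 :]:
            values = []
            for pid, relevant in relevant_by_phenotype.items():
                j = jaccard_at_k(
                    items_by_model[ma][pid], items_by_model[mb][pid], relevant, k, mode
                )
                if j is not None:
                    values.append(j)
            med = float(np.median(values)) if values else np.nan
            out.loc[ma, mb] = out.loc[mb, ma] = med
    return out


@dataclass
class BenchmarkSummary:
    """Per-phenotype scores plus median summaries per category and overall."""

    scores: pd.DataFrame      # producer, phenotype_id, category, metric columns
    summary: pd.DataFrame     # producer, category, metric, k, median, n_phenotypes
    k: int
    n_evaluated: int
    ap_convention: str = AP_CONVENTION

    def median(self, producer: str, metric: str, category: str = OVERALL) -> float:
        row = self.summary[
            (self.summary["producer"] == producer)
            & (self.summary["metric"] == metric)
            & (self.summary["category"] == category)
        ]
        return float(row["median"].iloc[0])

    def to_wide(self) -> pd.DataFrame:
        return self.summary.pivot_table(
            index=["producer", "category"], columns="metric", values="median"
        ).reset_index()


def run_benchmark(
    producers: Sequence,
    definitions: Sequence[PhenotypeDefinition],
    catalog: IcdCatalog,
    k: int = DEFAULT_K,
) -> BenchmarkSummary:
    """Evaluate every producer on every evaluable, non-trivial phenotype.

    Definitions must already be restricted to the catalogue; trivial
    (≤ 10 codes) and unevaluable (empty restricted set) definitions are
    excluded before scoring.  Producers expose ``producer_id`` and
    ``rank(query_id, name, category)``.
    """
    evaluable = [d for d in definitions if not d.unevaluable and not is_trivial(d)]
    if not evaluable:
        raise DataError("no evaluable, non-trivial phenotype definitions")
    for d in evaluable:
        missing = [key for key in d.icd_set if key not in catalog]
        if missing:
            raise DataError(
                f"phenotype {d.phenotype_id} not restricted to catalogue: e.g. {missing[0]}"
            )

    rows = []
    for producer in producers:
        for d in evaluable:
            ranking = producer.rank(d.phenotype_id, d.name, d.category)
            items = ranking.items
            rows.append(
                {
                    "producer": producer.producer_id,
                    "phenotype_id": d.phenotype_id,
                    "category": d.category,
                    "n_relevant": len(d.icd_set),
                    "recall_at_k": recall_at_k(items, d.icd_set, k),
                    "ap_at_k": average_precision_at_k(items, d.icd_set, k),
                }
            )
    scores = pd.DataFrame(rows)

    summaries = []
    for metric in ("recall_at_k", "ap_at_k"):
        for (producer, category), group in scores.groupby(["producer", "category"]):
            summaries.append(
                {
                    "producer": producer,
                    "category": category,
                    "metric": metric,
                    "k": k,
                    "median": float(group[metric].median()),
                    "n_phenotypes": len(group),
                }
            )
        for producer, group in scores.groupby("producer"):
            summaries.append(
                {
                    "producer": producer,
                    "category": OVERALL,
                    "metric": metric,
                    "k": k,
                    "median": float(group[metric].median()),
                    "n_phenotypes": len(group),
                }
            )
    return BenchmarkSummary(
        scores=scores,
        summary=pd.DataFrame(summaries),
        k=k,
        n_evaluated=len(evaluable),
    )
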