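"""Shared test utilities: ranking construction and ordering comparison."""

from __future__ import annotations

import numpy as np

from icdsem.retrieval import Ranking


def key(name: str, vocab: str = "ICD10CM") -> tuple[str, str]:
    return (vocab, name)


def make_ranking(
    items_in_order: list[tuple[str, str]],
    model_id: str = "m",
    query_id: str = "q",
    scores: dict | None = None,
) -> Ranking:
    """Build a Ranking whose descending order is ``items_in_order``.

    Without explicit scores, item i gets score N - i (strictly decreasing,
    so the requested order is exact).
    """
    universe = tuple(sorted(items_in_order))
    if scores is None:
        scores = {item: float(len(items_in_order) - i) for i, item in enumerate(items_in_order)}
    aligned = np.array([scores[k] for k in universe], dtype=float)
    return Ranking(model_id=model_id, query_id=query_id, universe=universe, scores=aligned)


def ranking_from_scores(
    score_map: dict, model_id: str = "m", query_id: str = "q"
) -> Ranking:
    universe = tuple(sorted(score_map))
    return Ranking(
        model_id=model_id,
        query_id=query_id,
        universe=universe,
        scores=np.array([score_map[k] for k in universe], dtype=float),
    )


def orderings_equivalent(ra: Ranking, rb: Ranking, tol: float = 1e-9) -> bool:
    """True when the two orderings agree up to swaps of near-tied scores.

    Floating-point summation order can perturb fused scores by an ulp;
    an ordering difference only matters if the scores it swaps genuinely
    differ.
    """
    items_a, items_b = ra.items, rb.items
    if items_a == items_b:
        return True
    score_a = dict(zip(ra.universe, ra.scores))
    return all(
        x == y or abs(score_a[x] - score_a[y]) <= tol for x, y in zip(items_a, items_b)
    )
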