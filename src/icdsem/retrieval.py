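"""Cosine-similarity ranking of a full ICD catalogue for one query.

Every ranking covers the *entire* catalogue (scores kept), because
score-level fusion needs all models' scores over the same universe.
Rankings are stored aligned to the lexicographically sorted key universe;
the descending ordering is derived with a stable sort, so ties break by
(vocabulary, code) and the result is a deterministic function of
(scores, keys) — invariant to catalogue row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import Key
from .encoder import EmbeddingMatrix
from .exceptions import ConfigurationError, DataError

DEFAULT_K = 100


@dataclass(eq=False)
class Ranking:
    """A full descending ordering of a key universe with scores.

    ``universe`` is the lexicographically sorted tuple of keys and
    ``scores`` is aligned to it; ``items`` / ``ordered_scores`` expose the
    descending view.  Subclasses only differ in provenance metadata.
    """

    model_id: str
    query_id: str
    universe: tuple[Key, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.universe),):
            raise DataError("scores must align with the universe")
        if len(self.universe) == 0:
            raise DataError("empty ranking universe")

    @cached_property
    def _order(self) -> np.ndarray:
        # stable sort on descending score; universe is pre-sorted by key,
        # so exact ties fall back to lexicographic (vocabulary, code)
        return np.argsort(-self.scores, kind="stable")

    @property
    def items(self) -> list[Key]:
        return [self.universe[i] for i in self._order]

    @property
    def ordered_scores(self) -> np.ndarray:
        return self.scores[self._order]

    def ranks(self) -> np.ndarray:
        """1-based rank of each universe entry, aligned to ``universe``."""
        ranks = np.empty(len(self.universe), dtype=np.int64)
        ranks[self._order] = np.arange(1, len(self.universe) + 1)
        return ranks

    def rank_of(self, key: Key) -> int:
        return int(self.ranks()[self.universe.index(key)])

    def to_frame(self) -> pd.DataFrame:
        items = self.items
        return pd.DataFrame(
            {
                "query_id": self.query_id,
                "model_id": self.model_id,
                "rank": np.arange(1, len(items) + 1),
                "vocabulary": [k[0] for k in items],
                "code": [k[1] for k in items],
                "score": self.ordered_scores,
            }
        )


@dataclass(eq=False)
class SimilarityRanking(Ranking):
    """One encoder's cosine-similarity ordering of the catalogue."""


def rank_catalog(
    query_vec: np.ndarray,
    catalog_embeddings: EmbeddingMatrix,
    query_id: str,
    model_id: str | None = None,
) -> SimilarityRanking:
    """Rank every catalogue entry by cosine similarity to ``query_vec``.

    Catalogue rows and the query are unit vectors, so the dot product is
    the cosine.  The full ordering is materialised, never truncated here.
    """
    query_vec = np.asarray(query_vec, dtype=np.float64).ravel()
    if query_vec.shape[0] != catalog_embeddings.dimension:
        raise DataError(
            f"query dimension {query_vec.shape[0]} != catalogue dimension "
            f"{catalog_embeddings.dimension}"
        )
    keys = catalog_embeddings.keys
    if len(keys) == 0:
        raise DataError("empty catalogue embeddings")
    scores = catalog_embeddings.matrix @ query_vec
    perm = sorted(range(len(keys)), key=keys.__getitem__)
    universe = tuple(keys[i] for i in perm)
    return SimilarityRanking(
        model_id=model_id or catalog_embeddings.model_id,
        query_id=query_id,
        universe=universe,
        scores=scores[perm],
    )


def top_k(ranking: Ranking, k: int = DEFAULT_K) -> list[Key]:
    """First min(k, N) items of the descending ordering."""
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    return ranking.items[:k]


def write_rankings(rankings: list[Ranking], path: str | Path) -> None:
    """Export rankings as one long-format CSV (query, model, rank, key, score)."""
    pd.concat([r.to_frame() for r in rankings], ignore_index=True).to_csv(path, index=False)


def read_rankings(path: str | Path) -> list[Ranking]:
    """Reconstruct rankings from an exported CSV (full-universe exports only)."""
    frame = pd.read_csv(path, dtype={"vocabulary": str, "code": str})
    rankings: list[Ranking] = []
    for (qid, mid), group in frame.groupby(["query_id", "model_id"], sort=False):
        pairs = sorted(
            zip(zip(group["vocabulary"], group["code"]), group["score"].astype(float))
        )
        rankings.append(
            Ranking(
                model_id=str(mid),
                query_id=str(qid),
                universe=tuple(k for k, _ in pairs),
                scores=np.array([s for _, s in pairs]),
            )
        )
    return rankings


@dataclass
class EncoderProducer:
    """Ranking producer backed by one encoder's catalogue embeddings.

    Queries are embedded lazily with the backend; the catalogue matrix is
    computed once and shared across queries.
    """

    backend: object
    catalog_embeddings: EmbeddingMatrix
    query_template: str = "{name}"
    producer_id: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not self.producer_id:
            self.producer_id = self.catalog_embeddings.model_id

    def rank(self, query_id: str, name: str, category: str = "") -> SimilarityRanking:
        text = self.query_template.format(name=name, category=category)
        query_vec = np.asarray(self.backend.embed([text]), dtype=np.float64)[0]
        query_vec = query_vec / np.linalg.norm(query_vec)
        return rank_catalog(query_vec, self.catalog_embeddings, query_id, self.producer_id)
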