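"""Unsupervised rank fusion over multiple encoders' rankings of one query.

Score-level methods (Z-sum, CombSum, CombMNZ, Fisher) combine per-model
similarity scores after a per-model normalisation; rank-level methods
(mean rank, median rank, reciprocal rank fusion, Borda) use only the rank
positions.  None of them require supervision or tuning, which is the point:
the ensemble stays applicable to arbitrary free-text queries.

Conventions (recorded here because the classical literature varies):

* Z-sum uses the population standard deviation; a constant score vector
  contributes all-zero z-scores rather than NaNs.
* CombSum min–max normalises each model's scores over the whole universe
  to [0, 1]; a constant vector maps to all 0.5.
* CombMNZ multiplies the CombSum score by the number of member rankings
  placing the item inside their top-``hit_depth`` (default 100, matching
  the evaluation depth).  Every model ranks the full universe, so a depth
  is needed to make "retrieved by the system" meaningful.
* Fisher treats rank/N as an empirical p-value (top item gets 1/N, never
  0) and combines with -2·Σ ln p.
* Ties are always broken lexicographically by (vocabulary, code).

MEDIAN_RANK, RRF and BORDA are standard members of the rank-based family,
included as configurable extras alongside MEAN_RANK.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .retrieval import Ranking
from .exceptions import ConfigurationError, DataError

SCORE_METHODS = ("zsum", "combsum", "combmnz", "fisher")
RANK_METHODS = ("mean_rank", "median_rank", "rrf", "borda")
FUSION_METHODS = SCORE_METHODS + RANK_METHODS

DEFAULT_HIT_DEPTH = 100
DEFAULT_RRF_K = 60


@dataclass(eq=False)
class FusedRanking(Ranking):
    """Ensemble ordering; ``model_id`` is the fusion method name."""

    method: str = ""
    member_model_ids: tuple[str, ...] = field(default_factory=tuple)


def _validate(rankings: list[Ranking]) -> tuple:
    if not rankings:
        raise ConfigurationError("need at least one ranking to fuse")
    universe = rankings[0].universe
    for r in rankings[1:]:
        if r.universe != universe:
            raise DataError(
                f"rankings cover different universes ({r.model_id} vs {rankings[0].model_id})"
            )
    return universe


def _build(method: str, rankings: list[Ranking], fused: np.ndarray) -> FusedRanking:
    return FusedRanking(
        model_id=method,
        query_id=rankings[0].query_id,
        universe=rankings[0].universe,
        scores=fused,
        method=method,
        member_model_ids=tuple(r.model_id for r in rankings),
    )


def _zscores(scores: np.ndarray) -> np.ndarray:
    sd = scores.std()  # population sd
    if sd == 0.0:
        return np.zeros_like(scores)
    return (scores - scores.mean()) / sd


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def zsum_fuse(rankings: list[Ranking]) -> FusedRanking:
    """Sum of per-model z-scored similarity scores."""
    _validate(rankings)
    fused = np.sum([_zscores(r.scores) for r in rankings], axis=0)
    return _build("zsum", rankings, fused)


def combsum_fuse(rankings: list[Ranking]) -> FusedRanking:
    """Sum of per-model min–max-normalised scores."""
    _validate(rankings)
    fused = np.sum([_minmax(r.scores) for r in rankings], axis=0)
    return _build("combsum", rankings, fused)


def combmnz_fuse(rankings: list[Ranking], hit_depth: int = DEFAULT_HIT_DEPTH) -> FusedRanking:
    """CombSum score scaled by the number of members ranking the item in their top-``hit_depth``."""
    if hit_depth < 1:
        raise ConfigurationError(f"hit_depth must be >= 1, got {hit_depth}")
    _validate(rankings)
    combsum = np.sum([_minmax(r.scores) for r in rankings], axis=0)
    hits = np.sum([(r.ranks() <= hit_depth) for r in rankings], axis=0)
    return _build("combmnz", rankings, combsum * hits)


def fisher_fuse(rankings: list[Ranking]) -> FusedRanking:
    """Fisher combination of empirical rank p-values, p = rank / N."""
    universe = _validate(rankings)
    n = len(universe)
    fused = np.sum([-2.0 * np.log(r.ranks() / n) for r in rankings], axis=0)
    return _build("fisher", rankings, fused)


def rank_based_fuse(
    rankings: list[Ranking], method: str, rrf_k: int = DEFAULT_RRF_K
) -> FusedRanking:
    """Rank-level fusion: MEAN_RANK, MEDIAN_RANK, RRF or BORDA.

    Mean/median rank order ascending (smaller aggregate rank is better);
    internally the fused score is the negated aggregate so all rankings
    share one descending-score convention.
    """
    method = method.lower()
    universe = _validate(rankings)
    ranks = np.stack([r.ranks().astype(np.float64) for r in rankings])
    if method == "mean_rank":
        fused = -ranks.mean(axis=0)
    elif method == "median_rank":
        fused = -np.median(ranks, axis=0)
    elif method == "rrf":
        if rrf_k < 1:
            raise ConfigurationError(f"rrf_k must be >= 1, got {rrf_k}")
        fused = np.sum(1.0 / (rrf_k + ranks), axis=0)
    elif method == "borda":
        fused = np.sum(len(universe) - ranks, axis=0)
    else:
        raise ConfigurationError(f"unknown rank-based method {method!r}")
    return _build(method, rankings, fused)


def fuse(rankings: list[Ranking], method: str, **params) -> FusedRanking:
    """Dispatch by method name (see ``FUSION_METHODS``)."""
    method = method.lower()
    if method == "zsum":
        return zsum_fuse(rankings)
    if method == "combsum":
        return combsum_fuse(rankings)
    if method == "combmnz":
        return combmnz_fuse(rankings, **params)
    if method == "fisher":
        return fisher_fuse(rankings)
    if method in RANK_METHODS:
        return rank_based_fuse(rankings, method, **params)
    raise ConfigurationError(f"unknown fusion method {method!r}; choose from {FUSION_METHODS}")


@dataclass
class EnsembleProducer:
    """Ranking producer that fuses the outputs of member producers."""

    members: list
    method: str
    params: dict = field(default_factory=dict)
    producer_id: str = ""

    def __post_init__(self) -> None:
        if not self.producer_id:
            self.producer_id = self.method.lower()

    def rank(self, query_id: str, name: str, category: str = "") -> FusedRanking:
        member_rankings = [m.rank(query_id, name, category) for m in self.members]
        fused = fuse(member_rankings, self.method, **self.params)
        fused.model_id = self.producer_id
        return fused
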