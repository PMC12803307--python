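"""Text-embedding backends and row-aligned embedding matrices.

Retrieval only needs two things from an encoder: a stable ``model_id`` and
a batch text → vector map.  Real sentence-encoder adapters (e.g. a
SentenceTransformers wrapper) can be plugged in behind the same protocol;
nothing in the package or its tests requires pretrained weights.

The bundled :class:`HashingTextEncoder` is a deterministic stand-in: it
hashes tokens and their character 3-grams into ``dimension`` buckets,
accumulates term frequencies and L2-normalises.  Texts that share tokens
get strictly higher cosine similarity in expectation than token-disjoint
texts, which is all the synthetic benchmarks need.  An optional per-text
Gaussian noise term (seeded from the encoder seed and the text itself, so
still fully deterministic) lets several differently-seeded instances stand
in for an ensemble of encoders with partially independent errors.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .exceptions import ConfigurationError, DataError

UNIT_NORM_TOL = 1e-6  # float32 backends round-trip within this

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@runtime_checkable
class EncoderBackend(Protocol):
    """Contract every embedding backend satisfies."""

    model_id: str
    dimension: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # (n, dimension)
        ...


@dataclass
class EmbeddingMatrix:
    """Unit-row embedding matrix aligned by position to an ordered key list."""

    model_id: str
    keys: tuple
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.keys):
            raise DataError(
                f"matrix shape {self.matrix.shape} does not match {len(self.keys)} keys"
            )
        norms = np.linalg.norm(self.matrix, axis=1)
        if not np.allclose(norms, 1.0, atol=UNIT_NORM_TOL):
            raise DataError("embedding rows must be unit-norm")

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]


def _hash_bucket(feature: str, seed: int, dimension: int) -> int:
    digest = hashlib.blake2b(
        feature.encode("utf-8"), digest_size=8, key=str(seed).encode("utf-8")
    ).digest()
    return int.from_bytes(digest, "big") % dimension


def _features(text: str) -> list[str]:
    tokens = _TOKEN_RE.findall(text.lower())
    feats: list[str] = []
    for tok in tokens:
        feats.append(tok)
        padded = f"#{tok}#"
        feats.extend(padded[i : i + 3] for i in range(len(padded) - 2))
    return feats


def toy_encode(text: str, dimension: int, seed: int, noise_sigma: float = 0.0) -> np.ndarray:
    """Deterministic hashed bag-of-features unit vector for one text."""
    if dimension < 8:
        raise ConfigurationError("toy encoder dimension must be >= 8")
    feats = _features(text)
    if not feats:
        raise DataError(f"text has no tokens: {text!r}")
    vec = np.zeros(dimension)
    for feat in feats:
        vec[_hash_bucket(feat, seed, dimension)] += 1.0
    if noise_sigma > 0.0:
        text_digest = hashlib.blake2b(
            f"{seed}|{text}".encode("utf-8"), digest_size=4
        ).digest()
        rng = np.random.default_rng(int.from_bytes(text_digest, "big"))
        noise = rng.standard_normal(dimension)
        # noise_sigma is the norm of the perturbation relative to the unit signal
        vec = vec / np.linalg.norm(vec) + noise_sigma * noise / np.linalg.norm(noise)
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        raise DataError(f"degenerate zero vector for text {text!r}")
    return vec / norm


class HashingTextEncoder:
    """Seeded hashing encoder implementing :class:`EncoderBackend`."""

    def __init__(
        self,
        dimension: int = 256,
        seed: int = 0,
        noise_sigma: float = 0.0,
        model_id: str | None = None,
    ):
        if dimension < 8:
            raise ConfigurationError("dimension must be >= 8")
        self.dimension = dimension
        self.seed = seed
        self.noise_sigma = noise_sigma
        self.model_id = model_id or f"hash-d{dimension}-s{seed}" + (
            f"-n{noise_sigma:g}" if noise_sigma else ""
        )

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack(
            [toy_encode(t, self.dimension, self.seed, self.noise_sigma) for t in texts]
        )


def encode_texts(texts: Sequence[str], backend: EncoderBackend, keys: Sequence | None = None) -> EmbeddingMatrix:
    """Encode a text list into a row-aligned unit-norm matrix.

    ``keys`` defaults to the texts themselves; pass catalogue keys to align
    rows with a catalogue.  Rows are re-normalised regardless of backend
    behaviour; empty texts and zero vectors raise with the offending index.
    """
    texts = list(texts)
    if not texts:
        raise DataError("no texts to encode")
    for i, t in enumerate(texts):
        if not str(t).strip():
            raise DataError(f"text at index {i} is empty")
    raw = np.asarray(backend.embed(texts), dtype=np.float64)
    if raw.shape != (len(texts), backend.dimension):
        raise DataError(
            f"backend {backend.model_id} returned shape {raw.shape}, "
            f"expected {(len(texts), backend.dimension)}"
        )
    norms = np.linalg.norm(raw, axis=1)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise DataError(f"backend {backend.model_id} produced a zero vector at index {zero[0]}")
    matrix = raw / norms[:, None]
    key_list = tuple(keys) if keys is not None else tuple(texts)
    if len(key_list) != len(texts):
        raise ConfigurationError("keys length must match texts length")
    return EmbeddingMatrix(model_id=backend.model_id, keys=key_list, matrix=matrix)


def _cache_stem(model_id: str, keys: Sequence) -> str:
    digest = hashlib.sha256(json.dumps(list(map(list, map(_aslist, keys)))).encode()).hexdigest()[:16]
    safe = re.sub(r"[^A-Za-z0-9._-]", "_", model_id)
    return f"{safe}-{digest}"


def _aslist(key) -> list:
    return list(key) if isinstance(key, (tuple, list)) else [key]


def save_embeddings(matrix: EmbeddingMatrix, cache_dir: str | Path) -> Path:
    """Write matrix + JSON sidecar (model id, dimension, key order) to a cache dir."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    stem = _cache_stem(matrix.model_id, matrix.keys)
    np.save(cache_dir / f"{stem}.npy", matrix.matrix)
    sidecar = {
        "model_id": matrix.model_id,
        "dimension": matrix.dimension,
        "keys": [_aslist(k) for k in matrix.keys],
    }
    (cache_dir / f"{stem}.json").write_text(json.dumps(sidecar))
    return cache_dir / f"{stem}.npy"


def load_embeddings(model_id: str, keys: Sequence, cache_dir: str | Path) -> EmbeddingMatrix | None:
    """Load a cached matrix for (model_id, key list); None on cache miss."""
    stem = _cache_stem(model_id, keys)
    npy = Path(cache_dir) / f"{stem}.npy"
    sidecar = Path(cache_dir) / f"{stem}.json"
    if not (npy.exists() and sidecar.exists()):
        return None
    meta = json.loads(sidecar.read_text())
    loaded_keys = tuple(tuple(k) if isinstance(k, list) and len(k) > 1 else k[0] for k in meta["keys"])
    return EmbeddingMatrix(model_id=meta["model_id"], keys=loaded_keys, matrix=np.load(npy))


def get_or_encode(
    texts: Sequence[str],
    backend: EncoderBackend,
    keys: Sequence | None = None,
    cache_dir: str | Path | None = None,
) -> EmbeddingMatrix:
    """Cached wrapper around :func:`encode_texts`, keyed by (model_id, keys)."""
    key_list = tuple(keys) if keys is not None else tuple(texts)
    if cache_dir is not None:
        cached = load_embeddings(backend.model_id, key_list, cache_dir)
        if cached is not None:
            return cached
    matrix = encode_texts(texts, backend, keys=key_list)
    if cache_dir is not None:
        save_embeddings(matrix, cache_dir)
    return matrix
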