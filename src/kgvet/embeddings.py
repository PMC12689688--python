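"""Pluggable text-to-vector backends.

Semantic scoring treats each triple element — head, relation and tail alike
— as a free-text phrase mapped to a fixed-dimension real vector by a
biomedical sentence encoder (e.g. PubMedBERT). For offline, deterministic
testing two lightweight backends are provided:

* :class:`MockEmbeddingBackend` — a seeded pseudo-random unit vector keyed
  by a stable hash of the text. Same text, same vector, across processes.
* :class:`PlantedEmbeddingBackend` — returns exact vectors from a fixture
  table (unknown text falls back to the mock), which is what makes
  semantic-evaluation tests exact: fixtures can plant ``t = h + r`` so the
  translation distance is provably zero.

A transformer-backed encoder is available behind the ``transformer`` extra;
nothing in the library or tests requires it.
"""

from __future__ import annotations

import hashlib
from typing import Mapping

import numpy as np

__all__ = [
    "EmbeddingBackend",
    "MockEmbeddingBackend",
    "PlantedEmbeddingBackend",
    "TransformerEmbeddingBackend",
    "cosine_similarity",
    "make_backend",
]


class EmbeddingBackend:
    """Interface: maps non-empty text to a vector of fixed ``dimension``.

    ``normalized`` records whether vectors are L2-normalized before use in
    the translation distance; both behaviours are testable.
    """

    name: str = "abstract"
    dimension: int
    normalized: bool = False

    def embed(self, text: str) -> np.ndarray:
        raise NotImplementedError

    def _check_text(self, text: str) -> str:
        if not isinstance(text, str) or not text.strip():
            raise ValueError("cannot embed an empty entity/relation label")
        return text.strip()


class MockEmbeddingBackend(EmbeddingBackend):
    """Deterministic pseudo-random unit vectors, keyed by a stable hash.

    The hash (BLAKE2b of ``"{seed}\\x1f{text}"``) seeds a PCG64 generator,
    so the mapping is reproducible across processes and Python versions,
    collision-resistant at fixture scale, and distinct texts get
    near-orthogonal vectors with overwhelming probability in 32+ dims.
    """

    name = "mock"

    def __init__(self, dimension: int = 32, seed: int = 0) -> None:
        if dimension < 1:
            raise ValueError("dimension must be positive")
        self.dimension = int(dimension)
        self.seed = int(seed)
        self.normalized = True
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, text: str) -> np.ndarray:
        text = self._check_text(text)
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(
            f"{self.seed}\x1f{text}".encode("utf-8"), digest_size=8
        ).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "big"))
        v = rng.standard_normal(self.dimension)
        v /= np.linalg.norm(v)
        self._cache[text] = v
        return v


class PlantedEmbeddingBackend(EmbeddingBackend):
    """Fixture-table backend: exact vectors for known text, mock fallback.

    All table vectors must share one dimension; the fallback mock is built
    with the same dimension so one run never mixes dimensions.
    """

    name = "planted"

    def __init__(
        self,
        table: Mapping[str, np.ndarray],
        dimension: int | None = None,
        seed: int = 0,
    ) -> None:
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        dims = {v.shape[0] for v in self.table.values()}
        if len(dims) > 1:
            raise ValueError(f"planted vectors have mixed dimensions: {sorted(dims)}")
        if dimension is None:
            if not dims:
                raise ValueError("empty planted table requires explicit dimension")
            dimension = dims.pop()
        elif dims and dims != {dimension}:
            raise ValueError("declared dimension disagrees with table vectors")
        self.dimension = int(dimension)
        self.normalized = False
        self._fallback = MockEmbeddingBackend(dimension=self.dimension, seed=seed)

    def embed(self, text: str) -> np.ndarray:
        text = self._check_text(text)
        hit = self.table.get(text)
        if hit is not None:
            return hit
        return self._fallback.embed(text)


class TransformerEmbeddingBackend(EmbeddingBackend):
    """Sentence-transformer encoder (mean-pooled token states).

    Requires the ``transformer`` extra; import is lazy so the core library
    stays dependency-light and fully offline.
    """

    name = "transformer"

    def __init__(self, model_name: str = "NeuML/pubmedbert-base-embeddings",
                 normalized: bool = False) -> None:
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError(
                "the transformer backend requires the 'transformer' extra: "
                "pip install kgvet[transformer]"
            ) from exc
        self._model = SentenceTransformer(model_name)  # pragma: no cover
        self.model_name = model_name  # pragma: no cover
        self.dimension = int(self._model.get_sentence_embedding_dimension())  # pragma: no cover
        self.normalized = normalized  # pragma: no cover

    def embed(self, text: str) -> np.ndarray:  # pragma: no cover - optional extra
        text = self._check_text(text)
        v = np.asarray(self._model.encode([text])[0], dtype=float)
        if self.normalized:
            v = v / np.linalg.norm(v)
        return v


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Standard cosine similarity in [-1, 1]; errors on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for an all-zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def make_backend(kind: str = "mock", *, dimension: int = 32, seed: int = 0,
                 table: Mapping[str, np.ndarray] | None = None,
                 model_name: str | None = None) -> EmbeddingBackend:
    """Construct a backend from config keys (``embedding.backend`` etc.)."""
    if kind == "mock":
        return MockEmbeddingBackend(dimension=dimension, seed=seed)
    if kind == "planted":
        # an explicit table defines its own dimension
        return PlantedEmbeddingBackend(
            table or {}, dimension=None if table else dimension, seed=seed)
    if kind == "transformer":
        kwargs = {"model_name": model_name} if model_name else {}
        return TransformerEmbeddingBackend(**kwargs)
    raise ValueError(f"unknown embedding backend {kind!r}; choose mock, planted or transformer")
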