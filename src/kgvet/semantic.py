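"""Semantic plausibility scoring via translation energy.

A triple ``(h, r, t)`` is semantically plausible when the head vector plus
the relation vector approximately equals the tail vector, ``h + r ≈ t``
(the TransE translation criterion, applied to fixed encoder embeddings
rather than learned ones). The raw distance is the squared Euclidean norm

    d_trans = ||h + r − t||²,

so large deviations are quadratically penalized. Raw distances are min–max
normalized across the whole corpus and inverted:

    score = 1 − (d − d_min) / (d_max − d_min),

placing every triple on [0, 1] with higher = more plausible (the corpus
minimum-distance triple scores 1, the maximum scores 0). The inversion is
explicit here: distances are *normalized*, scores are reported with the
"higher is plausible" orientation.

Note the corpus dependence: min–max runs over all triples scored together,
so a triple's score shifts when corpus composition changes. Per-concept
normalization is available behind a flag in the pipeline layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingBackend
from .stats import ScoreSummary, summarize_scores
from .triples import TripleSet

__all__ = [
    "SemanticResult",
    "translation_distance",
    "minmax_normalize",
    "semantic_scores",
    "summarize_semantic",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SemanticResult:
    triple_id: str
    raw_distance: float  # d_trans = ||h + r - t||^2, >= 0
    score: float         # 1 - minmax(d_trans), in [0, 1]


def translation_distance(h: np.ndarray, r: np.ndarray, t: np.ndarray) -> float:
    """Squared Euclidean translation energy ``||h + r − t||²``.

    Zero iff the translation is exact (h + r = t).
    """
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (h.shape == r.shape == t.shape):
        raise ValueError(
            f"dimension mismatch among h {h.shape}, r {r.shape}, t {t.shape}"
        )
    diff = h + r - t
    return float(diff @ diff)


def minmax_normalize(distances) -> np.ndarray:
    """Min–max normalize a non-empty sequence onto [0, 1], order-preserving.

    Degenerate corpus (all values equal, including a single value) maps to
    all zeros — no spread means no evidence of implausibility; a warning is
    logged so the degenerate case is visible.
    """
    arr = np.asarray(list(distances), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot min-max normalize an empty sequence")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        logger.warning(
            "min-max normalization degenerate: all %d value(s) equal %.6g; "
            "returning zeros", arr.size, lo,
        )
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def semantic_scores(
    triples: TripleSet, backend: EmbeddingBackend
) -> list[SemanticResult]:
    """Score every triple in a corpus; one result per triple, same order.

    ``score_i = 1 − minmax(d_trans)_i``: smaller distance, higher score.
    Embedding errors are re-raised naming the offending triple.
    """
    if len(triples) == 0:
        raise ValueError("semantic_scores requires a non-empty TripleSet")
    distances = []
    maybe_norm = (lambda v: v / np.linalg.norm(v)) if backend.normalized else (lambda v: v)
    for t in triples:
        try:
            h = maybe_norm(backend.embed(t.head))
            r = maybe_norm(backend.embed(t.relation))
            tl = maybe_norm(backend.embed(t.tail))
        except ValueError as exc:
            raise ValueError(f"embedding failed for triple {t.triple_id}: {exc}") from exc
        distances.append(translation_distance(h, r, tl))
    scores = 1.0 - minmax_normalize(distances)
    return [
        SemanticResult(triple_id=t.triple_id, raw_distance=d, score=float(s))
        for t, d, s in zip(triples, distances, scores)
    ]


def summarize_semantic(results, ddof: int = 1) -> ScoreSummary:
    """Corpus summary (mean, SD, min, max) of semantic plausibility scores."""
    return summarize_scores([r.score for r in results], ddof=ddof)
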