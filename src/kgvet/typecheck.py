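"""Ontology-grounded type-compatibility scoring.

Each triple endpoint is matched to the ontology and assigned a *type set*
(its own semantic type plus all ancestor types). Compatibility is the
Jaccard similarity of the two sets,

    Jaccard(T_head, T_tail) = |T_head ∩ T_tail| / |T_head ∪ T_tail|,

which rewards entities that sit under shared generalized categories. When
either endpoint has no ontology match, a hybrid fallback scores the pair by
embedding cosine similarity of the two labels, affinely mapped onto [0, 1]
via (1 + cos)/2 so ordering over the full cosine range is preserved.

Every matched pair shares at least the root's type, which floors the
ontology-path Jaccard above 0 — a known score-inflation source, disclosed
rather than corrected. Relation-aware type constraints (e.g. drug—treats→
condition legality) are deliberately not enforced; ``RELATION_RULES`` is an
empty hook for future rule-based checks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .embeddings import EmbeddingBackend, cosine_similarity
from .ontology import MatchResult, OntologyGraph, match_entity, type_set
from .stats import ScoreSummary, summarize_scores
from .triples import Triple

__all__ = [
    "TypeResult",
    "TypeSummary",
    "jaccard",
    "fallback_similarity",
    "type_score",
    "summarize_type",
    "RELATION_RULES",
]

#: Hook for relation-specific type legality rules; intentionally ships empty.
RELATION_RULES: dict[str, callable] = {}


@dataclass(frozen=True)
class TypeResult:
    triple_id: str
    score: float            # in [0, 1]
    method: str             # "ontology" iff both endpoints matched, else "fallback"
    head_match: MatchResult
    tail_match: MatchResult


@dataclass(frozen=True)
class TypeSummary:
    scores: ScoreSummary
    fallback_fraction: float

    def as_dict(self) -> dict:
        d = self.scores.as_dict()
        d["fallback_fraction"] = self.fallback_fraction
        return d


def jaccard(a: set, b: set) -> float:
    """Intersection over union of two sets; 1 iff equal, 0 iff disjoint."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("Jaccard undefined for two empty sets (untypeable pair)")
    return len(a & b) / len(a | b)


def fallback_similarity(
    head_label: str, tail_label: str, backend: EmbeddingBackend
) -> float:
    """Embedding proxy for type compatibility: (1 + cos(h, t)) / 2 ∈ [0, 1]."""
    cos = cosine_similarity(backend.embed(head_label), backend.embed(tail_label))
    return (1.0 + cos) / 2.0


def type_score(
    triple: Triple, graph: OntologyGraph, backend: EmbeddingBackend
) -> TypeResult:
    """Hybrid type-compatibility score for one triple.

    Both endpoints matched → Jaccard of their type sets (method
    ``ontology``); otherwise — including when only one side is missing,
    since Jaccard needs both sets — the embedding fallback (method
    ``fallback``). The relation label never affects the score.
    """
    hm = match_entity(triple.head, graph)
    tm = match_entity(triple.tail, graph)
    if hm.matched and tm.matched:
        score = jaccard(type_set(hm.node_id, graph), type_set(tm.node_id, graph))
        method = "ontology"
    else:
        score = fallback_similarity(triple.head, triple.tail, backend)
        method = "fallback"
    return TypeResult(
        triple_id=triple.triple_id,
        score=float(score),
        method=method,
        head_match=hm,
        tail_match=tm,
    )


def summarize_type(results, ddof: int = 1) -> TypeSummary:
    """Summary over type scores plus the fraction resolved via fallback."""
    results = list(results)
    if not results:
        raise ValueError("cannot summarize an empty type-result sequence")
    n_fb = sum(1 for r in results if r.method == "fallback")
    return TypeSummary(
        scores=summarize_scores([r.score for r in results], ddof=ddof),
        fallback_fraction=n_fb / len(results),
    )
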