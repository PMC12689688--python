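"""Structural-importance scoring via ResourceRank and connectivity checks.

ResourceRank is a damped rank-propagation centrality over the ontology,

    R(v_i) = (1 − d) + d · Σ_{v_j ∈ In(v_i)} R(v_j) / |Out(v_j)|,

with damping d = 0.85 by default. It quantifies how central and
well-connected an entity is within trusted clinical knowledge: both the
number of entities linking to it and the importance of those linkers count.
The recurrence is implemented exactly as written: dangling nodes
(|Out| = 0) contribute nothing to any sum, so total rank is not conserved —
unlike classical PageRank, which rescales the baseline by 1/N and
redistributes dangling mass. A ``dangling="redistribute"`` compatibility
switch enables uniform redistribution for comparison. The fixed point is
unique (the iteration matrix has spectral radius ≤ d < 1) and is reached by
iteration from an all-ones start; every rank is bounded below by 1 − d.

A triple is *resource valid* when both endpoints match ontology nodes and
are connected by a plausible path: a direct edge, a hierarchy role
(parent / child / sibling), or a short indirect path. Triples with an
unmatched endpoint are *flagged* — rare, isolated or out-of-vocabulary
entities — and score 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .ontology import OntologyGraph, ancestors, match_entity
from .stats import ScoreSummary, summarize_scores
from .triples import Triple

__all__ = [
    "RankVector",
    "ResourceResult",
    "ResourceSummary",
    "resource_rank",
    "normalize_ranks",
    "connectivity_class",
    "resource_validate",
    "summarize_resource",
]

logger = logging.getLogger(__name__)

CONNECTIVITY_CLASSES = ("direct", "parent", "child", "sibling", "indirect", "none")


@dataclass(frozen=True)
class RankVector:
    ranks: dict[str, float]
    damping: float
    iterations_used: int
    converged: bool

    def __getitem__(self, node_id: str) -> float:
        return self.ranks[node_id]


@dataclass(frozen=True)
class ResourceResult:
    triple_id: str
    head_rank_norm: float | None
    tail_rank_norm: float | None
    score: float
    connectivity: str       # one of CONNECTIVITY_CLASSES
    resource_valid: bool
    flagged: bool           # true iff head or tail failed ontology matching


@dataclass(frozen=True)
class ResourceSummary:
    scores: ScoreSummary | None  # over non-flagged triples (None if all flagged)
    flagged_count: int
    valid_fraction: float        # resource-valid fraction of all triples

    def as_dict(self) -> dict:
        d = self.scores.as_dict() if self.scores is not None else {
            "mean": None, "sd": None, "min": None, "max": None, "n": 0}
        d["flagged_count"] = self.flagged_count
        d["valid_fraction"] = self.valid_fraction
        return d


def _scope_graph(graph: OntologyGraph, edge_scope: str) -> nx.DiGraph:
    if edge_scope == "union":
        return graph.union_graph
    if edge_scope == "hierarchy_only":
        return graph.hierarchy
    raise ValueError(f"unknown edge_scope {edge_scope!r}; use union or hierarchy_only")


def resource_rank(
    graph: OntologyGraph,
    damping: float = 0.85,
    tolerance: float = 1e-8,
    max_iterations: int = 500,
    edge_scope: str = "union",
    dangling: str = "as_printed",
) -> RankVector:
    """Iterate the ResourceRank recurrence to its fixed point.

    Initialization is all-ones; convergence is max-norm change below
    ``tolerance``. Non-convergence returns the last iterate with
    ``converged=False`` and a warning rather than raising.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie strictly in (0, 1)")
    g = _scope_graph(graph, edge_scope)
    node_ids = sorted(g.nodes())
    n = len(node_ids)
    if n == 0:
        raise ValueError("cannot rank an empty ontology")
    index = {nid: i for i, nid in enumerate(node_ids)}

    # M[j, i] = 1/|Out(v_j)| for each edge j -> i; dangling rows stay zero
    # under the as_printed rule.
    out_deg = np.array([g.out_degree(nid) for nid in node_ids], dtype=float)
    rows, cols, vals = [], [], []
    for u, v in g.edges():
        j, i = index[u], index[v]
        rows.append(i)
        cols.append(j)
        vals.append(1.0 / out_deg[j])
    from scipy.sparse import csr_matrix

    mt = csr_matrix((vals, (rows, cols)), shape=(n, n))  # this is M^T
    dangling_mask = out_deg == 0

    r = np.ones(n)
    converged = False
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        new = (1.0 - damping) + damping * (mt @ r)
        if dangling == "redistribute" and dangling_mask.any():
            new = new + damping * r[dangling_mask].sum() / n
        delta = float(np.max(np.abs(new - r)))
        r = new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        logger.warning(
            "ResourceRank did not converge in %d iterations (tol %.1e)",
            max_iterations, tolerance,
        )
    return RankVector(
        ranks={nid: float(r[index[nid]]) for nid in node_ids},
        damping=damping,
        iterations_used=iterations,
        converged=converged,
    )


def normalize_ranks(ranks: RankVector) -> dict[str, float]:
    """Min–max normalize ranks onto [0, 1] over all ontology nodes.

    Degenerate (all ranks equal) maps to 1.0 everywhere: a uniformly
    connected graph gives no node a reason to be down-weighted.
    """
    values = np.array(list(ranks.ranks.values()))
    if values.size == 0:
        raise ValueError("empty rank vector")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return {nid: 1.0 for nid in ranks.ranks}
    return {nid: (v - lo) / (hi - lo) for nid, v in ranks.ranks.items()}


def connectivity_class(
    head_node: str,
    tail_node: str,
    graph: OntologyGraph,
    max_hops: int = 3,
) -> str:
    """Classify how two matched ontology nodes relate structurally.

    Precedence: ``direct`` (a 1-hop edge in either direction, any edge
    type) > hierarchy roles — ``parent`` (head is an ancestor of tail),
    ``child`` (head is a descendant of tail), ``sibling`` (shared direct
    is_a parent) > ``indirect`` (undirected path of length ≤ ``max_hops``
    in the union graph) > ``none``. Path plausibility ignores edge
    direction: clinical relatedness reads both ways.
    """
    for nid in (head_node, tail_node):
        if nid not in graph:
            raise KeyError(f"unknown ontology node {nid!r}")
    if head_node == tail_node:
        return "direct"
    union = graph.union_graph
    if union.has_edge(head_node, tail_node) or union.has_edge(tail_node, head_node):
        return "direct"
    head_anc = ancestors(head_node, graph)
    tail_anc = ancestors(tail_node, graph)
    if head_node in tail_anc:
        return "parent"
    if tail_node in head_anc:
        return "child"
    head_parents = set(graph.hierarchy.successors(head_node))
    tail_parents = set(graph.hierarchy.successors(tail_node))
    if head_parents & tail_parents:
        return "sibling"
    undirected = union.to_undirected(as_view=True)
    try:
        dist = nx.shortest_path_length(undirected, head_node, tail_node)
    except nx.NetworkXNoPath:
        return "none"
    return "indirect" if dist <= max_hops else "none"


def resource_validate(
    triple: Triple,
    graph: OntologyGraph,
    ranks: RankVector,
    max_hops: int = 3,
    combiner: str = "mean",
    normalized_ranks: dict[str, float] | None = None,
) -> ResourceResult:
    """Score one triple's structural importance.

    Unmatched endpoint → flagged, score 0, not resource valid. Otherwise
    the score combines the endpoints' min–max-normalized ranks (arithmetic
    mean by default, ``min`` available) and the triple is resource valid
    when the endpoints are connected (connectivity ≠ none).
    """
    if combiner not in ("mean", "min"):
        raise ValueError(f"unknown combiner {combiner!r}; use mean or min")
    norm = normalized_ranks if normalized_ranks is not None else normalize_ranks(ranks)
    hm = match_entity(triple.head, graph)
    tm = match_entity(triple.tail, graph)
    if not (hm.matched and tm.matched):
        return ResourceResult(
            triple_id=triple.triple_id,
            head_rank_norm=norm.get(hm.node_id) if hm.matched else None,
            tail_rank_norm=norm.get(tm.node_id) if tm.matched else None,
            score=0.0,
            connectivity="none",
            resource_valid=False,
            flagged=True,
        )
    hr, tr = norm[hm.node_id], norm[tm.node_id]
    score = (hr + tr) / 2.0 if combiner == "mean" else min(hr, tr)
    conn = connectivity_class(hm.node_id, tm.node_id, graph, max_hops=max_hops)
    return ResourceResult(
        triple_id=triple.triple_id,
        head_rank_norm=hr,
        tail_rank_norm=tr,
        score=float(score),
        connectivity=conn,
        resource_valid=conn != "none",
        flagged=False,
    )


def summarize_resource(
    results, ddof: int = 1, include_flagged: bool = False
) -> ResourceSummary:
    """Summary over resource scores plus flag/validity counts.

    Flagged triples (score 0 by fiat) are excluded from the score summary
    by default so the mean reflects matched entities; switchable.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot summarize an empty resource-result sequence")
    flagged = sum(1 for r in results if r.flagged)
    pool = results if include_flagged else [r for r in results if not r.flagged]
    summary = summarize_scores([r.score for r in pool], ddof=ddof) if pool else None
    return ResourceSummary(
        scores=summary,
        flagged_count=flagged,
        valid_fraction=sum(1 for r in results if r.resource_valid) / len(results),
    )
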