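"""Ontology representation, entity matching, and type-set extraction.

The ontology is a labeled directed graph over clinical concepts in which
hierarchy (``is_a``) edges — stored child→parent — are distinguished from
other relational edges (``treats``, ``monitors``, ...). The hierarchy must
be a DAG; this is checked at load time with a named cycle witness.

Two inputs are supported:

* ``edge_tsv`` — one edge per line, ``child<TAB>relation<TAB>parent``;
  relation ``is_a`` goes to the hierarchy, anything else is relational.
  Node metadata (label, semantic type, synonyms) lives in an optional
  sidecar TSV ``node_id<TAB>label<TAB>semantic_type<TAB>syn1|syn2``.
* ``obo`` — an OBO 1.4 subset (``[Term]``, ``id:``, ``name:``, ``is_a:``,
  ``relationship:``, ``synonym:``), parsed with :mod:`obonet`.

Entity matching tries the exact preferred label, then a normalized form
(lowercase, collapsed whitespace, stripped edge punctuation), then
synonyms, in that order; ambiguous normalized labels resolve to the
lexicographically smallest node id with a warning — determinism over
silent ambiguity.

Ancestor closure runs over hierarchy edges only; relational edges are used
only by connectivity checks in resource validation. An entity's *type set*
is its own semantic type plus the types of all its ancestors — the
ancestors supply the generalized semantic categories that type
compatibility is judged against.
"""

from __future__ import annotations

import logging
import re
import string
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path

import networkx as nx

__all__ = [
    "OntologyNode",
    "OntologyGraph",
    "MatchResult",
    "load_ontology",
    "match_entity",
    "ancestors",
    "type_set",
    "normalize_label",
]

logger = logging.getLogger(__name__)

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Lowercase, collapse internal whitespace, strip edge punctuation."""
    out = _WS.sub(" ", label.strip().lower())
    return out.strip(string.punctuation + " ")


@dataclass(frozen=True)
class OntologyNode:
    node_id: str
    label: str
    semantic_type: str | None = None
    synonyms: tuple[str, ...] = ()

    @property
    def effective_type(self) -> str:
        """Nodes without an explicit semantic type default to their own
        label as type, which keeps every type set non-empty."""
        return self.semantic_type if self.semantic_type else self.label


@dataclass(frozen=True)
class MatchResult:
    query: str
    node_id: str | None
    match_kind: str  # exact | normalized | synonym | none

    @property
    def matched(self) -> bool:
        return self.node_id is not None


class OntologyGraph:
    """Validated ontology: node table + hierarchy DAG + relational edges."""

    def __init__(
        self,
        nodes: dict[str, OntologyNode],
        hierarchy_edges: list[tuple[str, str]],
        relational_edges: list[tuple[str, str, str]] = (),
    ) -> None:
        self.nodes = dict(nodes)
        for (u, v) in hierarchy_edges:
            self._require(u)
            self._require(v)
        for (u, v, _rel) in relational_edges:
            self._require(u)
            self._require(v)

        self.hierarchy = nx.DiGraph()
        self.hierarchy.add_nodes_from(self.nodes)
        self.hierarchy.add_edges_from(hierarchy_edges)
        if not nx.is_directed_acyclic_graph(self.hierarchy):
            cycle = nx.find_cycle(self.hierarchy)
            witness = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
            raise ValueError(f"hierarchy (is_a) edges contain a cycle: {witness}")

        self.relational = nx.MultiDiGraph()
        self.relational.add_nodes_from(self.nodes)
        for (u, v, rel) in relational_edges:
            self.relational.add_edge(u, v, key=rel, relation=rel)

        logger.info(
            "ontology loaded: %d nodes, %d hierarchy edges, %d relational edges",
            len(self.nodes), self.hierarchy.number_of_edges(),
            self.relational.number_of_edges(),
        )

    def _require(self, node_id: str) -> None:
        if node_id not in self.nodes:
            raise ValueError(f"dangling edge endpoint: unknown node {node_id!r}")

    # -- derived views -------------------------------------------------

    @cached_property
    def union_graph(self) -> nx.DiGraph:
        """Hierarchy + relational edges as one simple directed graph
        (parallel edges collapsed: out-degree counts distinct targets)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.hierarchy.edges())
        g.add_edges_from((u, v) for u, v, _k in self.relational.edges(keys=True))
        return g

    @cached_property
    def _match_index(self) -> tuple[dict, dict, dict]:
        exact: dict[str, list[str]] = {}
        norm: dict[str, list[str]] = {}
        syn: dict[str, list[str]] = {}
        for nid, node in self.nodes.items():
            exact.setdefault(node.label, []).append(nid)
            norm.setdefault(normalize_label(node.label), []).append(nid)
            for s in node.synonyms:
                syn.setdefault(normalize_label(s), []).append(nid)
        return exact, norm, syn

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)


def _pick(candidates: list[str], label: str, tier: str) -> str:
    if len(candidates) > 1:
        logger.warning(
            "label %r matches %d nodes at the %s tier; taking smallest id %s",
            label, len(candidates), tier, min(candidates),
        )
    return min(candidates)


def match_entity(label: str, graph: OntologyGraph) -> MatchResult:
    """Match a free-text label to an ontology node. Deterministic and
    total: no-match is a valid result, not an error."""
    if not label or not label.strip():
        raise ValueError("cannot match an empty label")
    exact, norm, syn = graph._match_index
    if label in exact:
        return MatchResult(label, _pick(exact[label], label, "exact"), "exact")
    key = normalize_label(label)
    if key in norm:
        return MatchResult(label, _pick(norm[key], label, "normalized"), "normalized")
    if key in syn:
        return MatchResult(label, _pick(syn[key], label, "synonym"), "synonym")
    return MatchResult(label, None, "none")


def ancestors(node_id: str, graph: OntologyGraph) -> set[str]:
    """All nodes reachable from ``node_id`` by following is_a edges upward
    (transitive closure over hierarchy edges only, excluding the node)."""
    if node_id not in graph:
        raise KeyError(f"unknown ontology node {node_id!r}")
    return set(nx.descendants(graph.hierarchy, node_id))


def type_set(node_id: str, graph: OntologyGraph) -> set[str]:
    """The entity's own semantic type plus the types of all its ancestors."""
    if node_id not in graph:
        raise KeyError(f"unknown ontology node {node_id!r}")
    types = {graph.nodes[node_id].effective_type}
    for a in ancestors(node_id, graph):
        types.add(graph.nodes[a].effective_type)
    return types


# -- loading -----------------------------------------------------------


_OBO_SYN = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _load_edge_tsv(path: Path, nodes_path: Path | None) -> OntologyGraph:
    hier: list[tuple[str, str]] = []
    rel: list[tuple[str, str, str]] = []
    endpoint_ids: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected child<TAB>relation<TAB>parent, got {line!r}"
            )
        child, relation, parent = (p.strip() for p in parts)
        endpoint_ids += [child, parent]
        if relation == "is_a":
            hier.append((child, parent))
        else:
            rel.append((child, parent, relation))

    if nodes_path is None:
        candidate = path.with_suffix(".nodes.tsv")
        nodes_path = candidate if candidate.exists() else None

    nodes: dict[str, OntologyNode] = {}
    if nodes_path is not None:
        for lineno, line in enumerate(
            Path(nodes_path).read_text(encoding="utf-8").splitlines(), 1
        ):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{nodes_path}:{lineno}: expected node_id<TAB>label[<TAB>type[<TAB>syns]]"
                )
            nid = parts[0].strip()
            label = parts[1].strip()
            stype = parts[2].strip() if len(parts) > 2 and parts[2].strip() else None
            syns = tuple(
                s.strip() for s in parts[3].split("|") if s.strip()
            ) if len(parts) > 3 else ()
            nodes[nid] = OntologyNode(nid, label, stype, syns)
        missing = sorted(set(endpoint_ids) - set(nodes))
        if missing:
            raise ValueError(
                f"dangling edge endpoint(s) not in node sidecar {nodes_path}: {missing}"
            )
    else:
        for nid in endpoint_ids:
            nodes.setdefault(nid, OntologyNode(nid, nid))
    return OntologyGraph(nodes, hier, rel)


def _load_obo(path: Path) -> OntologyGraph:
    import obonet

    g = obonet.read_obo(str(path))
    nodes: dict[str, OntologyNode] = {}
    for nid, data in g.nodes(data=True):
        syns = tuple(
            m.group(1) for raw in data.get("synonym", ())
            if (m := _OBO_SYN.search(raw))
        )
        # No dedicated semantic-type tag in plain OBO; namespace serves when
        # present, else the node label becomes its own type.
        nodes[nid] = OntologyNode(
            node_id=nid,
            label=data.get("name", nid),
            semantic_type=data.get("namespace"),
            synonyms=syns,
        )
    hier: list[tuple[str, str]] = []
    rel: list[tuple[str, str, str]] = []
    for u, v, key in g.edges(keys=True):
        if key == "is_a":
            hier.append((u, v))
        else:
            rel.append((u, v, key))
    return OntologyGraph(nodes, hier, rel)


def load_ontology(
    path: str | Path,
    format: str = "edge_tsv",
    nodes_path: str | Path | None = None,
) -> OntologyGraph:
    """Load and validate an ontology from ``edge_tsv`` or ``obo`` input.

    Raises on hierarchy cycles (with a witness) and on edges referencing
    nodes absent from an explicit node table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ontology file not found: {path}")
    if format == "edge_tsv":
        return _load_edge_tsv(path, Path(nodes_path) if nodes_path else None)
    if format == "obo":
        return _load_obo(path)
    raise ValueError(f"unknown ontology format {format!r}; supported: edge_tsv, obo")
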