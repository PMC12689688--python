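"""Seeded synthetic fixtures: toy clinical ontology, labeled triple corpora,
and planted embedding tables.

The generators emulate the *structure* of a chronic-kidney-disease ontology
and of LLM-generated triples about it, so that every validation component
is testable offline with known ground truth:

* :func:`generate_toy_ontology` — a rooted DAG with four typed branches
  (condition, medication, procedure, lab_finding), each a 3-level tree
  (branch root → two subcategories → leaves), plus a few cross-branch
  relational edges (medication —treats→ condition, procedure —diagnoses→
  condition, lab_finding —monitors→ condition).
* :func:`generate_labeled_triples` — *plausible* triples follow existing
  edges or pair hierarchy siblings; *implausible* triples connect
  cross-branch node pairs with no short path; *unmatched* triples carry a
  tail label provably absent from the ontology (these are the triples
  resource validation must flag).
* :func:`plant_embeddings` — a vector table realizing the translation
  regime: for plausible triples the tail vector is head + relation +
  Gaussian noise, for implausible triples the tail is an independent
  random direction. Entities keep the vector from their first assignment;
  conflicts are logged, and plausible triples are sampled with
  entity-disjoint tails whenever counts permit so the planted oracle stays
  clean.

Branch vocabulary is synthetic but domain-flavored (``drug_07``,
``condition_03``) — readable fixtures without real clinical content.
Everything is deterministic per seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .embeddings import PlantedEmbeddingBackend
from .ontology import OntologyGraph, OntologyNode, load_ontology
from .triples import Triple, TripleSet, read_triples, write_triples

__all__ = [
    "FixtureBundle",
    "generate_toy_ontology",
    "generate_labeled_triples",
    "plant_embeddings",
    "make_fixture_bundle",
    "BRANCHES",
]

logger = logging.getLogger(__name__)

#: branch name -> (leaf label stem, leaf semantic type)
BRANCHES = {
    "condition": ("condition", "disorder"),
    "medication": ("drug", "drug"),
    "procedure": ("procedure", "intervention"),
    "lab_finding": ("lab", "measurement"),
}

_CROSS_RELATIONS = [
    ("medication", "treats", "condition"),
    ("procedure", "diagnoses", "condition"),
    ("lab_finding", "monitors", "condition"),
]

ROOT_ID = "clinical_entity"


def toy_ontology_node_count(n_per_branch: int) -> int:
    """1 root + per branch: 1 branch root + 2 subcategories + n leaves."""
    return 1 + len(BRANCHES) * (3 + n_per_branch)


def generate_toy_ontology(n_per_branch: int = 12, seed: int = 0) -> OntologyGraph:
    """Build the toy clinical ontology; deterministic per seed.

    Hierarchy: leaf —is_a→ subcategory —is_a→ branch root —is_a→ root.
    The seed only affects which leaves get cross-branch relational edges.
    """
    if n_per_branch < 1:
        raise ValueError("n_per_branch must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: dict[str, OntologyNode] = {
        ROOT_ID: OntologyNode(ROOT_ID, "clinical entity", "entity")
    }
    hier: list[tuple[str, str]] = []
    rel: list[tuple[str, str, str]] = []
    leaves: dict[str, list[str]] = {}

    for branch, (stem, leaf_type) in BRANCHES.items():
        broot = f"{branch}_branch"
        nodes[broot] = OntologyNode(broot, branch.replace("_", " "), branch)
        hier.append((broot, ROOT_ID))
        subcats = []
        for g in (1, 2):
            sub = f"{branch}_group_{g}"
            nodes[sub] = OntologyNode(sub, f"{branch} group {g}", f"{branch}_category")
            hier.append((sub, broot))
            subcats.append(sub)
        leaves[branch] = []
        for k in range(1, n_per_branch + 1):
            nid = f"{stem}_{k:02d}"
            nodes[nid] = OntologyNode(
                nid, nid, leaf_type,
                synonyms=(nid.upper().replace("_", "-"),),
            )
            hier.append((nid, subcats[(k - 1) % 2]))
            leaves[branch].append(nid)

    n_rel = max(1, n_per_branch // 3)
    for src_branch, relation, dst_branch in _CROSS_RELATIONS:
        src = rng.choice(leaves[src_branch], size=n_rel, replace=False)
        dst = rng.choice(leaves[dst_branch], size=n_rel, replace=False)
        for u, v in zip(src, dst):
            rel.append((str(u), str(v), relation))

    return OntologyGraph(nodes, hier, rel)


def _leaf_ids(graph: OntologyGraph) -> dict[str, list[str]]:
    """Leaves (in-degree 0 in the hierarchy) grouped by branch."""
    out: dict[str, list[str]] = {b: [] for b in BRANCHES}
    for branch in BRANCHES:
        broot = f"{branch}_branch"
        for nid in sorted(nx.ancestors(graph.hierarchy, broot)):
            if graph.hierarchy.in_degree(nid) == 0:
                out[branch].append(nid)
    return out


def generate_labeled_triples(
    graph: OntologyGraph,
    n_plausible: int = 100,
    n_implausible: int = 100,
    n_unmatched: int = 10,
    seed: int = 0,
    max_hops: int = 3,
) -> tuple[TripleSet, dict[str, str], set[str]]:
    """Sample a labeled corpus from a toy ontology; deterministic per seed.

    Returns ``(triples, labels, unmatched_ids)`` where ``labels`` maps
    every triple_id to ``plausible`` or ``implausible`` (unmatched triples
    are labeled implausible — their tails are planted off-translation —
    and additionally listed in ``unmatched_ids``).
    """
    if min(n_plausible, n_implausible, n_unmatched) < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    leaves = _leaf_ids(graph)
    label_of = lambda nid: graph.nodes[nid].label

    # Plausible candidates: sibling leaf pairs, hierarchy edges, relational
    # edges. Greedy pass prefers candidates whose tail entity is fresh so
    # the planted translation t = h + r + eps has no vector conflicts.
    candidates: list[tuple[str, str, str]] = []
    for branch in BRANCHES:
        for nid in leaves[branch]:
            parent = next(iter(graph.hierarchy.successors(nid)))
            candidates.append((nid, "is a", parent))
    for u, v in graph.hierarchy.edges():
        if graph.hierarchy.in_degree(u) > 0:  # subcat/branch-level is_a
            candidates.append((u, "is a", v))
    for u, v, key in graph.relational.edges(keys=True):
        candidates.append((u, key.replace("_", " "), v))
    sibling_pairs = []
    for branch in BRANCHES:
        for nid in leaves[branch]:
            parent = next(iter(graph.hierarchy.successors(nid)))
            for other in graph.hierarchy.predecessors(parent):
                if other != nid:
                    sibling_pairs.append((nid, "is related to", other))
    candidates += sibling_pairs
    rng.shuffle(candidates)

    candidates = [(h, r, t) for h, r, t in candidates if h != t]
    used_entities: set[str] = set()
    planted_tails: set[str] = set()
    plausible: list[tuple[str, str, str]] = []
    remaining = list(candidates)
    while len(plausible) < n_plausible and remaining:
        # Tail must be fresh so its vector can be set to h + r + eps.
        # Prefer reusing a head that was never itself a planted tail (its
        # vector is a unit vector, so translated tails keep bounded norm
        # and distances stay on one scale); then a fully fresh pair; only
        # then a head that is a planted tail (starts a translation chain).
        def tier(cand) -> int:
            h, _r, t = cand
            if t in used_entities:
                return 3
            if h in used_entities and h not in planted_tails:
                return 0
            if h not in used_entities:
                return 1
            return 2

        pick = min(remaining, key=tier)
        if tier(pick) == 3:
            break
        remaining.remove(pick)
        plausible.append(pick)
        used_entities.update((pick[0], pick[2]))
        planted_tails.add(pick[2])
    if len(plausible) < n_plausible:
        logger.warning(
            "only %d fresh-tail plausible candidates; reusing tails "
            "(planted-vector conflicts will be logged)", len(plausible),
        )
        for cand in remaining:
            if len(plausible) >= n_plausible:
                break
            plausible.append(cand)
    if len(plausible) < n_plausible:
        raise ValueError(
            f"graph too small: only {len(plausible)} plausible candidates "
            f"available, {n_plausible} requested"
        )

    # Implausible: ordered cross-branch leaf pairs farther apart than
    # max_hops in the undirected union graph.
    undirected = graph.union_graph.to_undirected(as_view=True)
    branches = list(BRANCHES)
    implausible: list[tuple[str, str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    relations = ["causes", "treats", "is associated with"]
    attempts = 0
    max_attempts = 200 * max(n_implausible, 1) + 1000
    while len(implausible) < n_implausible and attempts < max_attempts:
        attempts += 1
        b1, b2 = rng.choice(branches, size=2, replace=False)
        h = str(rng.choice(leaves[b1]))
        t = str(rng.choice(leaves[b2]))
        if (h, t) in seen_pairs:
            continue
        try:
            dist = nx.shortest_path_length(undirected, h, t)
        except nx.NetworkXNoPath:
            dist = np.inf
        if dist <= max_hops:
            continue
        seen_pairs.add((h, t))
        implausible.append((h, str(rng.choice(relations)), t))
    if len(implausible) < n_implausible:
        raise ValueError(
            f"graph too small/too connected: found {len(implausible)} "
            f"cross-branch pairs beyond {max_hops} hops, {n_implausible} requested"
        )

    all_leaves = [nid for b in BRANCHES for nid in leaves[b]]
    unmatched: list[tuple[str, str, str]] = []
    for k in range(1, n_unmatched + 1):
        h = str(rng.choice(all_leaves))
        unmatched.append((h, "is related to", f"unlisted entity {k:03d}"))

    def branch_of(nid: str) -> str:
        for b in BRANCHES:
            if nid in leaves[b] or nid.startswith(b):
                return b
        return "condition"

    triples: list[Triple] = []
    labels: dict[str, str] = {}
    unmatched_ids: set[str] = set()
    i = 0
    for group, lab in ((plausible, "plausible"), (implausible, "implausible"),
                       (unmatched, "implausible")):
        for h, r, t in group:
            i += 1
            tid = f"t{i:04d}"
            head_label = label_of(h) if h in graph.nodes else h
            tail_label = label_of(t) if t in graph.nodes else t
            triples.append(Triple(head_label, r, tail_label,
                                  concept_tag=branch_of(h), triple_id=tid))
            labels[tid] = lab
            if group is unmatched:
                unmatched_ids.add(tid)
    return TripleSet(triples), labels, unmatched_ids


def plant_embeddings(
    triples: TripleSet,
    labels: dict[str, str],
    noise_sd: float = 0.05,
    seed: int = 0,
    dimension: int = 32,
) -> dict[str, np.ndarray]:
    """Construct the planted vector table realizing ``h + r ≈ t`` for
    plausible triples and a displaced tail for implausible ones.

    Heads and relations get random unit vectors; a plausible triple's tail
    is set to head + relation + N(0, noise_sd²) per coordinate, an
    implausible triple's tail to an independent random unit vector. Text
    already assigned keeps its first vector (conflicts are logged), so the
    table is a single-valued function of the label.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    table: dict[str, np.ndarray] = {}

    def unit() -> np.ndarray:
        v = rng.standard_normal(dimension)
        return v / np.linalg.norm(v)

    def ensure(text: str) -> np.ndarray:
        if text not in table:
            table[text] = unit()
        return table[text]

    conflicts = 0
    for t in triples:
        h = ensure(t.head)
        r = ensure(t.relation)
        if t.tail in table:
            conflicts += 1
            continue
        if labels.get(t.triple_id) == "plausible":
            table[t.tail] = h + r + rng.normal(0.0, noise_sd, size=dimension)
        else:
            table[t.tail] = unit()
    if conflicts:
        logger.info("plant_embeddings: %d tail vector(s) kept first assignment", conflicts)
    return table


@dataclass
class FixtureBundle:
    """Everything one offline validation run needs, with ground truth."""

    ontology: OntologyGraph
    triples: TripleSet
    labels: dict[str, str]
    unmatched_ids: set[str]
    planted_vectors: dict[str, np.ndarray]
    seed: int
    params: dict = field(default_factory=dict)

    def backend(self) -> PlantedEmbeddingBackend:
        return PlantedEmbeddingBackend(self.planted_vectors, seed=self.seed)

    # -- disk round-trip (plain-text formats only) ----------------------

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        edge_lines = [f"{u}\tis_a\t{v}" for u, v in sorted(self.ontology.hierarchy.edges())]
        edge_lines += [
            f"{u}\t{k}\t{v}"
            for u, v, k in sorted(self.ontology.relational.edges(keys=True))
        ]
        (out / "ontology.tsv").write_text("\n".join(edge_lines) + "\n", encoding="utf-8")
        node_lines = []
        for nid in sorted(self.ontology.nodes):
            node = self.ontology.nodes[nid]
            node_lines.append(
                f"{nid}\t{node.label}\t{node.semantic_type or ''}\t{'|'.join(node.synonyms)}"
            )
        (out / "ontology.nodes.tsv").write_text("\n".join(node_lines) + "\n", encoding="utf-8")
        write_triples(self.triples, out / "triples.csv", "csv")
        label_lines = ["triple_id,label,unmatched"]
        for t in self.triples:
            label_lines.append(
                f"{t.triple_id},{self.labels[t.triple_id]},"
                f"{int(t.triple_id in self.unmatched_ids)}"
            )
        (out / "labels.csv").write_text("\n".join(label_lines) + "\n", encoding="utf-8")
        with (out / "vectors.jsonl").open("w", encoding="utf-8") as fh:
            for text in sorted(self.planted_vectors):
                fh.write(json.dumps(
                    {"text": text, "vector": [float(x) for x in self.planted_vectors[text]]}
                ) + "\n")
        (out / "meta.json").write_text(
            json.dumps({"seed": self.seed, "params": self.params}, indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, in_dir: str | Path) -> "FixtureBundle":
        src = Path(in_dir)
        ontology = load_ontology(src / "ontology.tsv", "edge_tsv",
                                 nodes_path=src / "ontology.nodes.tsv")
        triples = read_triples(src / "triples.csv", "csv")
        labels: dict[str, str] = {}
        unmatched: set[str] = set()
        for line in (src / "labels.csv").read_text(encoding="utf-8").splitlines()[1:]:
            if not line.strip():
                continue
            tid, lab, um = line.split(",")
            labels[tid] = lab
            if um == "1":
                unmatched.add(tid)
        vectors: dict[str, np.ndarray] = {}
        for line in (src / "vectors.jsonl").read_text(encoding="utf-8").splitlines():
            obj = json.loads(line)
            vectors[obj["text"]] = np.asarray(obj["vector"], dtype=float)
        meta = json.loads((src / "meta.json").read_text(encoding="utf-8"))
        return cls(ontology, triples, labels, unmatched, vectors,
                   seed=meta["seed"], params=meta.get("params", {}))


def make_fixture_bundle(
    n_per_branch: int = 30,
    n_plausible: int = 100,
    n_implausible: int = 100,
    n_unmatched: int = 10,
    noise_sd: float = 0.05,
    dimension: int = 32,
    seed: int = 0,
) -> FixtureBundle:
    """One-call default fixture: ontology + labeled corpus + planted table.

    Defaults are the standard study conditions used throughout the test
    suite: 120 leaves (30 per branch), 100 plausible + 100 implausible +
    10 unmatched triples, translation noise SD 0.05 in 32 dimensions.
    """
    ontology = generate_toy_ontology(n_per_branch=n_per_branch, seed=seed)
    triples, labels, unmatched_ids = generate_labeled_triples(
        ontology, n_plausible=n_plausible, n_implausible=n_implausible,
        n_unmatched=n_unmatched, seed=seed + 1,
    )
    vectors = plant_embeddings(triples, labels, noise_sd=noise_sd,
                               seed=seed + 2, dimension=dimension)
    return FixtureBundle(
        ontology=ontology,
        triples=triples,
        labels=labels,
        unmatched_ids=unmatched_ids,
        planted_vectors=vectors,
        seed=seed,
        params={
            "n_per_branch": n_per_branch,
            "n_plausible": n_plausible,
            "n_implausible": n_implausible,
            "n_unmatched": n_unmatched,
            "noise_sd": noise_sd,
            "dimension": dimension,
        },
    )
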