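"""Knowledge-graph triple data model and file dialects.

A triple is a directed ``(head, relation, tail)`` assertion — e.g.
``("Hypertension", "is treated with", "ACE inhibitors")`` — the atomic unit
of a knowledge graph. Triples produced by an LLM arrive either as structured
files (CSV/TSV/JSON-lines) or as raw model output containing bracketed spans
of the form ``[[entity1, relationship, entity2]]``.

Labels are preserved verbatim (case-sensitively); all fuzzy matching is the
ontology layer's job, so the raw LLM output stays auditable.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx

__all__ = [
    "Triple",
    "TripleSet",
    "ConceptKG",
    "read_triples",
    "write_triples",
    "parse_llm_bracket_output",
    "aggregate_concept_kgs",
    "DIALECTS",
]

#: Dialects understood by :func:`read_triples`.
DIALECTS = ("csv", "tsv", "jsonl", "llm_bracket")

#: Dialects :func:`write_triples` can produce (the bracket dialect is
#: read-only: it cannot represent concept tags or quoting).
WRITE_DIALECTS = ("csv", "tsv", "jsonl")

DEFAULT_CONCEPT = "_untagged"

_CSV_HEADER = ["head", "relation", "tail", "concept_tag"]


@dataclass(frozen=True)
class Triple:
    """One directed head–relation–tail assertion.

    All three labels must be non-empty after whitespace trimming; trimming
    happens at construction so downstream code never sees padded labels.
    """

    head: str
    relation: str
    tail: str
    concept_tag: str | None = None
    triple_id: str = ""

    def __post_init__(self) -> None:
        for name in ("head", "relation", "tail"):
            value = getattr(self, name)
            if not isinstance(value, str):
                raise TypeError(f"{name} must be a string, got {type(value).__name__}")
            trimmed = value.strip()
            if not trimmed:
                raise ValueError(f"triple {name} is empty after trimming")
            object.__setattr__(self, name, trimmed)
        if self.concept_tag is not None:
            tag = self.concept_tag.strip()
            object.__setattr__(self, "concept_tag", tag or None)

    def as_dict(self) -> dict:
        d = {"head": self.head, "relation": self.relation, "tail": self.tail}
        if self.concept_tag is not None:
            d["concept_tag"] = self.concept_tag
        return d


class TripleSet:
    """An ordered collection of :class:`Triple` with stable iteration order.

    For file-loaded sets the order equals file order. ``malformed_count``
    records how many records were rejected during parsing — malformed input
    is counted and reported, never silently dropped.
    """

    def __init__(
        self,
        triples: list[Triple] | None = None,
        provenance: str | None = None,
        malformed_count: int = 0,
    ) -> None:
        triples = list(triples or [])
        # Assign sequential ids to triples that carry none.
        assigned: list[Triple] = []
        for i, t in enumerate(triples):
            if not t.triple_id:
                t = Triple(t.head, t.relation, t.tail, t.concept_tag, f"t{i + 1:04d}")
            assigned.append(t)
        ids = [t.triple_id for t in assigned]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate triple_id(s) in TripleSet: {dupes}")
        self.triples = assigned
        self.provenance = provenance
        self.malformed_count = malformed_count

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __getitem__(self, i):
        return self.triples[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, TripleSet) and self.triples == other.triples

    def __repr__(self) -> str:
        return f"TripleSet(n={len(self)}, malformed={self.malformed_count})"

    def dedupe(self) -> "TripleSet":
        """Collapse exact (head, relation, tail, concept_tag) duplicates,
        keeping the first occurrence. Duplicates are kept by default
        everywhere else because they shift corpus-level min–max
        normalization and should stay user-visible."""
        seen: set[tuple] = set()
        kept = []
        for t in self.triples:
            key = (t.head, t.relation, t.tail, t.concept_tag)
            if key not in seen:
                seen.add(key)
                kept.append(t)
        return TripleSet(kept, provenance=self.provenance,
                         malformed_count=self.malformed_count)


@dataclass
class ConceptKG:
    """The sub-knowledge-graph of triples generated for one medical concept.

    ``adjacency`` is a head→tail multigraph keyed by relation label, the
    aggregate KG for the concept.
    """

    concept: str
    triples: TripleSet
    adjacency: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)

    def __post_init__(self) -> None:
        for t in self.triples:
            tag = t.concept_tag if t.concept_tag is not None else DEFAULT_CONCEPT
            if tag != self.concept:
                raise ValueError(
                    f"triple {t.triple_id} tagged {tag!r} placed in ConceptKG {self.concept!r}"
                )
        if self.adjacency.number_of_edges() == 0 and len(self.triples):
            for t in self.triples:
                self.adjacency.add_edge(t.head, t.tail, key=t.relation,
                                        relation=t.relation, triple_id=t.triple_id)


_BRACKET_SPAN = re.compile(r"\[\[(.*?)\]\]", re.DOTALL)


def parse_llm_bracket_output(text: str, provenance: str | None = None) -> TripleSet:
    """Extract triples from raw LLM output in the ``[[a, b, c]]`` dialect.

    Every non-overlapping ``[[...]]`` span is split on commas; spans with
    exactly three non-empty comma-separated fields become triples (fields
    whitespace-trimmed), anything else increments the malformed count.
    Always returns; degenerate input yields an empty set.
    """
    triples: list[Triple] = []
    malformed = 0
    for m in _BRACKET_SPAN.finditer(text or ""):
        fields = [f.strip() for f in m.group(1).split(",")]
        if len(fields) == 3 and all(fields):
            triples.append(Triple(*fields))
        else:
            malformed += 1
    return TripleSet(triples, provenance=provenance, malformed_count=malformed)


def _parse_delim(handle, delimiter: str) -> tuple[list[Triple], int]:
    reader = csv.reader(handle, delimiter=delimiter)
    rows = list(reader)
    if not rows:
        return [], 0
    header = [h.strip().lower() for h in rows[0]]
    try:
        idx = {k: header.index(k) for k in ("head", "relation", "tail")}
    except ValueError:
        raise ValueError(
            f"missing required column(s) in header {header!r}; "
            "expected head, relation, tail"
        )
    tag_idx = header.index("concept_tag") if "concept_tag" in header else None
    triples, malformed = [], 0
    for row in rows[1:]:
        if not row or all(not c.strip() for c in row):
            continue
        try:
            fields = [row[idx[k]] for k in ("head", "relation", "tail")]
            tag = None
            if tag_idx is not None and tag_idx < len(row) and row[tag_idx].strip():
                tag = row[tag_idx]
            triples.append(Triple(fields[0], fields[1], fields[2], tag))
        except (IndexError, ValueError):
            malformed += 1
    return triples, malformed


def _parse_jsonl(handle) -> tuple[list[Triple], int]:
    triples, malformed = [], 0
    for line in handle:
        line = line.strip()
        if not line:
            continue
        try:
            obj = json.loads(line)
            triples.append(
                Triple(obj["head"], obj["relation"], obj["tail"], obj.get("concept_tag"))
            )
        except (json.JSONDecodeError, KeyError, TypeError, ValueError):
            malformed += 1
    return triples, malformed


def read_triples(path: str | Path, dialect: str = "csv") -> TripleSet:
    """Load a triple file. Triples keep file order; malformed records are
    counted on the returned set, not silently dropped."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; supported: {', '.join(DIALECTS)}")
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot read triple file {path}: {exc}") from exc
    if dialect == "llm_bracket":
        out = parse_llm_bracket_output(text, provenance=str(path))
        return out
    handle = io.StringIO(text)
    if dialect == "jsonl":
        triples, malformed = _parse_jsonl(handle)
    else:
        triples, malformed = _parse_delim(handle, "\t" if dialect == "tsv" else ",")
    return TripleSet(triples, provenance=str(path), malformed_count=malformed)


def write_triples(tset: TripleSet, path: str | Path, dialect: str = "csv") -> None:
    """Write a TripleSet so that ``read_triples`` round-trips it exactly
    (labels, order, and sequentially assigned ids)."""
    if dialect not in WRITE_DIALECTS:
        raise ValueError(
            f"unknown write dialect {dialect!r}; supported: {', '.join(WRITE_DIALECTS)}"
        )
    path = Path(path)
    try:
        with path.open("w", encoding="utf-8", newline="") as fh:
            if dialect == "jsonl":
                for t in tset:
                    fh.write(json.dumps(t.as_dict(), ensure_ascii=False) + "\n")
            else:
                writer = csv.writer(fh, delimiter="\t" if dialect == "tsv" else ",")
                writer.writerow(_CSV_HEADER)
                for t in tset:
                    writer.writerow([t.head, t.relation, t.tail, t.concept_tag or ""])
    except OSError as exc:
        raise OSError(f"cannot write triple file {path}: {exc}") from exc


def aggregate_concept_kgs(tset: TripleSet) -> dict[str, ConceptKG]:
    """Group triples into one :class:`ConceptKG` per distinct concept tag,
    preserving file order within each group. Untagged triples group under
    ``_untagged``. The groups partition the input."""
    groups: dict[str, list[Triple]] = {}
    for t in tset:
        tag = t.concept_tag if t.concept_tag is not None else DEFAULT_CONCEPT
        groups.setdefault(tag, []).append(t)
    return {
        tag: ConceptKG(concept=tag, triples=TripleSet(ts))
        for tag, ts in groups.items()
    }
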