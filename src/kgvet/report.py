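"""Corpus-level orchestration of the three validation views.

``validate_corpus`` runs semantic scoring (one corpus-wide pass, because
min–max normalization couples triples), per-triple type scoring, and
resource validation (one rank computation, then per-triple checks), and
assembles a :class:`ValidationReport` holding per-triple records,
per-component summaries, accept/reject decisions and the full resolved
configuration. Stored summaries are recomputed from the per-triple records
on export as a self-consistency check.

Acceptance is a conjunctive threshold rule by default — every component
score must clear its threshold (0.75 each) and the triple must not be
flagged — switchable to a weighted average of the three scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .embeddings import EmbeddingBackend
from .ontology import OntologyGraph
from .resource import (
    ResourceResult,
    ResourceSummary,
    normalize_ranks,
    resource_rank,
    resource_validate,
    summarize_resource,
)
from .semantic import SemanticResult, semantic_scores, summarize_semantic
from .triples import DEFAULT_CONCEPT, TripleSet
from .typecheck import TypeResult, summarize_type, type_score

__all__ = [
    "TripleScores",
    "ValidationReport",
    "validate_corpus",
    "apply_thresholds",
    "export_report",
    "load_report",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
HISTOGRAM_BINS = 20
COMPONENTS = ("semantic", "type", "resource")


@dataclass(frozen=True)
class TripleScores:
    triple_id: str
    semantic: SemanticResult
    type: TypeResult
    resource: ResourceResult

    def __post_init__(self) -> None:
        ids = {self.semantic.triple_id, self.type.triple_id, self.resource.triple_id}
        if ids != {self.triple_id}:
            raise ValueError(f"sub-results disagree on triple_id: {ids}")

    def component_score(self, component: str) -> float:
        return getattr(self, component).score


@dataclass
class ValidationReport:
    per_triple: list[TripleScores]
    summaries: dict  # component -> summary dataclass
    config_snapshot: dict
    decisions: dict[str, str] = field(default_factory=dict)  # id -> accept|reject
    errors: list[dict] = field(default_factory=list)

    @property
    def accepted_ids(self) -> list[str]:
        return [tid for tid, d in self.decisions.items() if d == "accept"]

    @property
    def rejected_ids(self) -> list[str]:
        return [tid for tid, d in self.decisions.items() if d == "reject"]


def _recompute_summaries(per_triple: list[TripleScores], config: RunConfig) -> dict:
    ddof = config.sd_ddof
    return {
        "semantic": summarize_semantic([ts.semantic for ts in per_triple], ddof=ddof),
        "type": summarize_type([ts.type for ts in per_triple], ddof=ddof),
        "resource": summarize_resource([ts.resource for ts in per_triple], ddof=ddof),
    }


def validate_corpus(
    triples: TripleSet,
    graph: OntologyGraph,
    backend: EmbeddingBackend,
    config: RunConfig | None = None,
    keep_going: bool = False,
) -> ValidationReport:
    """Run all three views over a corpus; deterministic given backend+config.

    With ``keep_going``, per-triple failures in the type/resource stages are
    recorded in ``report.errors`` (with the triple id) instead of aborting;
    affected triples are dropped from per-triple records.
    """
    config = config or RunConfig()
    if len(triples) == 0:
        raise ValueError("cannot validate an empty corpus")
    if config.dedupe:
        triples = triples.dedupe()

    # Semantic view: min-max normalization is corpus-wide by default, or
    # within each concept KG when per_concept_normalization is set.
    if config.per_concept_normalization:
        by_id: dict[str, SemanticResult] = {}
        groups: dict[str, list] = {}
        for t in triples:
            groups.setdefault(t.concept_tag or DEFAULT_CONCEPT, []).append(t)
        for tag, group in groups.items():
            for res in semantic_scores(TripleSet(list(group)), backend):
                by_id[res.triple_id] = res
        sem = [by_id[t.triple_id] for t in triples]
    else:
        sem = semantic_scores(triples, backend)

    ranks = resource_rank(
        graph,
        damping=config.resource.damping,
        tolerance=config.resource.tolerance,
        max_iterations=config.resource.max_iterations,
        edge_scope=config.resource.edge_scope,
        dangling=config.resource.dangling,
    )
    logger.info("ResourceRank: %d iterations, converged=%s",
                ranks.iterations_used, ranks.converged)
    norm = normalize_ranks(ranks)

    per_triple: list[TripleScores] = []
    errors: list[dict] = []
    for t, s in zip(triples, sem):
        try:
            ty = type_score(t, graph, backend)
            rs = resource_validate(
                t, graph, ranks,
                max_hops=config.resource.max_hops,
                combiner=config.resource.combiner,
                normalized_ranks=norm,
            )
        except Exception as exc:
            if not keep_going:
                raise RuntimeError(f"validation failed for triple {t.triple_id}: {exc}") from exc
            errors.append({"triple_id": t.triple_id, "error": str(exc)})
            continue
        per_triple.append(TripleScores(t.triple_id, s, ty, rs))

    if not per_triple:
        raise RuntimeError("every triple failed validation")

    report = ValidationReport(
        per_triple=per_triple,
        summaries=_recompute_summaries(per_triple, config),
        config_snapshot=config.to_dict(),
        errors=errors,
    )
    report.decisions = apply_thresholds(report, config.thresholds,
                                        rule=config.combination_rule)
    return report


def apply_thresholds(
    report: ValidationReport,
    thresholds: dict | None = None,
    rule: str = "conjunctive",
) -> dict[str, str]:
    """Partition the corpus into accept/reject at per-component thresholds.

    Conjunctive rule (default): accepted iff every component score ≥ its
    threshold and the triple is not flagged. ``weighted_average``: accepted
    iff the unweighted mean of the three scores ≥ the mean threshold and
    not flagged. Partition sizes always sum to corpus size.
    """
    thresholds = dict(thresholds or {c: 0.75 for c in COMPONENTS})
    for c in COMPONENTS:
        th = thresholds.get(c, 0.75)
        if not 0.0 <= th <= 1.0:
            raise ValueError(f"threshold for {c} must lie in [0, 1], got {th}")
        thresholds[c] = th
    decisions: dict[str, str] = {}
    for ts in report.per_triple:
        if ts.resource.flagged:
            decisions[ts.triple_id] = "reject"
            continue
        if rule == "conjunctive":
            ok = all(ts.component_score(c) >= thresholds[c] for c in COMPONENTS)
        elif rule == "weighted_average":
            mean_score = np.mean([ts.component_score(c) for c in COMPONENTS])
            ok = mean_score >= np.mean([thresholds[c] for c in COMPONENTS])
        else:
            raise ValueError(f"unknown combination rule {rule!r}")
        decisions[ts.triple_id] = "accept" if ok else "reject"
    return decisions


# -- serialization -------------------------------------------------------


def _match_dict(m) -> dict:
    return {"query": m.query, "node_id": m.node_id, "match_kind": m.match_kind}


def _triple_record(ts: TripleScores) -> dict:
    return {
        "triple_id": ts.triple_id,
        "semantic": {"raw_distance": ts.semantic.raw_distance, "score": ts.semantic.score},
        "type": {
            "score": ts.type.score,
            "method": ts.type.method,
            "head_match": _match_dict(ts.type.head_match),
            "tail_match": _match_dict(ts.type.tail_match),
        },
        "resource": {
            "score": ts.resource.score,
            "head_rank_norm": ts.resource.head_rank_norm,
            "tail_rank_norm": ts.resource.tail_rank_norm,
            "connectivity": ts.resource.connectivity,
            "resource_valid": ts.resource.resource_valid,
            "flagged": ts.resource.flagged,
        },
    }


def _histograms(report: ValidationReport) -> dict:
    out = {}
    for c in COMPONENTS:
        scores = [ts.component_score(c) for ts in report.per_triple]
        counts, _edges = np.histogram(scores, bins=HISTOGRAM_BINS, range=(0.0, 1.0))
        out[c] = [int(x) for x in counts]
    return out


def _summary_dict(s) -> dict:
    return s.as_dict() if hasattr(s, "as_dict") else dict(s)


def _check_self_consistency(report: ValidationReport) -> None:
    cfg = RunConfig.from_dict(report.config_snapshot)
    fresh = _recompute_summaries(report.per_triple, cfg)
    for c in COMPONENTS:
        stored = _summary_dict(report.summaries[c])
        recomputed = _summary_dict(fresh[c])
        for key, want in recomputed.items():
            got = stored.get(key)
            if isinstance(want, float) and isinstance(got, float):
                if abs(want - got) > 1e-12:
                    raise ValueError(
                        f"summary self-consistency violated: {c}.{key} "
                        f"stored {got} vs recomputed {want}"
                    )
            elif got != want:
                raise ValueError(
                    f"summary self-consistency violated: {c}.{key} "
                    f"stored {got!r} vs recomputed {want!r}"
                )


def export_report(report: ValidationReport, path: str | Path, format: str = "json") -> None:
    """Write a report: ``json`` = full nested document (config snapshot,
    per-triple records, summaries, 20-bin histograms per component);
    ``csv`` = flat one-row-per-triple table. JSON export re-verifies that
    stored summaries match recomputation from per-triple records."""
    path = Path(path)
    if format == "json":
        _check_self_consistency(report)
        doc = {
            "schema_version": SCHEMA_VERSION,
            "config": report.config_snapshot,
            "summaries": {c: _summary_dict(report.summaries[c]) for c in COMPONENTS},
            "histograms": _histograms(report),
            "decisions": report.decisions,
            "errors": report.errors,
            "per_triple": [_triple_record(ts) for ts in report.per_triple],
        }
        try:
            path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n",
                            encoding="utf-8")
        except OSError as exc:
            raise OSError(f"cannot write report to {path}: {exc}") from exc
    elif format == "csv":
        rows = []
        for ts in report.per_triple:
            rows.append({
                "triple_id": ts.triple_id,
                "semantic_raw_distance": ts.semantic.raw_distance,
                "semantic_score": ts.semantic.score,
                "type_score": ts.type.score,
                "type_method": ts.type.method,
                "head_match_kind": ts.type.head_match.match_kind,
                "tail_match_kind": ts.type.tail_match.match_kind,
                "resource_score": ts.resource.score,
                "head_rank_norm": ts.resource.head_rank_norm,
                "tail_rank_norm": ts.resource.tail_rank_norm,
                "connectivity": ts.resource.connectivity,
                "resource_valid": ts.resource.resource_valid,
                "flagged": ts.resource.flagged,
                "decision": report.decisions.get(ts.triple_id, ""),
            })
        try:
            pd.DataFrame(rows).to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"cannot write report to {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown report format {format!r}; use json or csv")


def load_report(path: str | Path) -> dict:
    """Reload an exported JSON report as a plain document (dict)."""
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)
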