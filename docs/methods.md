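# Methods

`kgvet` scores LLM-generated knowledge-graph triples along three views —
semantic plausibility, ontology-grounded type compatibility, and
structural importance — and combines them into per-triple accept/reject
decisions plus corpus-level summaries. This note records the models,
their assumptions, every tunable that changes a number, and the design
choices made where the design was genuinely open.

## Semantic plausibility

**Model.** A triple (h, r, t) is treated as a translation in embedding
space: it is plausible when h + r ≈ t. Each element — head, relation and
tail alike, with no special relation encoder — is embedded as one text
phrase. The raw quantity is the squared Euclidean translation energy
d_trans = ‖h + r − t‖²; squaring is the only penalty applied (no further
exponentiation), so large deviations are penalized quadratically.

**Normalization and inversion.** Raw distances are min–max normalized
across *all* triples scored together, then inverted: score = 1 −
(d − d_min)/(d_max − d_min). Distances live on [0, 1] after normalization,
but the reported score is oriented so that higher = more plausible; the
inversion is explicit and recorded in the report's config snapshot. The
corpus minimum-distance triple therefore scores exactly 1 and the maximum
exactly 0. Consequences worth knowing:

* scores are corpus-relative — adding or removing triples (including
  duplicates, which are kept by default) shifts everyone's score. A
  per-concept normalization mode (`per_concept_normalization`) restricts
  min–max to each concept's sub-KG;
* a degenerate corpus (all distances equal, including n = 1) normalizes
  to all-zero distances, i.e. score 1 for every triple — no spread gives
  no evidence of implausibility; a warning is logged. Rank normalization
  (below) resolves its degenerate case to 1.0 for the same reason;
* scores are invariant to positive rescaling of all distances, so the
  embedding's overall scale does not matter, only relative geometry.

**Embeddings.** Backends are pluggable behind one interface. The mock
backend maps text to a seeded pseudo-random unit vector (BLAKE2b-keyed
PCG64; dimension 32 by default) — deterministic across processes,
collision-resistant at fixture scale. The planted backend serves exact
vectors from a table (unknown text falls back to the mock) and is what
makes semantic tests exact. A sentence-transformer backend (mean-pooled,
biomedical encoder by default) sits behind an optional extra. A
`normalized` flag optionally L2-normalizes vectors before the translation
distance, since encoders differ on whether their outputs arrive
normalized; the default leaves vectors as produced.

## Type compatibility

Head and tail labels are matched to ontology nodes in three deterministic
tiers: exact preferred label, normalized label (lowercase, collapsed
whitespace, stripped edge punctuation), then synonyms. Ambiguity at any
tier resolves to the lexicographically smallest node id with a warning.

A matched entity's *type set* is its own semantic type (defaulting to its
label when the ontology supplies none, so type sets are never empty) plus
the types of all ancestors reached through `is_a` edges only; relational
edges never participate in the closure. Compatibility is the Jaccard
similarity of the two type sets. When either endpoint is unmatched —
Jaccard needs both sets, so one missing side suffices — the score falls
back to embedding cosine similarity of the two labels mapped affinely onto
[0, 1] via (1 + cos)/2; the affine map (rather than clamping negatives at
0) preserves ordering over the whole cosine range. Each result records
which method produced it, and summaries report the fallback fraction.

Known score-inflation source: every matched pair shares at least the root
type, so the ontology-path score is floored above 0 for any two matched
entities. Relation-aware type constraints (e.g. whether *treats* may link
a drug to a condition) are deliberately not enforced — the score depends
only on the two type sets — but an empty rule hook exists for future
domain checks. No normalization beyond Jaccard's intrinsic [0, 1] range is
applied.

## Structural importance

**ResourceRank.** R(v) = (1 − d) + d·Σ_{u ∈ In(v)} R(u)/|Out(u)|, damping
d = 0.85, computed over the union of hierarchy and relational edges in
their stored direction (parallel edges collapsed; a hierarchy-only scope
is available). The recurrence is implemented exactly as written: dangling
nodes contribute nothing to any sum, so total rank is *not* conserved —
this differs from classical PageRank, which scales the baseline by 1/N
and redistributes dangling mass; a `dangling="redistribute"` switch
restores redistribution for comparison. The fixed point is unique (the
iteration matrix has spectral radius ≤ d) and every rank is ≥ 1 − d.

Numerics: all-ones initialization; convergence when the max-norm change
drops below 1e−8; iteration cap 500 (the contraction factor is 0.85 per
step, so ~115 iterations can be needed from a unit-scale start; 100 would
not always converge at this tolerance). Non-convergence returns the last
iterate flagged `converged=False` with a warning rather than raising.
Tests pin the iterated solution against a dense linear solve of
(I − d·Mᵀ)R = (1 − d)·1.

**Per-triple score.** Node ranks are min–max normalized over the whole
ontology; a triple's score is the arithmetic mean of its endpoints'
normalized ranks (a `min` combiner is available — the entity-to-triple
aggregation is a genuine free choice and is recorded in the config
snapshot). Triples with an unmatched endpoint are flagged, score 0, and
are excluded from the summary mean by default (switchable).

**Connectivity.** Endpoint pairs are classified with precedence
direct (1-hop edge, either direction, any edge type) > parent/child
(transitive hierarchy ancestor/descendant) > sibling (shared direct
parent) > indirect (undirected path of ≤ `max_hops` = 3 edges in the
union graph) > none. "Plausible paths" ignores edge direction — clinical
relatedness reads both ways — and the small hop cap prevents everything
from counting as connected in a well-connected ontology. A triple is
resource valid iff both endpoints matched and connectivity ≠ none.

## Aggregation and decisions

The pipeline runs semantic scoring once over the corpus (the shared
min–max couples triples), type scoring per triple, and one rank
computation followed by per-triple resource checks. Reports carry
per-triple records, per-component summaries (mean, SD, min, max; sample
SD with n−1 by default, one global `sd_ddof` switch), 20-bin score
histograms, and the fully resolved configuration, so every number is
reproducible from the report file alone. On JSON export the stored
summaries are re-derived from the per-triple records and must agree to
1e−12, otherwise export fails.

Acceptance is conjunctive by default: a triple is accepted iff all three
scores clear their thresholds (0.75 each, following the convention that
scores above 0.75 indicate a plausible, coherent, well-grounded triple)
and it is not flagged. A weighted-average rule is available; conjunction
is the strictest reading and raising any threshold can only shrink the
accepted set (tested as a monotonicity property).

## Synthetic fixtures: what they emulate and what they do not

The generator builds a rooted DAG shaped like a compact clinical ontology:
four typed branches (condition, medication, procedure, lab_finding), each
branch root → two subcategories → `n_per_branch` leaves, plus a few
cross-branch relational edges (treats / diagnoses / monitors). Labels are
domain-flavored but synthetic (`drug_07`); every leaf gets one synonym.

Labeled corpora plant three populations: *plausible* triples follow
existing edges or pair hierarchy siblings; *implausible* triples join
cross-branch leaves farther than `max_hops` apart; *unmatched* triples
carry a tail label guaranteed absent from the ontology (these are exactly
the triples resource validation must flag — tested as an exact set
equality). The planted vector table realizes the translation regime: unit
vectors for heads and relations, tail = head + relation + N(0, noise_sd²)
for plausible triples, an independent unit vector otherwise. An entity
keeps its first-assigned vector; the sampler therefore prefers candidates
with fresh tails and with heads that were never planted as tails (a head
that is itself a translated tail would chain translations and let vector
norms — and hence the corpus max distance — grow without bound, washing
out the normalized separation). Conflicts that survive are logged.

Default study conditions, chosen once: 30 leaves per branch (133 nodes),
100 plausible + 100 implausible + 10 unmatched triples, noise_sd = 0.05,
dimension 32. Under these conditions the planted semantic separation
(mean plausible − mean implausible) is ≈ 0.5, comfortably above the 0.3
the test suite requires, and within-branch type scores exceed cross-branch
ones by ≈ 0.8.

What passing these tests does **not** show: the fixtures are a structural
analogy, not a statistical mimic. The toy graph's degree distribution is
root-dominated, so min–max-normalized ranks put almost all probability
mass near 0 — resource scores on fixtures are small and the 0.75 default
threshold rejects everything, whereas a production ontology with a dense
relational layer concentrates normalized ranks much higher. Likewise the
planted embedding geometry is idealized (exact translations plus Gaussian
noise); real encoder embeddings separate plausible from implausible
triples far less cleanly. Results on fixtures validate the *machinery* —
formulas, normalizations, flags, determinism — not expected score levels
on real corpora.

## Degenerate inputs and tie-breaks

* Empty triple files parse to empty sets with zero malformed count;
  malformed records (wrong arity, missing fields, bad JSON) are counted
  and reported, never silently dropped.
* Bracket spans `[[a, b, c]]` are assumed flat and non-nested; spans with
  ≠ 3 non-empty fields count as malformed.
* Hierarchy cycles and (when a node table is supplied) dangling edge
  endpoints abort ontology loading with a named witness.
* Duplicate triples are kept by default (they shift corpus-level
  normalization and should stay user-visible); `dedupe` collapses exact
  (h, r, t, tag) duplicates keeping the first.
* Triple ids are assigned sequentially in file order on read; the CSV/TSV/
  JSONL writers do not serialize custom ids, so round-trips preserve ids
  for file-loaded sets (custom ids are regenerated on reload).

## Known limitations

Temporal validity, contradiction detection, relation-aware type legality
and corpus diversity are out of scope. No cross-ontology (UMLS/SNOMED)
mapping is attempted; matching is label/synonym-based only. ResourceRank
is unweighted and non-personalized. The CLI's `--keep-going` tolerates
per-triple failures only in the type/resource stages; the semantic stage
is corpus-coupled, so an embedding failure there is fatal by design.
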