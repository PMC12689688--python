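# kgvet

Multi-view validation of LLM-generated knowledge-graph triples.

Large language models can draft medical knowledge-graph triples —
directed `(head, relation, tail)` assertions such as
*Hypertension — is treated with — ACE inhibitors* — far faster than manual
curation, but their output needs systematic quality control before it can
feed clinical decision support. `kgvet` scores every triple along three
complementary dimensions and partitions a corpus into accepted and
rejected triples:

1. **Semantic plausibility.** Each of *h*, *r*, *t* is embedded as text;
   a triple is plausible when *h* + *r* ≈ *t* (the TransE translation
   criterion). The raw score is the quadratically penalized translation
   energy *d*<sub>trans</sub> = ‖*h* + *r* − *t*‖², min–max normalized
   across the corpus and inverted so that 1 = most plausible.
2. **Type compatibility.** Head and tail are matched to an ontology; each
   gets a *type set* (its own semantic type plus the types of all `is_a`
   ancestors) and the score is Jaccard(T<sub>head</sub>, T<sub>tail</sub>)
   = |T<sub>head</sub> ∩ T<sub>tail</sub>| / |T<sub>head</sub> ∪
   T<sub>tail</sub>|. Entities the ontology does not cover fall back to an
   embedding cosine proxy mapped onto [0, 1].
3. **Structural importance.** ResourceRank, the damped rank-propagation
   centrality R(v) = (1 − d) + d·Σ<sub>u∈In(v)</sub> R(u)/|Out(u)| with
   d = 0.85, quantifies how well-connected each matched entity is;
   triples whose endpoints have no ontology match are *flagged*, and a
   triple is *resource valid* when its endpoints are linked by a direct
   edge, a hierarchy role (parent/child/sibling), or a short indirect path.

Everything runs offline: embedding backends are pluggable, with a
deterministic mock and a fixture-driven "planted" backend built in (a
transformer encoder is an optional extra), and a seeded generator produces
toy clinical ontologies and labeled triple corpora with known ground truth.

## Worked example

Generate a synthetic fixture (toy 45-node clinical ontology; 20 plausible,
20 implausible and 2 deliberately out-of-ontology triples) and validate it
with the planted embedding table:

```bash
kgvet fixtures make --out fx --seed 0 --n-plausible 20 --n-implausible 20 \
    --n-unmatched 2 --n-per-branch 8
kgvet validate fx/triples.csv fx/ontology.tsv \
    --nodes-path fx/ontology.nodes.tsv --vectors fx/vectors.jsonl \
    --out-prefix report
```

which prints:

```
loaded 42 triples (0 malformed)
component        mean       sd      min      max
semantic       0.7131   0.3017   0.0000   1.0000
type           0.5154   0.3960   0.1429   1.0000
resource       0.0240   0.1050   0.0000   0.6632
accepted 0 / rejected 42 (thresholds: {'semantic': 0.75, 'type': 0.75, 'resource': 0.75})
report written to report.json and report.csv
```

Reading the table: planted-plausible triples sit near semantic score 1 and
planted-implausible ones far below (the corpus mean 0.71 averages the two
groups); type scores split the same way (within-branch pairs share most of
their type sets, cross-branch pairs share only the root). Resource scores
are small on *this* fixture because min–max normalization of ranks puts the
toy ontology's root at 1 and its many leaves near 0 — so the default
conjunctive 0.75 threshold rejects every triple here; pass `--threshold` to
choose a cut appropriate for your graph. `report.json` carries per-triple
records, 20-bin score histograms, accept/reject decisions and the full
resolved configuration; `report.csv` is the same per-triple table flat.

The same pipeline is a library:

```python
from kgvet import make_fixture_bundle, validate_corpus

bundle = make_fixture_bundle(seed=0)   # 100 + 100 + 10 triples, 133 nodes
report = validate_corpus(bundle.triples, bundle.ontology, bundle.backend())
print(report.summaries["semantic"])
# ScoreSummary(mean=0.7033939..., sd=0.3035951..., min=0.0, max=1.0, n=210)
```

Real corpora load with `read_triples(path, dialect)` (csv / tsv / jsonl /
the raw LLM `[[entity1, relationship, entity2]]` dialect) and real
ontologies with `load_ontology(path, "edge_tsv" | "obo")`.

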