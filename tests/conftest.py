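import pytest

from kgvet.fixtures import make_fixture_bundle
from kgvet.ontology import OntologyGraph, OntologyNode
from kgvet.report import validate_corpus


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic fixture: 100 plausible + 100 implausible +
    10 unmatched triples over a 133-node toy clinical ontology."""
    return make_fixture_bundle(seed=0)


@pytest.fixture(scope="session")
def report(bundle):
    return validate_corpus(bundle.triples, bundle.ontology, bundle.backend())


def small_ontology() -> OntologyGraph:
    """Hand-built mini ontology: two typed branches under one root, two
    sibling drugs, one treats edge, one synonym, one isolated node.

        root(entity)
          condition_branch(condition)      drug_branch(chemical)
            hypertension(disorder)           drug_a(drug)   drug_b(drug)
        drug_a -treats-> hypertension ; isolated node floats free
    """
    nodes = {
        "root": OntologyNode("root", "clinical entity", "entity"),
        "cond": OntologyNode("cond", "condition branch", "condition"),
        "chem": OntologyNode("chem", "drug branch", "chemical"),
        "htn": OntologyNode("htn", "Hypertension", "disorder", synonyms=("HTN",)),
        "drug_a": OntologyNode("drug_a", "ACE inhibitors", "drug"),
        "drug_b": OntologyNode("drug_b", "beta blockers", "drug"),
        "iso": OntologyNode("iso", "isolated thing", None),
    }
    hier = [("cond", "root"), ("chem", "root"), ("htn", "cond"),
            ("drug_a", "chem"), ("drug_b", "chem")]
    rel = [("drug_a", "htn", "treats")]
    return OntologyGraph(nodes, hier, rel)


@pytest.fixture()
def mini_graph():
    return small_ontology()
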