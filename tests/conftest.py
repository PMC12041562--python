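import pytest

from phenoprio.benchmark import EvaluationCase, GenePhenotypeRecord
from phenoprio.ontology import OntologyGraph, OntologyTerm
from phenoprio.synthetic import (
    SyntheticConfig,
    generate_knowledge_base,
    generate_ontology,
    generate_patients,
)


@pytest.fixture
def diamond_graph():
    """A <- B, A <- C, B <- D, C <- D."""
    return OntologyGraph(
        [
            OntologyTerm("HP:A", "alpha", frozenset({"first"})),
            OntologyTerm("HP:B", "beta", parent_ids=frozenset({"HP:A"})),
            OntologyTerm("HP:C", "gamma", parent_ids=frozenset({"HP:A"})),
            OntologyTerm("HP:D", "delta", parent_ids=frozenset({"HP:B", "HP:C"})),
        ]
    )


@pytest.fixture
def chain_graph():
    """A <- B <- C."""
    return OntologyGraph(
        [
            OntologyTerm("HP:A", "top"),
            OntologyTerm("HP:B", "mid", parent_ids=frozenset({"HP:A"})),
            OntologyTerm("HP:C", "leaf", parent_ids=frozenset({"HP:B"})),
        ]
    )


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study: ontology, knowledge base, patients."""
    graph = generate_ontology(n_terms=80, max_parents=3, seed=11)
    kb = generate_knowledge_base(graph, n_genes=40, phenotypes_per_gene=5, seed=11)
    config = SyntheticConfig(
        n_terms=80, max_parents=3, n_genes=40, phenotypes_per_gene=5, seed=11
    )
    patients = generate_patients(kb, graph, n_patients=30, config=config)
    return graph, kb, patients


@pytest.fixture
def toy_case():
    return EvaluationCase(
        case_id="case-1",
        phenotypes=["short stature", "seizures"],
        genes=["GENEA", "GENEB"],
        causative_gene="GENEA",
        sex="female",
        moi="autosomal recessive",
    )


@pytest.fixture
def toy_records():
    from datetime import date

    return [
        GenePhenotypeRecord(
            record_id=f"R{i}",
            gene=f"GENE{i:04d}",
            phenotype_ids=[],
            phenotype_labels=["short stature", "seizures"],
            sex="male",
            moi="autosomal dominant",
            date_added=date(2023, 8, 1),
        )
        for i in range(1, 6)
    ]
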