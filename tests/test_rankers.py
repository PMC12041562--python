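"""Offline ranking backends: simulator noise model and the KB-similarity baseline."""

import math

import pytest

from phenoprio.benchmark import EvaluationCase, GenePhenotypeRecord
from phenoprio.ontology import OntologyGraph, OntologyTerm
from phenoprio.parsing import parse_response
from phenoprio.rankers import (
    KBSimilarityRanker,
    SimulatedRanker,
    SimulatorParams,
)


def _case(i, n=5):
    genes = [f"GENE{j:03d}" for j in range(n)]
    return EvaluationCase(
        case_id=f"c{i}",
        phenotypes=["short stature"],
        genes=genes,
        causative_gene=genes[i % n],
        sex="male",
        moi="genetic",
    )


class TestSimulatedRanker:
    def test_noiseless_output_is_perfect(self):
        ranker = SimulatedRanker(SimulatorParams(quality=1.0))
        resp = ranker.rank(_case(0))
        lines = resp.raw_text.splitlines()
        assert lines[0] == "Ranked List:"
        assert len(lines) == 6
        assert lines[1] == "1. GENE000"

    def test_total_dropout_leaves_header_only(self):
        ranker = SimulatedRanker(SimulatorParams(p_drop=1.0))
        resp = ranker.rank(_case(0))
        assert resp.raw_text.strip() == "Ranked List:"

    def test_deterministic_given_seed(self):
        a = SimulatedRanker(SimulatorParams(quality=0.5, p_drop=0.3, seed=9))
        b = SimulatedRanker(SimulatorParams(quality=0.5, p_drop=0.3, seed=9))
        case = _case(1)
        assert a.rank(case).raw_text == b.rank(case).raw_text

    def test_parse_round_trip_recovers_internal_order(self):
        ranker = SimulatedRanker(SimulatorParams(quality=1.0, seed=3))
        for i in range(20):
            case = _case(i, n=10)
            parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
            assert parsed.ranked_genes[0] == case.causative_gene
            assert parsed.missing == set()
            assert parsed.extra == set()
            assert len(parsed.ranked_genes) == 10

    def test_drop_rate_recovery(self):
        """Fraction of prompts missing >=1 of 5 input genes ~ 1 - 0.7^5."""
        ranker = SimulatedRanker(SimulatorParams(p_drop=0.3, seed=0))
        n_prompts = 1000
        n_missing = 0
        for i in range(n_prompts):
            case = _case(i)
            parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
            if parsed.missing:
                n_missing += 1
        expected = 1 - 0.7**5
        se = math.sqrt(expected * (1 - expected) / n_prompts)
        assert abs(n_missing / n_prompts - expected) < 3 * se

    def test_extra_rate_recovery(self):
        ranker = SimulatedRanker(SimulatorParams(p_extra=0.2, seed=1))
        n_prompts = 1000
        n_extra = sum(
            1
            for i in range(n_prompts)
            if parse_response(
                ranker.rank(_case(i)).raw_text, set(_case(i).genes)
            ).extra
        )
        se = math.sqrt(0.2 * 0.8 / n_prompts)
        assert abs(n_extra / n_prompts - 0.2) < 3 * se

    def test_duplicate_injection_detected_by_parser(self):
        ranker = SimulatedRanker(SimulatorParams(p_dup=1.0, seed=2))
        parsed = parse_response(ranker.rank(_case(0)).raw_text, set(_case(0).genes))
        assert parsed.duplicates_collapsed == 1

    def test_force_last_pins_causative_to_final_rank(self):
        ranker = SimulatedRanker(SimulatorParams(force_last=True, seed=4))
        for i in range(5):
            case = _case(i, n=8)
            parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
            assert parsed.ranked_genes[-1] == case.causative_gene

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            SimulatorParams(quality=1.2)


@pytest.fixture
def six_term_graph():
    """R <- A <- B, R <- C <- {D, E}: closures computable by hand."""
    return OntologyGraph(
        [
            OntologyTerm("T:R", "root"),
            OntologyTerm("T:A", "a", parent_ids=frozenset({"T:R"})),
            OntologyTerm("T:B", "b", parent_ids=frozenset({"T:A"})),
            OntologyTerm("T:C", "c", parent_ids=frozenset({"T:R"})),
            OntologyTerm("T:D", "d", parent_ids=frozenset({"T:C"})),
            OntologyTerm("T:E", "e", parent_ids=frozenset({"T:C"})),
        ]
    )


def _kb_record(gene, terms, graph):
    return GenePhenotypeRecord(
        record_id=f"KB:{gene}",
        gene=gene,
        phenotype_ids=list(terms),
        phenotype_labels=[graph.label_of(t) for t in terms],
    )


class TestKBSimilarityRanker:
    def test_exact_profile_match_ranks_first(self, six_term_graph):
        kb = [
            _kb_record("G1", ["T:B"], six_term_graph),
            _kb_record("G2", ["T:D"], six_term_graph),
        ]
        ranker = KBSimilarityRanker(kb, six_term_graph)
        case = EvaluationCase(
            case_id="c",
            phenotypes=["b"],
            phenotype_ids=["T:B"],
            genes=["G2", "G1"],
            causative_gene="G1",
        )
        parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
        assert parsed.ranked_genes[0] == "G1"

    def test_hand_computed_jaccard_scores(self, six_term_graph):
        """Case closure {B,A,R,E,C}; G1 closure {B,A,R} -> 3/5; G2 closure
        {D,C,R} -> 2/6."""
        kb = [
            _kb_record("G1", ["T:B"], six_term_graph),
            _kb_record("G2", ["T:D"], six_term_graph),
        ]
        ranker = KBSimilarityRanker(kb, six_term_graph)
        case = EvaluationCase(
            case_id="c",
            phenotypes=["b", "e"],
            phenotype_ids=["T:B", "T:E"],
            genes=["G1", "G2"],
            causative_gene="G1",
        )
        assert ranker.score(case, "G1") == pytest.approx(3 / 5)
        assert ranker.score(case, "G2") == pytest.approx(2 / 6)
        parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
        assert parsed.ranked_genes == ["G1", "G2"]

    def test_all_zero_overlap_falls_back_to_lexicographic(self, six_term_graph):
        kb = [
            _kb_record("GZ", ["T:B"], six_term_graph),
            _kb_record("GA", ["T:B"], six_term_graph),
        ]
        ranker = KBSimilarityRanker(kb, six_term_graph)
        case = EvaluationCase(
            case_id="c",
            phenotypes=["nothing mapped"],
            phenotype_ids=[],
            genes=["GZ", "GA"],
            causative_gene="GA",
        )
        parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
        assert parsed.ranked_genes == ["GA", "GZ"]

    def test_permutation_invariance(self, six_term_graph):
        kb = [
            _kb_record("G1", ["T:B"], six_term_graph),
            _kb_record("G2", ["T:D"], six_term_graph),
            _kb_record("G3", ["T:E"], six_term_graph),
        ]
        ranker = KBSimilarityRanker(kb, six_term_graph)
        base = EvaluationCase(
            case_id="c",
            phenotypes=["b"],
            phenotype_ids=["T:B"],
            genes=["G1", "G2", "G3"],
            causative_gene="G1",
        )
        shuffled = EvaluationCase(
            case_id="c",
            phenotypes=["b"],
            phenotype_ids=["T:B"],
            genes=["G3", "G1", "G2"],
            causative_gene="G1",
        )
        a = parse_response(ranker.rank(base).raw_text, set(base.genes))
        b = parse_response(ranker.rank(shuffled).raw_text, set(shuffled.genes))
        assert a.ranked_genes == b.ranked_genes

    def test_free_text_labels_resolved_through_dictionary(self, six_term_graph):
        kb = [
            _kb_record("G1", ["T:B"], six_term_graph),
            _kb_record("G2", ["T:D"], six_term_graph),
        ]
        ranker = KBSimilarityRanker(kb, six_term_graph)
        case = EvaluationCase(
            case_id="c",
            phenotypes=["B"],  # label-only profile, resolved via lookup
            phenotype_ids=[],
            genes=["G1", "G2"],
            causative_gene="G1",
        )
        parsed = parse_response(ranker.rank(case).raw_text, set(case.genes))
        assert parsed.ranked_genes[0] == "G1"
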