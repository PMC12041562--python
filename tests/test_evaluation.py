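"""Single-positive rank metrics against brute-force oracles, and cohort arithmetic."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from phenoprio.benchmark import EvaluationCase
from phenoprio.evaluation import (
    CaseOutcome,
    aggregate,
    average_precision_single_positive,
    hallucination_rates,
    hits_at_k,
    overlap_stats,
    rank_of_causative,
    repetition_summary,
    roc_auc_single_positive,
    topk_success_rate,
)
from phenoprio.parsing import ParsedRanking, parse_response


def _outcome(rank, n, absent=False, case_id="c"):
    return CaseOutcome(case_id=case_id, n=n, rank=rank, absent=absent)


def _case(n, causative="GENE000"):
    genes = [f"GENE{i:03d}" for i in range(n)]
    return EvaluationCase(
        case_id="c", phenotypes=["p"], genes=genes, causative_gene=causative
    )


class TestRankOfCausative:
    def test_causative_first(self):
        parsed = ParsedRanking(ranked_genes=[f"GENE{i:03d}" for i in range(10)])
        outcome = rank_of_causative(parsed, _case(10))
        assert outcome.rank == 1 and not outcome.absent

    def test_absent_causative_scores_last_rank(self):
        parsed = ParsedRanking(ranked_genes=["GENE001", "GENE002"])
        outcome = rank_of_causative(parsed, _case(25))
        assert outcome.rank == 25 and outcome.absent
        for k in (1, 5, 10, 24):
            assert hits_at_k([outcome], k) == 0.0

    def test_extras_do_not_shift_the_rank(self):
        # hallucinated FAKEGENE above the causative is not a candidate
        raw = "1. GENE001\n2. FAKEGENE\n3. GENE002\n4. GENE000\n5. GENE003"
        case = _case(5)
        parsed = parse_response(raw, set(case.genes))
        outcome = rank_of_causative(parsed, case)
        assert outcome.rank == 3

    def test_failed_parse_scores_last_rank(self):
        parsed = ParsedRanking(failed=True)
        outcome = rank_of_causative(parsed, _case(5))
        assert outcome.rank == 5 and outcome.absent


class TestHitsAtK:
    def test_single_perfect_outcome(self):
        assert hits_at_k([_outcome(1, 10)], 1) == 100.0

    def test_enumerated_fraction(self):
        outcomes = [_outcome(r, 20) for r in (1, 3, 12)]
        assert hits_at_k(outcomes, 10) == pytest.approx(200 / 3)

    def test_k_capped_at_list_size(self):
        assert hits_at_k([_outcome(3, 3)], 10) == 100.0

    def test_absent_never_hits_even_at_full_depth(self):
        assert hits_at_k([_outcome(5, 5, absent=True)], 5) == 0.0


class TestClosedForms:
    def test_perfect_and_worst_auc(self):
        assert roc_auc_single_positive(1, 10) == 1.0
        assert roc_auc_single_positive(10, 10) == 0.0

    def test_midrank_auc(self):
        # 4 positive-negative pairs, 2 ordered correctly
        assert roc_auc_single_positive(3, 5) == 0.5

    def test_single_candidate_auc_defined_as_one(self):
        assert roc_auc_single_positive(1, 1) == 1.0

    def test_average_precision_values(self):
        assert average_precision_single_positive(1) == 1.0
        assert average_precision_single_positive(4) == 0.25
        assert average_precision_single_positive(0, n=20, absent=True) == 0.05

    def test_oracle_equivalence_brute_force(self):
        """Closed forms match sklearn on explicit score lists for 500
        random (rank, n) pairs, to 1e-12."""
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(2, 120))
            r = int(rng.integers(1, n + 1))
            scores = [float(n - i) for i in range(1, n + 1)]  # rank i -> n - i
            labels = [1 if i == r else 0 for i in range(1, n + 1)]
            assert roc_auc_single_positive(r, n) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )
            assert average_precision_single_positive(r) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )


class TestAggregate:
    def test_ceiling_row(self):
        outcomes = [_outcome(1, 5, case_id=f"c{i}") for i in range(4)]
        (row,) = aggregate(outcomes)
        assert (row.hits_at_1, row.hits_at_5, row.hits_at_10) == (100.0, 100.0, 100.0)
        assert row.roc_auc == 1.0 and row.aupr == 1.0

    def test_macro_average_of_two_cases(self):
        outcomes = [_outcome(1, 5), _outcome(5, 5)]
        (row,) = aggregate(outcomes)
        assert row.roc_auc == pytest.approx(0.5)
        assert row.aupr == pytest.approx(0.6)

    def test_empty_input_gives_no_rows(self):
        assert aggregate([]) == []

    def test_hits_monotone_in_k(self):
        rng = np.random.default_rng(3)
        outcomes = [
            _outcome(int(rng.integers(1, 51)), 50, case_id=f"c{i}")
            for i in range(200)
        ]
        (row,) = aggregate(outcomes)
        assert row.hits_at_1 <= row.hits_at_5 <= row.hits_at_10


class TestHallucinationRates:
    def test_one_in_four_missing(self):
        parses = [ParsedRanking(missing={"A"})] + [ParsedRanking() for _ in range(3)]
        stats = hallucination_rates(parses)
        assert stats.pct_prompts_missing == 25.0
        assert stats.pct_prompts_extra == 0.0

    def test_all_clean(self):
        stats = hallucination_rates([ParsedRanking() for _ in range(5)])
        assert (stats.pct_prompts_missing, stats.pct_prompts_extra) == (0.0, 0.0)


class TestRepetitionSummary:
    def test_constant_values(self):
        assert repetition_summary([0.9, 0.9, 0.9]) == (0.9, 0.0)

    def test_two_values(self):
        mean, sd = repetition_summary([0.8, 1.0])
        assert mean == pytest.approx(0.9)
        assert sd == pytest.approx(0.141421356, abs=1e-6)

    def test_single_repetition_has_no_sd(self):
        assert repetition_summary([0.75]) == (0.75, None)


class TestCohortComparison:
    def test_printed_overlap_arithmetic(self):
        """23 and 18 plausible genes with 10 shared -> 10/31 of the union."""
        a = {
            "F1": {"A1", "A2"}, "F2": {"B1", "B2"}, "F3": {"C1", "C2"},
            "F4": {"D1"}, "F5": {"E1"}, "F6": {"G1"}, "F7": {"H1"},
            "F8": {"X1", "X2", "X3", "X4", "X5", "X6", "X7"},
            "F9": {"X8", "X9", "X10", "X11", "X12", "X13"},
        }
        b = {
            "F1": {"A1", "A2"}, "F2": {"B1", "B2"}, "F3": {"C1", "C2"},
            "F4": {"D1"}, "F5": {"E1"}, "F6": {"G1"}, "F7": {"H1"},
            "F10": {"Y1", "Y2", "Y3", "Y4"}, "F11": {"Y5", "Y6", "Y7", "Y8"},
        }
        stats = overlap_stats(a, b)
        assert stats["n_a"] == 23
        assert stats["n_b"] == 18
        assert stats["n_overlap"] == 10
        assert stats["n_union"] == 31
        assert round(stats["pct_overlap_of_union"], 2) == 32.26

    def test_disjoint_and_identical_sets(self):
        assert overlap_stats({"F": {"A"}}, {"F": {"B"}})["pct_overlap_of_union"] == 0.0
        assert (
            overlap_stats({"F": {"A", "B"}}, {"F": {"A", "B"}})["pct_overlap_of_union"]
            == 100.0
        )

    def test_success_rates(self):
        solved = {f"F{i}": f"G{i}" for i in range(5)}
        all_hit = {f"F{i}": [f"G{i}", "X", "Y"] for i in range(5)}
        assert topk_success_rate(solved, all_hit, k=5) == 100.0
        two_hit = {
            "F0": ["G0"], "F1": ["G1"],
            "F2": ["X"], "F3": ["X"], "F4": ["X", "Y", "Z", "W", "V"],
        }
        assert topk_success_rate(solved, two_hit, k=5) == 40.0

    def test_zero_solved_families_rejected(self):
        with pytest.raises(ValueError):
            topk_success_rate({}, {})
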