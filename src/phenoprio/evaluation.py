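"""Rank-based metrics for single-relevant-item retrieval.

Each evaluation case has exactly one relevant gene among n candidates,
so every ranking metric reduces to a closed form in the causative
gene's 1-based rank r:

* Hits@k — the percentage of cases with the causative gene ranked in
  the top k (a case whose causative gene is absent from the output
  never counts as a hit);
* ROC AUC — the probability that the positive outranks a random
  negative, (n - r) / (n - 1);
* AUPR — average precision, the area under the precision-recall step
  function, which with a single positive is 1 / r.

A causative gene that the ranker omitted (or a failed parse) is scored
pessimistically at the last rank, r = n — the same convention the
one-shot prompt instructs: rank all genes with no evidence last.
Non-input (hallucinated extra) symbols are excluded before computing r:
they are not candidates.

The module also provides the hallucination-rate accounting (fraction of
prompts whose ranked list misses input genes or contains extra ones),
mean/SD summaries over repeated runs, and the cohort-comparison
arithmetic (plausible-gene overlap between two tools, and top-k success
rate on solved cases).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .benchmark import EvaluationCase
from .parsing import ParsedRanking

logger = logging.getLogger(__name__)

__all__ = [
    "CaseOutcome",
    "MetricsRow",
    "HallucinationStats",
    "rank_of_causative",
    "hits_at_k",
    "roc_auc_single_positive",
    "average_precision_single_positive",
    "aggregate",
    "metrics_frame",
    "hallucination_rates",
    "repetition_summary",
    "overlap_stats",
    "topk_success_rate",
]


@dataclass(frozen=True)
class CaseOutcome:
    """The rank of the causative gene in one case."""

    case_id: str
    n: int
    rank: int
    absent: bool = False
    template_id: str = ""
    dataset: str = ""
    repetition: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n:
            raise ValueError(
                f"case {self.case_id}: rank {self.rank} outside 1..{self.n}"
            )


@dataclass(frozen=True)
class MetricsRow:
    """One aggregated cell: dataset x template x gene-list size."""

    dataset: str
    template_id: str
    size: int
    hits_at_1: float
    hits_at_5: float
    hits_at_10: float
    roc_auc: float
    aupr: float
    n_cases: int


@dataclass(frozen=True)
class HallucinationStats:
    pct_prompts_missing: float
    pct_prompts_extra: float
    n_prompts: int


def rank_of_causative(
    parsed: ParsedRanking,
    case: EvaluationCase,
    template_id: str = "",
    dataset: str = "",
    repetition: int = 0,
) -> CaseOutcome:
    """Locate the causative gene in a parsed ranking.

    The rank counts input genes only (parsed rankings never contain
    extras).  Absent causative gene or failed parse scores the
    pessimistic last rank n with ``absent=True``.
    """
    causative = case.causative_gene.upper()
    try:
        rank = parsed.ranked_genes.index(causative) + 1
        absent = False
    except ValueError:
        rank = case.n
        absent = True
    return CaseOutcome(
        case_id=case.case_id,
        n=case.n,
        rank=rank,
        absent=absent,
        template_id=template_id,
        dataset=dataset,
        repetition=repetition,
    )


def hits_at_k(outcomes: Sequence[CaseOutcome], k: int) -> float:
    """Percentage of cases with the causative gene present in the top k.

    k larger than a case's list size caps at that size, so the metric
    never exceeds 100%.
    """
    if not outcomes:
        raise ValueError("no outcomes to aggregate")
    hits = sum(
        1 for o in outcomes if not o.absent and o.rank <= min(k, o.n)
    )
    return 100.0 * hits / len(outcomes)


def roc_auc_single_positive(r: int, n: int, absent: bool = False) -> float:
    """Closed-form ROC AUC with one positive among n candidates.

    Scoring candidates by descending rank position, the AUC equals the
    fraction of negatives ranked below the positive: (n - r) / (n - 1).
    An absent positive is scored at the last rank.  A single-candidate
    list carries no ranking information; 1.0 is returned with a note.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        logger.info("ROC AUC undefined for n=1; returning 1.0")
        return 1.0
    if absent:
        r = n
    if not 1 <= r <= n:
        raise ValueError(f"rank {r} outside 1..{n}")
    return (n - r) / (n - 1)


def average_precision_single_positive(
    r: int, n: Optional[int] = None, absent: bool = False
) -> float:
    """Average precision with a single positive: 1 / r.

    The precision-recall curve has one recall step, at the positive's
    rank, where precision is 1/r.  An absent positive scores 1/n.
    """
    if absent:
        if n is None:
            raise ValueError("n is required to score an absent positive")
        r = n
    if r < 1:
        raise ValueError("rank must be >= 1")
    return 1.0 / r


def aggregate(
    outcomes: Iterable[CaseOutcome],
    key: Callable[[CaseOutcome], tuple] = lambda o: (o.dataset, o.template_id, o.n),
) -> list[MetricsRow]:
    """Macro-aggregate outcomes into one row per (dataset, template, size).

    AUC and AP are averaged per case (macro), so every case weighs
    equally regardless of its list size.
    """
    groups: dict[tuple, list[CaseOutcome]] = {}
    for o in outcomes:
        groups.setdefault(key(o), []).append(o)

    rows = []
    for (dataset, template_id, n), members in sorted(groups.items()):
        if not members:
            logger.warning("empty group %s; no row emitted", (dataset, template_id, n))
            continue
        rows.append(
            MetricsRow(
                dataset=dataset,
                template_id=template_id,
                size=n,
                hits_at_1=hits_at_k(members, 1),
                hits_at_5=hits_at_k(members, 5),
                hits_at_10=hits_at_k(members, 10),
                roc_auc=_mean(
                    roc_auc_single_positive(o.rank, o.n, o.absent) for o in members
                ),
                aupr=_mean(
                    average_precision_single_positive(o.rank, o.n, o.absent)
                    for o in members
                ),
                n_cases=len(members),
            )
        )
    return rows


def _mean(values: Iterable[float]) -> float:
    values = list(values)
    return sum(values) / len(values)


def metrics_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Rows as a DataFrame, the layout used for TSV/JSON reports."""
    return pd.DataFrame(
        [
            {
                "dataset": r.dataset,
                "template_id": r.template_id,
                "size": r.size,
                "hits@1": r.hits_at_1,
                "hits@5": r.hits_at_5,
                "hits@10": r.hits_at_10,
                "roc_auc": r.roc_auc,
                "aupr": r.aupr,
                "n_cases": r.n_cases,
            }
            for r in rows
        ]
    )


def hallucination_rates(parses: Sequence[ParsedRanking]) -> HallucinationStats:
    """Fraction of prompts with missing input genes / extra symbols.

    Computed over all prompts regardless of gene-list size; failed
    parses count as missing every input gene.
    """
    if not parses:
        raise ValueError("no parses to aggregate")
    n = len(parses)
    n_missing = sum(1 for p in parses if p.missing)
    n_extra = sum(1 for p in parses if p.extra)
    return HallucinationStats(
        pct_prompts_missing=100.0 * n_missing / n,
        pct_prompts_extra=100.0 * n_extra / n,
        n_prompts=n,
    )


def repetition_summary(values: Sequence[float]) -> tuple[float, Optional[float]]:
    """Sample mean and sample SD (n-1 denominator) across repetitions.

    A single repetition has no dispersion estimate: SD is ``None``.
    """
    if not values:
        raise ValueError("no values to summarize")
    mean = sum(values) / len(values)
    if len(values) == 1:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, math.sqrt(var)


def overlap_stats(
    plausible_a: Mapping[str, set], plausible_b: Mapping[str, set]
) -> dict:
    """Agreement between two tools' per-family plausible-gene sets.

    Counts are summed over families; the overlap percentage is taken of
    the union (n_a + n_b - n_overlap).  A per-family breakdown and the
    alternative sum denominator (n_a + n_b, which double-counts shared
    genes) are also reported.
    """
    families = sorted(set(plausible_a) | set(plausible_b))
    per_family = {}
    n_a = n_b = n_overlap = 0
    for fam in families:
        a = set(plausible_a.get(fam, set()))
        b = set(plausible_b.get(fam, set()))
        per_family[fam] = {
            "n_a": len(a),
            "n_b": len(b),
            "n_overlap": len(a & b),
        }
        n_a += len(a)
        n_b += len(b)
        n_overlap += len(a & b)
    n_union = n_a + n_b - n_overlap
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_overlap": n_overlap,
        "n_union": n_union,
        "pct_overlap_of_union": 100.0 * n_overlap / n_union if n_union else 0.0,
        "pct_overlap_of_sum": 100.0 * n_overlap / (n_a + n_b) if n_a + n_b else 0.0,
        "per_family": per_family,
    }


def topk_success_rate(
    solved_cases: Mapping[str, str],
    topk_lists: Mapping[str, Sequence[str]],
    k: int = 5,
) -> float:
    """Percentage of solved families whose causative gene is in the top k."""
    if not solved_cases:
        raise ValueError("success rate undefined with zero solved families")
    hits = sum(
        1
        for fam, gene in solved_cases.items()
        if gene in list(topk_lists.get(fam, []))[:k]
    )
    return 100.0 * hits / len(solved_cases)
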