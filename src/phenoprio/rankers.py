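"""Ranking backends behind a single contract.

A ranker is any callable ``rank(case, rendered_prompt) -> RankerResponse``
returning free text.  Two offline backends make the pipeline fully
testable without a model API:

* :class:`SimulatedRanker` — a stochastic generator with a controllable
  quality knob (probability the causative gene lands on rank 1) and
  controllable hallucination behaviors: per-gene omission, injection of
  an out-of-list symbol, and duplication of a listed gene.  It emits the
  'Ranked List:' numbered format so the parser sees realistic input.
* :class:`KBSimilarityRanker` — a deterministic phenotype-match baseline
  scoring each candidate gene by the Jaccard similarity between the
  is_a ancestor closure of the case phenotypes and that of the gene's
  knowledge-base phenotypes.  It plays the role of a classical
  ontology-based prioritizer for sweep experiments; it is not a
  re-implementation of any published tool.

Live chat-completion adapters belong behind the same contract but are an
external, untested interface; nothing in this package performs network
calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from ._seeds import rng_for
from .benchmark import EvaluationCase, GenePhenotypeRecord
from .ontology import OntologyGraph
from .prompting import RenderedPrompt

__all__ = [
    "RankerResponse",
    "SimulatorParams",
    "SimulatedRanker",
    "KBSimilarityRanker",
    "simulated_rank",
    "kb_similarity_rank",
    "format_ranked_list",
]

REFUSAL_TOKEN = "[refusal]"


@dataclass(frozen=True)
class RankerResponse:
    case_id: str
    template_id: str
    raw_text: str
    backend_id: str

    def __post_init__(self) -> None:
        if not self.raw_text:
            object.__setattr__(self, "raw_text", REFUSAL_TOKEN)


@dataclass(frozen=True)
class SimulatorParams:
    """Knobs of the stochastic ranker simulator.

    ``quality`` is the probability of placing the causative gene at rank
    1; otherwise it is inserted uniformly among the later ranks.
    ``p_drop`` is the per-gene probability of omission from the output;
    ``p_extra`` the per-prompt probability of inserting one symbol that
    was never in the candidate list; ``p_dup`` the per-prompt probability
    of repeating one listed gene.  ``force_last`` pins the causative gene
    to the final rank, the adversarial floor case.
    """

    quality: float = 1.0
    p_drop: float = 0.0
    p_extra: float = 0.0
    p_dup: float = 0.0
    seed: int = 0
    force_last: bool = False

    def __post_init__(self) -> None:
        for name in ("quality", "p_drop", "p_extra", "p_dup"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


def format_ranked_list(genes: Sequence[str]) -> str:
    lines = [f"{i}. {g}" for i, g in enumerate(genes, start=1)]
    return "Ranked List:\n" + "\n".join(lines)


class SimulatedRanker:
    """Stochastic offline backend; stateless and seed-deterministic.

    The per-call RNG derives from (params.seed, case_id, template_id), so
    repeated calls for the same prompt reproduce the same text while
    different cases or repetition seeds decorrelate.
    """

    backend_id = "simulated"

    def __init__(self, params: SimulatorParams):
        self.params = params

    def rank(
        self, case: EvaluationCase, rendered_prompt: Optional[RenderedPrompt] = None
    ) -> RankerResponse:
        p = self.params
        template_id = rendered_prompt.template_id if rendered_prompt else ""
        rng = rng_for("simulated", p.seed, case.case_id, template_id)

        decoys = [g for g in case.genes if g != case.causative_gene]
        rng.shuffle(decoys)
        if p.force_last:
            order = decoys + [case.causative_gene]
        elif rng.random() < p.quality:
            order = [case.causative_gene] + decoys
        else:
            pos = int(rng.integers(1, len(decoys) + 1)) if decoys else 0
            order = decoys[:pos] + [case.causative_gene] + decoys[pos:]

        kept = [g for g in order if rng.random() >= p.p_drop]

        if rng.random() < p.p_extra:
            fake = f"ZZFAKE{int(rng.integers(10_000)):04d}"
            while fake in case.genes:
                fake = f"ZZFAKE{int(rng.integers(10_000)):04d}"
            kept.insert(int(rng.integers(len(kept) + 1)), fake)

        if kept and rng.random() < p.p_dup:
            src = int(rng.integers(len(kept)))
            kept.insert(int(rng.integers(src + 1, len(kept) + 1)), kept[src])

        return RankerResponse(
            case_id=case.case_id,
            template_id=template_id,
            raw_text=format_ranked_list(kept),
            backend_id=self.backend_id,
        )

    __call__ = rank


class KBSimilarityRanker:
    """Deterministic Jaccard-over-ancestor-closure phenotype matcher.

    Each gene's knowledge-base phenotype set is expanded to its full
    is_a ancestor closure once at construction; a case is scored against
    each gene by Jaccard similarity of closures.  Output is sorted by
    descending score with ties broken lexicographically by gene symbol,
    which makes the ranking invariant to the order of G.
    """

    backend_id = "kb_similarity"

    def __init__(self, kb: Sequence[GenePhenotypeRecord], graph: OntologyGraph):
        self.graph = graph
        self._gene_closures: dict[str, frozenset[str]] = {
            rec.gene: self._closure(rec.phenotype_ids) for rec in kb
        }

    def _closure(self, term_ids: Sequence[str]) -> frozenset[str]:
        closed: set[str] = set()
        for tid in term_ids:
            if tid in self.graph:
                closed |= self.graph.ancestors(tid, include_self=True)
        return frozenset(closed)

    def _case_closure(self, case: EvaluationCase) -> frozenset[str]:
        terms = list(case.phenotype_ids)
        if not terms:
            # free-text profile: resolve labels through the dictionary
            terms = [
                t
                for t in (self.graph.map_text_to_term(lbl) for lbl in case.phenotypes)
                if t is not None
            ]
        return self._closure(terms)

    def score(self, case: EvaluationCase, gene: str) -> float:
        a = self._case_closure(case)
        b = self._gene_closures.get(gene, frozenset())
        union = a | b
        if not union:
            return 0.0
        return len(a & b) / len(union)

    def rank(
        self, case: EvaluationCase, rendered_prompt: Optional[RenderedPrompt] = None
    ) -> RankerResponse:
        a = self._case_closure(case)
        scored = []
        for gene in case.genes:
            b = self._gene_closures.get(gene, frozenset())
            union = a | b
            score = len(a & b) / len(union) if union else 0.0
            scored.append((-score, gene))
        ordered = [gene for _, gene in sorted(scored)]
        return RankerResponse(
            case_id=case.case_id,
            template_id=rendered_prompt.template_id if rendered_prompt else "",
            raw_text=format_ranked_list(ordered),
            backend_id=self.backend_id,
        )

    __call__ = rank


def simulated_rank(case: EvaluationCase, params: SimulatorParams) -> RankerResponse:
    """Functional form of :class:`SimulatedRanker`."""
    return SimulatedRanker(params).rank(case)


def kb_similarity_rank(
    case: EvaluationCase, kb: Sequence[GenePhenotypeRecord], graph: OntologyGraph
) -> RankerResponse:
    """Functional form of :class:`KBSimilarityRanker` (builds closures per call)."""
    return KBSimilarityRanker(kb, graph).rank(case)
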