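"""Evaluation-case construction.

A benchmark dataset is a table of genotype-phenotype records: one gene
per record together with the phenotype profile observed in a patient
carrying a (likely) pathogenic variant in that gene.  From each record we
build evaluation cases (G, P): a candidate gene list G of fixed
cardinality n containing the single causative gene plus n-1 decoy genes
sampled from a decoy pool, paired with the record's phenotype set P.
Cardinalities default to 5, 25, 50, 75 and 100, spanning the candidate
counts that remain after standard variant filtering of an exome or
genome.

Decoy pools come in two flavours: an explicit gene universe ("all human
genes" style) or the set of genes present in the knowledge base itself.
The causative gene's position within G is uniformly randomized so that a
ranker can never exploit list position.

Records can also be restricted to a calendar window on their
``date_added`` field — the device used to keep evaluation variants past
a model's training cut-off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

from ._seeds import rng_for, stable_seed

logger = logging.getLogger(__name__)

__all__ = [
    "GenePhenotypeRecord",
    "EvaluationCase",
    "DateWindow",
    "filter_by_date",
    "build_cases",
    "kb_gene_pool",
    "write_cases_jsonl",
    "read_cases_jsonl",
]


@dataclass
class GenePhenotypeRecord:
    """One gene <-> phenotype-profile association with optional metadata."""

    record_id: str
    gene: str
    phenotype_ids: list[str] = field(default_factory=list)
    phenotype_labels: list[str] = field(default_factory=list)
    sex: Optional[str] = None
    moi: Optional[str] = None
    date_added: Optional[date] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError(f"record {self.record_id}: gene must be non-empty")

    @property
    def n_phenotypes(self) -> int:
        return max(len(self.phenotype_ids), len(self.phenotype_labels))


@dataclass
class EvaluationCase:
    """A (G, P) pair: candidate genes, phenotypes, one causative gene."""

    case_id: str
    phenotypes: list[str]            # natural-language labels, prompt-ready
    genes: list[str]                 # ordered candidate list G
    causative_gene: str
    phenotype_ids: list[str] = field(default_factory=list)
    sex: Optional[str] = None
    moi: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.causative_gene not in self.genes:
            raise ValueError(
                f"case {self.case_id}: causative gene not in candidate list"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"case {self.case_id}: duplicate candidate genes")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def m(self) -> int:
        return len(self.phenotypes)


@dataclass(frozen=True)
class DateWindow:
    """A closed calendar interval [start, end]."""

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} after end {self.end}")

    def __contains__(self, day: date) -> bool:
        return self.start <= day <= self.end


def filter_by_date(
    records: Iterable[GenePhenotypeRecord], window: DateWindow
) -> list[GenePhenotypeRecord]:
    """Keep records whose ``date_added`` falls inside the closed window.

    Records without a date are dropped with a logged warning — they
    cannot be shown to postdate a training cut-off.  Input order is
    preserved.
    """
    kept = []
    for rec in records:
        if rec.date_added is None:
            logger.warning("record %s has no date_added; dropped", rec.record_id)
            continue
        if rec.date_added in window:
            kept.append(rec)
    return kept


def kb_gene_pool(records: Iterable[GenePhenotypeRecord]) -> list[str]:
    """The decoy universe consisting of all genes present in the records."""
    return sorted({rec.gene for rec in records})


def build_cases(
    records: Sequence[GenePhenotypeRecord],
    sizes: Iterable[int],
    pool: Sequence[str],
    master_seed: int,
) -> list[EvaluationCase]:
    """Build one case per (record, cardinality).

    For each record and each requested gene-list size n, the causative
    gene is joined by n-1 decoys drawn uniformly without replacement from
    ``pool`` minus the causative gene, and the combined list is uniformly
    shuffled.  Decoy draws are nested across sizes: each record gets one
    random permutation of the decoy universe and size n takes its first
    n-1 entries.  Size comparisons are therefore paired — a smaller case
    is always a subset of a larger one — which makes performance
    degradation with list size a structural property rather than a
    sampling artifact.  The per-case shuffle seed derives from
    (master_seed, record_id, n) so adding records or sizes never
    perturbs existing cases.

    Records with an empty phenotype profile are skipped with a warning —
    a prompt without phenotypes cannot discriminate genes.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("gene-list sizes must be positive")
    pool = sorted(set(pool))
    if sizes and len(pool) < max(sizes):
        raise ValueError(
            f"decoy pool of {len(pool)} genes cannot support size {max(sizes)}"
        )

    cases: list[EvaluationCase] = []
    for rec in records:
        if rec.n_phenotypes == 0:
            logger.warning(
                "record %s has an empty phenotype profile; skipped", rec.record_id
            )
            continue
        if rec.gene not in pool:
            raise ValueError(
                f"record {rec.record_id}: gene {rec.gene} not in decoy pool"
            )
        decoy_universe = [g for g in pool if g != rec.gene]
        perm_rng = rng_for(master_seed, rec.record_id, "decoys")
        perm_rng.shuffle(decoy_universe)
        for n in sizes:
            seed = stable_seed(master_seed, rec.record_id, n)
            rng = rng_for(master_seed, rec.record_id, n)
            decoys = decoy_universe[: n - 1]
            genes = decoys + [rec.gene]
            rng.shuffle(genes)
            cases.append(
                EvaluationCase(
                    case_id=f"{rec.record_id}:n{n}",
                    phenotypes=list(
                        rec.phenotype_labels or rec.phenotype_ids
                    ),
                    phenotype_ids=list(rec.phenotype_ids),
                    genes=[str(g) for g in genes],
                    causative_gene=rec.gene,
                    sex=rec.sex,
                    moi=rec.moi,
                    seed=seed,
                )
            )
    return cases


def write_cases_jsonl(cases: Iterable[EvaluationCase], path) -> None:
    with open(path, "w") as fh:
        for case in cases:
            fh.write(
                json.dumps(
                    {
                        "case_id": case.case_id,
                        "phenotypes": case.phenotypes,
                        "phenotype_ids": case.phenotype_ids,
                        "genes": case.genes,
                        "causative_gene": case.causative_gene,
                        "sex": case.sex,
                        "moi": case.moi,
                        "seed": case.seed,
                    }
                )
                + "\n"
            )


def read_cases_jsonl(path) -> list[EvaluationCase]:
    cases = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                cases.append(EvaluationCase(**json.loads(line)))
    return cases
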