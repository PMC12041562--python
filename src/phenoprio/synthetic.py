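"""Synthetic study data: ontology, knowledge base, and patient records.

Real benchmarks for phenotype-driven gene prioritization pair a curated
gene-to-phenotype knowledge base (GPCards-, ClinVar- or PAVS-like) with
a phenotype ontology.  This module generates structurally equivalent
artificial stand-ins so the entire pipeline can be exercised and tested
offline:

* a single-rooted acyclic term hierarchy with labels and synonyms,
  writable as an OBO file;
* a knowledge base assigning each synthetic gene a set of phenotype
  terms;
* patient records whose observed phenotype profile is the causative
  gene's knowledge-base profile under controlled noise — per-term
  dropout, replacement by a direct parent (imprecise clinical coding),
  and spurious additions (incidental findings) at a Poisson rate
  proportional to the profile size.

Everything is deterministic under a fixed seed.  Gene symbols are
synthetic ("GENE0001"), deliberately avoiding real nomenclature.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import pandas as pd

from ._seeds import rng_for
from .benchmark import GenePhenotypeRecord
from .ontology import OntologyGraph, OntologyTerm

__all__ = [
    "SyntheticConfig",
    "MOI_VOCABULARY",
    "generate_ontology",
    "write_obo",
    "generate_knowledge_base",
    "generate_patients",
    "write_records_tsv",
    "read_records_tsv",
]

#: Mode-of-inheritance vocabulary; "genetic" doubles as the prompt
#: template's fallback token for an unknown mode.
MOI_VOCABULARY = ("autosomal dominant", "autosomal recessive", "X-linked", "genetic")

_DATE_START = date(2023, 7, 2)
_DATE_END = date(2023, 10, 7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults describe a mid-sized study: a few hundred ontology terms
    and a 200-gene knowledge base with 8 phenotypes per gene (typical of
    a curated rare-disease profile).  Observation noise reflects that
    clinical phenotyping captures only part of a curated profile and
    records incidental findings: 30% per-term dropout, spurious
    additions at 30% of the profile size, and 20% generalization to a
    parent term.
    """

    n_terms: int = 300
    max_parents: int = 3
    n_genes: int = 200
    phenotypes_per_gene: int = 8
    profile_dropout: float = 0.3
    profile_spurious: float = 0.3
    profile_generalize: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("profile_dropout", "profile_spurious", "profile_generalize"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_terms", "max_parents", "n_genes", "phenotypes_per_gene"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.phenotypes_per_gene > self.n_terms:
            raise ValueError("phenotypes_per_gene cannot exceed n_terms")


def _term_id(i: int) -> str:
    return f"SYN:{i:07d}"


def generate_ontology(n_terms: int, max_parents: int, seed: int) -> OntologyGraph:
    """Generate a random single-rooted acyclic term hierarchy.

    Term 0 is the root.  Each later term i draws between 1 and
    ``max_parents`` parents uniformly from terms 0..i-1, which guarantees
    acyclicity and that every term reaches the root.  Labels are
    "term i" with one synonym "syn i".
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = rng_for("ontology", seed)
    terms = [
        OntologyTerm(term_id=_term_id(0), label="term 0", synonyms=frozenset({"syn 0"}))
    ]
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        terms.append(
            OntologyTerm(
                term_id=_term_id(i),
                label=f"term {i}",
                synonyms=frozenset({f"syn {i}"}),
                parent_ids=frozenset(_term_id(int(p)) for p in parents),
            )
        )
    return OntologyGraph(terms)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize a graph as an OBO flat file round-trippable by
    :func:`phenoprio.ontology.load_obo`."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: phenoprio-synthetic\n")
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            fh.write(f"\n[Term]\nid: {term.term_id}\nname: {term.label}\n")
            for syn in sorted(term.synonyms):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for pid in sorted(term.parent_ids):
                fh.write(f"is_a: {pid} ! {graph.terms[pid].label}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")


def generate_knowledge_base(
    graph: OntologyGraph, n_genes: int, phenotypes_per_gene: int, seed: int
) -> list[GenePhenotypeRecord]:
    """Assign each synthetic gene a profile of distinct phenotype terms.

    Terms are drawn uniformly from the non-root, non-obsolete pool; the
    record carries both CURIEs and their labels.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    candidates = graph.perturbable_terms()
    if phenotypes_per_gene > len(candidates):
        raise ValueError(
            f"phenotypes_per_gene={phenotypes_per_gene} exceeds the "
            f"{len(candidates)} available non-root terms"
        )
    rng = rng_for("kb", seed)
    records = []
    for g in range(1, n_genes + 1):
        gene = f"GENE{g:04d}"
        terms = sorted(
            str(t) for t in rng.choice(candidates, size=phenotypes_per_gene, replace=False)
        )
        records.append(
            GenePhenotypeRecord(
                record_id=f"KB:{gene}",
                gene=gene,
                phenotype_ids=terms,
                phenotype_labels=[graph.label_of(t) for t in terms],
            )
        )
    return records


def generate_patients(
    kb: Sequence[GenePhenotypeRecord],
    graph: OntologyGraph,
    n_patients: int,
    config: SyntheticConfig,
    seed: Optional[int] = None,
) -> list[GenePhenotypeRecord]:
    """Simulate patient records from the knowledge base.

    Each patient has one causative gene drawn uniformly from the KB.  The
    observed profile starts from that gene's KB terms; each term is
    independently dropped with ``profile_dropout``; each survivor is
    replaced by a uniformly chosen direct parent with
    ``profile_generalize``; then a Poisson(``profile_spurious`` * m)
    number of spurious terms (m = KB profile size) is added from terms
    outside the profile, capped by pool exhaustion.  Sex is uniform over
    male/female, mode of inheritance uniform over a fixed vocabulary, and
    ``date_added`` uniform over a three-month window so the date filter
    can be exercised.

    A patient whose profile noise removes every phenotype is still
    emitted (with an empty profile); downstream case construction skips
    and counts such records.
    """
    if not kb:
        raise ValueError("knowledge base is empty")
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    seed = config.seed if seed is None else seed
    spurious_pool = graph.perturbable_terms()
    n_days = (_DATE_END - _DATE_START).days

    patients = []
    for i in range(n_patients):
        rng = rng_for("patient", seed, i)
        src = kb[int(rng.integers(len(kb)))]
        m = len(src.phenotype_ids)

        observed: list[str] = []
        for tid in src.phenotype_ids:
            if rng.random() < config.profile_dropout:
                continue
            if rng.random() < config.profile_generalize:
                parents = sorted(graph.direct_parents(tid))
                if parents:
                    tid = parents[int(rng.integers(len(parents)))]
            if tid not in observed:
                observed.append(tid)

        n_spurious = int(rng.poisson(config.profile_spurious * m))
        available = [t for t in spurious_pool if t not in set(observed) | set(src.phenotype_ids)]
        n_spurious = min(n_spurious, len(available))
        if n_spurious:
            observed.extend(
                str(t) for t in rng.choice(available, size=n_spurious, replace=False)
            )

        patients.append(
            GenePhenotypeRecord(
                record_id=f"PT{i:05d}",
                gene=src.gene,
                phenotype_ids=observed,
                phenotype_labels=[graph.label_of(t) for t in observed],
                sex=("male", "female")[int(rng.integers(2))],
                moi=MOI_VOCABULARY[int(rng.integers(len(MOI_VOCABULARY)))],
                date_added=_DATE_START + timedelta(days=int(rng.integers(n_days + 1))),
            )
        )
    return patients


# -- TSV round trip ------------------------------------------------------

_COLUMNS = [
    "record_id",
    "gene",
    "phenotype_ids",
    "phenotype_labels",
    "sex",
    "moi",
    "date_added",
]


def write_records_tsv(records: Sequence[GenePhenotypeRecord], path) -> None:
    rows = [
        {
            "record_id": r.record_id,
            "gene": r.gene,
            "phenotype_ids": "|".join(r.phenotype_ids),
            "phenotype_labels": "|".join(r.phenotype_labels),
            "sex": r.sex or "",
            "moi": r.moi or "",
            "date_added": r.date_added.isoformat() if r.date_added else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list[GenePhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        try:
            when = date.fromisoformat(row.date_added) if row.date_added else None
        except ValueError as exc:
            raise ValueError(
                f"record {row.record_id}: malformed date {row.date_added!r}"
            ) from exc
        records.append(
            GenePhenotypeRecord(
                record_id=row.record_id,
                gene=row.gene,
                phenotype_ids=row.phenotype_ids.split("|") if row.phenotype_ids else [],
                phenotype_labels=row.phenotype_labels.split("|")
                if row.phenotype_labels
                else [],
                sex=row.sex or None,
                moi=row.moi or None,
                date_added=when,
            )
        )
    return records
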