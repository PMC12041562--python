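"""Experiment orchestration: size sweeps, noise sweeps, repetitions.

An experiment takes patient records (generated synthetically or loaded
from TSV), builds evaluation cases at each configured gene-list size,
renders a prompt per case, obtains a ranking from the configured
backend, parses it, and aggregates rank metrics and hallucination rates
into one row per (dataset, template, size) cell.

All randomness derives from the single master seed; a run with the same
configuration reproduces its outputs byte-identically.  When an output
directory is given, every intermediate (cases, prompts, responses,
parses) is persisted as JSONL together with a manifest, so parsing and
evaluation can be replayed offline without re-running the backend.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from ._seeds import stable_seed
from .benchmark import EvaluationCase, GenePhenotypeRecord, build_cases, kb_gene_pool
from .evaluation import (
    CaseOutcome,
    HallucinationStats,
    MetricsRow,
    aggregate,
    hallucination_rates,
    metrics_frame,
    rank_of_causative,
    repetition_summary,
)
from .ontology import OntologyGraph
from .parsing import ParsedRanking, parse_response
from .perturbation import SCENARIOS, PerturbationSpec, perturb
from .prompting import render, run_with_fallback
from .rankers import KBSimilarityRanker, SimulatedRanker, SimulatorParams
from .synthetic import (
    SyntheticConfig,
    generate_knowledge_base,
    generate_ontology,
    generate_patients,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "SweepResult",
    "run_size_sweep",
    "run_noise_sweep",
    "run_repetitions",
]

NOISE_PROPORTIONS = (0.10, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs, in one reproducible object."""

    dataset_name: str = "synthetic"
    sizes: tuple[int, ...] = (5, 25, 50, 75, 100)
    templates: tuple[str, ...] = ("Q4",)
    backend: str = "simulated"  # "simulated" | "kb_similarity"
    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    repetitions: int = 1
    master_seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_patients: int = 50
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if len(set(self.sizes)) != len(self.sizes) or any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive and distinct")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.backend not in ("simulated", "kb_similarity"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class World:
    """The synthetic study materials shared by all cells of a sweep."""

    graph: OntologyGraph
    kb: list[GenePhenotypeRecord]
    patients: list[GenePhenotypeRecord]
    pool: list[str]


@dataclass
class SweepResult:
    metrics: list[MetricsRow]
    hallucinations: HallucinationStats
    outcomes: list[CaseOutcome]
    parses: list[ParsedRanking]
    n_failures: int = 0


def build_world(config: ExperimentConfig) -> World:
    syn = config.synthetic
    graph = generate_ontology(syn.n_terms, syn.max_parents, config.master_seed)
    kb = generate_knowledge_base(
        graph, syn.n_genes, syn.phenotypes_per_gene, config.master_seed
    )
    patients = generate_patients(
        kb, graph, config.n_patients, syn, seed=config.master_seed
    )
    return World(graph=graph, kb=kb, patients=patients, pool=kb_gene_pool(kb))


def _make_ranker(config: ExperimentConfig, world: World, repetition: int):
    if config.backend == "kb_similarity":
        return KBSimilarityRanker(world.kb, world.graph)
    params = dataclasses.replace(
        config.simulator,
        seed=stable_seed(config.master_seed, "backend", repetition),
    )
    return SimulatedRanker(params)


def _run_template(
    cases: Sequence[EvaluationCase],
    template_id: str,
    ranker,
    dataset: str,
    repetition: int,
) -> tuple[list[CaseOutcome], list[ParsedRanking], list[dict], int]:
    outcomes: list[CaseOutcome] = []
    parses: list[ParsedRanking] = []
    records: list[dict] = []
    failures = 0
    for case in cases:
        try:
            if template_id == "Q2+Q3":
                parsed, used = run_with_fallback(
                    "Q2", "Q3", case, ranker, parse_response
                )
                parsed.case_id = case.case_id
                raw_text = None
            else:
                prompt = render(template_id, case)
                response = ranker.rank(case, prompt)
                raw_text = response.raw_text
                used = template_id
                parsed = parse_response(
                    raw_text, set(case.genes), case_id=case.case_id
                )
        except Exception:
            logger.exception("backend failed on case %s; marked failed", case.case_id)
            failures += 1
            parsed = ParsedRanking(
                case_id=case.case_id, missing={g.upper() for g in case.genes},
                failed=True,
            )
            raw_text, used = None, template_id
        parses.append(parsed)
        outcomes.append(
            rank_of_causative(
                parsed, case, template_id=template_id, dataset=dataset,
                repetition=repetition,
            )
        )
        records.append(
            {
                "case_id": case.case_id,
                "template_id": template_id,
                "used_template_id": used,
                "raw_text": raw_text,
                "ranked_genes": parsed.ranked_genes,
                "missing": sorted(parsed.missing),
                "extra": sorted(parsed.extra),
                "duplicates_collapsed": parsed.duplicates_collapsed,
                "failed": parsed.failed,
            }
        )
    return outcomes, parses, records, failures


def run_size_sweep(
    config: ExperimentConfig, world: Optional[World] = None
) -> SweepResult:
    """Run the full pipeline over every (size, template, repetition).

    Returns aggregated metric rows plus the hallucination accounting
    over all prompts regardless of size.  Failed or refused prompts stay
    in every denominator.
    """
    world = world or build_world(config)
    all_outcomes: list[CaseOutcome] = []
    all_parses: list[ParsedRanking] = []
    all_records: list[dict] = []
    all_cases: list[EvaluationCase] = []
    failures = 0

    cases = build_cases(
        world.patients, config.sizes, world.pool, config.master_seed
    )
    all_cases.extend(cases)
    for repetition in range(config.repetitions):
        # repetitions re-issue the same queries; only backend randomness
        # (seeded per repetition) varies, mirroring a stability study
        ranker = _make_ranker(config, world, repetition)
        for template_id in config.templates:
            outcomes, parses, records, n_fail = _run_template(
                cases, template_id, ranker, config.dataset_name, repetition
            )
            all_outcomes.extend(outcomes)
            all_parses.extend(parses)
            all_records.extend(records)
            failures += n_fail

    result = SweepResult(
        metrics=aggregate(all_outcomes),
        hallucinations=hallucination_rates(all_parses),
        outcomes=all_outcomes,
        parses=all_parses,
        n_failures=failures,
    )
    if config.out_dir:
        _persist(config, all_cases, all_records, result)
    return result


def _perturbed_records(
    patients: Sequence[GenePhenotypeRecord],
    graph: OntologyGraph,
    scenario: str,
    proportion: float,
    master_seed: int,
) -> tuple[list[GenePhenotypeRecord], int]:
    """Apply one noise cell to every patient profile; count skipped ones."""
    out = []
    skipped = 0
    for rec in patients:
        spec = PerturbationSpec(
            scenario=scenario,
            proportion=proportion,
            seed=stable_seed(master_seed, "noise", scenario, proportion, rec.record_id),
        )
        result = perturb(rec.phenotype_ids, spec, graph)
        if result.skipped:
            skipped += 1
        out.append(
            dataclasses.replace(
                rec,
                phenotype_ids=list(result.result),
                phenotype_labels=[
                    graph.label_of(t) if t in graph else t for t in result.result
                ],
            )
        )
    return out, skipped


def run_noise_sweep(
    config: ExperimentConfig,
    scenarios: Sequence[str] = SCENARIOS,
    proportions: Sequence[float] = NOISE_PROPORTIONS,
) -> dict[tuple[str, float], SweepResult]:
    """One metrics cell per (scenario, proportion), plus an unperturbed
    baseline under the key ("baseline", 0.0).

    Single-phenotype profiles pass through every cell unaltered and are
    counted in the log.
    """
    world = build_world(config)
    results: dict[tuple[str, float], SweepResult] = {
        ("baseline", 0.0): run_size_sweep(config, world)
    }
    for scenario in scenarios:
        for p in proportions:
            patients, skipped = _perturbed_records(
                world.patients, world.graph, scenario, p, config.master_seed
            )
            if skipped:
                logger.info(
                    "%s @ %.2f: %d single-phenotype profiles passed unaltered",
                    scenario, p, skipped,
                )
            cell_world = World(
                graph=world.graph, kb=world.kb, patients=patients, pool=world.pool
            )
            results[(scenario, p)] = run_size_sweep(config, cell_world)
    return results


def run_repetitions(
    config: ExperimentConfig, n_rep: int = 5
) -> dict[tuple[str, str, int], dict[str, tuple[float, Optional[float]]]]:
    """Repeat the sweep and report mean/SD per metric per cell.

    Cases are held fixed; backend seeds derive from (master_seed,
    repetition index), so the spread measures response stability.  A
    deterministic backend yields SD = 0 in every cell.
    """
    config = dataclasses.replace(config, repetitions=n_rep)
    result = run_size_sweep(config)

    by_cell_rep: dict[tuple, dict[int, list[CaseOutcome]]] = {}
    for o in result.outcomes:
        cell = (o.dataset, o.template_id, o.n)
        by_cell_rep.setdefault(cell, {}).setdefault(o.repetition, []).append(o)

    summary: dict[tuple[str, str, int], dict] = {}
    for cell, reps in sorted(by_cell_rep.items()):
        per_metric: dict[str, list[float]] = {}
        for rep_outcomes in (reps[r] for r in sorted(reps)):
            rows = aggregate(rep_outcomes)
            assert len(rows) == 1
            row = rows[0]
            per_metric.setdefault("hits@1", []).append(row.hits_at_1)
            per_metric.setdefault("hits@10", []).append(row.hits_at_10)
            per_metric.setdefault("roc_auc", []).append(row.roc_auc)
            per_metric.setdefault("aupr", []).append(row.aupr)
        summary[cell] = {
            name: repetition_summary(values) for name, values in per_metric.items()
        }
    return summary


# -- persistence ---------------------------------------------------------

def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _persist(
    config: ExperimentConfig,
    cases: Sequence[EvaluationCase],
    records: Sequence[dict],
    result: SweepResult,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    from . import __version__
    from .benchmark import write_cases_jsonl

    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "master_seed": config.master_seed,
        "version": __version__,
        "n_failures": result.n_failures,
        "denominator_note": (
            "failed/refused prompts are included in hits and hallucination "
            "denominators"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    write_cases_jsonl(cases, out / "cases.jsonl")
    with open(out / "responses.jsonl", "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")

    frame = metrics_frame(result.metrics)
    frame.to_csv(out / "metrics.tsv", sep="\t", index=False)
    frame.to_json(out / "metrics.json", orient="records", indent=2)
    (out / "hallucinations.tsv").write_text(
        "pct_prompts_missing\tpct_prompts_extra\tn_prompts\n"
        f"{result.hallucinations.pct_prompts_missing:.4f}\t"
        f"{result.hallucinations.pct_prompts_extra:.4f}\t"
        f"{result.hallucinations.n_prompts}\n"
    )
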