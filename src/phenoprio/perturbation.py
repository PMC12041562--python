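"""Controlled phenotype-noise scenarios.

Four perturbations probe a ranker's robustness to imperfect phenotyping,
each applied to a stated proportion p of a patient's profile:

* ``remove``     — delete randomly selected phenotypes;
* ``add``        — append ontology terms not already in the profile;
* ``generalize`` — replace selected terms by one of their direct parents
  (coarser clinical coding);
* ``specialize`` — replace selected terms by one of their direct
  children (over-specific coding).

The number of altered terms is floor(p * m) for a profile of size m.
Profiles with zero or one phenotype are passed through unaltered
(``skipped``): a single observation leaves nothing meaningful to perturb.

Profiles may contain free-text labels that failed dictionary mapping to
the ontology.  Such entries remain eligible for removal but are never
chosen for generalization/specialization (their neighbors are unknown)
and are reported in ``unmapped_labels``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

from ._seeds import rng_for
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

SCENARIOS = ("remove", "add", "generalize", "specialize")

__all__ = ["PerturbationSpec", "PerturbedProfile", "SCENARIOS", "n_alterations", "perturb"]


@dataclass(frozen=True)
class PerturbationSpec:
    scenario: str
    proportion: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError(f"proportion must be in (0, 1], got {self.proportion}")


@dataclass
class PerturbedProfile:
    original: list[str]
    result: list[str]
    altered_count: int
    skipped: bool = False
    unmapped_labels: list[str] = field(default_factory=list)


def n_alterations(m: int, p: float) -> int:
    """Number of phenotypes to alter in a profile of size m at proportion p.

    floor(p * m), with profiles of size <= 1 exempt from alteration.
    A small epsilon guards the floor against binary-representation error
    in products like 0.1 * 10.
    """
    if m < 0:
        raise ValueError("profile size must be non-negative")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"proportion must be in (0, 1], got {p}")
    if m <= 1:
        return 0
    return math.floor(p * m + 1e-9)


def _replacement_candidates(
    graph: OntologyGraph, term_id: str, scenario: str
) -> list[str]:
    if scenario == "generalize":
        parents = graph.direct_parents(term_id)
        informative = sorted(parents - graph.roots)
        # fall back to a root parent only when no informative parent exists
        return informative or sorted(parents)
    return sorted(graph.direct_children(term_id))


def perturb(
    profile: Sequence[str], spec: PerturbationSpec, graph: OntologyGraph
) -> PerturbedProfile:
    """Apply one noise scenario to a phenotype profile.

    Terms to alter are selected uniformly without replacement; each term
    is altered at most once.  For generalize/specialize, a replacement
    colliding with a term already in the profile triggers a re-draw among
    the remaining candidates; if every candidate collides the term is
    left in place (logged).  When fewer eligible terms exist than the
    floor count requires, as many as possible are altered and
    ``altered_count`` records the actual number.
    """
    original = list(profile)
    if len(set(original)) != len(original):
        raise ValueError("profile contains duplicate entries")
    unmapped = [t for t in original if t not in graph]
    m = len(original)
    k = n_alterations(m, spec.proportion)
    rng = rng_for("perturb", spec.seed, spec.scenario, spec.proportion)

    if k == 0:
        return PerturbedProfile(
            original=original,
            result=list(original),
            altered_count=0,
            skipped=m <= 1,
            unmapped_labels=unmapped,
        )

    if spec.scenario == "remove":
        victims = set(
            str(t) for t in rng.choice(original, size=min(k, m), replace=False)
        )
        result = [t for t in original if t not in victims]
        return PerturbedProfile(original, result, len(victims), False, unmapped)

    if spec.scenario == "add":
        pool = [t for t in graph.perturbable_terms() if t not in set(original)]
        n_add = min(k, len(pool))
        if n_add < k:
            logger.warning(
                "only %d of %d requested additions possible", n_add, k
            )
        added = [str(t) for t in rng.choice(pool, size=n_add, replace=False)]
        return PerturbedProfile(original, original + added, n_add, False, unmapped)

    # generalize / specialize
    eligible = [
        t
        for t in original
        if t in graph and _replacement_candidates(graph, t, spec.scenario)
    ]
    if len(eligible) < k:
        logger.warning(
            "%s: only %d eligible terms for %d requested alterations",
            spec.scenario,
            len(eligible),
            k,
        )
    chosen = set(
        str(t) for t in rng.choice(eligible, size=min(k, len(eligible)), replace=False)
    ) if eligible else set()

    result = list(original)
    present = set(original)
    altered = 0
    for idx, term in enumerate(original):
        if term not in chosen:
            continue
        candidates = _replacement_candidates(graph, term, spec.scenario)
        rng.shuffle(candidates)
        replacement = next((c for c in candidates if c not in present), None)
        if replacement is None:
            logger.warning(
                "%s: every replacement for %s collides with the profile; kept",
                spec.scenario,
                term,
            )
            continue
        present.discard(term)
        present.add(replacement)
        result[idx] = replacement
        altered += 1
    return PerturbedProfile(original, result, altered, False, unmapped)
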