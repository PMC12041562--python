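"""Phenotype ontology loading and queries.

The ontology (e.g. the Human Phenotype Ontology) is a directed acyclic
graph of phenotype terms connected by ``is_a`` relations.  This module
loads OBO flat files into a light-weight in-memory graph supporting the
three queries the rest of the pipeline needs:

* term lookup by identifier,
* dictionary-style lookup of free-text phenotype descriptions against
  term labels and synonyms (exact match after normalization — no fuzzy
  matching), and
* one-step traversal to direct parents / direct children, as used by the
  generalization and specialization noise scenarios.

Only ``is_a`` edges are considered; other OBO relationship types are
ignored.  Obsolete terms are loaded but excluded from the text-lookup
index and from perturbation candidate pools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import obonet

__all__ = [
    "OntologyTerm",
    "OntologyGraph",
    "OboValidationError",
    "AmbiguousLabelError",
    "normalize_text",
    "load_obo",
]


class OboValidationError(ValueError):
    """The OBO file violates a structural requirement (cycle, dangling edge)."""


class AmbiguousLabelError(ValueError):
    """Two distinct terms share a normalized label or synonym."""


_SYNONYM_RE = re.compile(r'"(.*?)"')
_WS_RE = re.compile(r"\s+")


def normalize_text(text: str) -> str:
    """Normalize a phenotype description for dictionary lookup.

    Lowercase, strip surrounding whitespace, collapse internal runs of
    whitespace to a single space.
    """
    return _WS_RE.sub(" ", text.strip().lower())


@dataclass(frozen=True)
class OntologyTerm:
    """A single ontology class with its label, synonyms and parents."""

    term_id: str
    label: str
    synonyms: frozenset[str] = field(default_factory=frozenset)
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if self.term_id in self.parent_ids:
            raise ValueError(f"term {self.term_id} lists itself as a parent")


class OntologyGraph:
    """An acyclic ``is_a`` hierarchy of :class:`OntologyTerm` objects.

    Construction validates that all parent references resolve, that the
    hierarchy is acyclic, and that no two distinct non-obsolete terms
    collide in the normalized label/synonym index.
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = {}
        for term in terms:
            if term.term_id in self.terms:
                raise OboValidationError(f"duplicate term id {term.term_id}")
            self.terms[term.term_id] = term

        self._children: dict[str, set[str]] = {tid: set() for tid in self.terms}
        for term in self.terms.values():
            for pid in term.parent_ids:
                if pid not in self.terms:
                    raise OboValidationError(
                        f"term {term.term_id} has dangling is_a target {pid}"
                    )
                self._children[pid].add(term.term_id)

        self._check_acyclic()

        self.roots: set[str] = {
            tid for tid, t in self.terms.items() if not t.parent_ids
        }
        self._text_index = self._build_text_index()

    def _check_acyclic(self) -> None:
        dg = nx.DiGraph()
        dg.add_nodes_from(self.terms)
        dg.add_edges_from(
            (t.term_id, pid) for t in self.terms.values() for pid in t.parent_ids
        )
        try:
            cycle = nx.find_cycle(dg)
        except nx.NetworkXNoCycle:
            return
        raise OboValidationError(
            f"is_a hierarchy contains a cycle through {cycle[0][0]}"
        )

    def _build_text_index(self) -> dict[str, str]:
        index: dict[str, str] = {}
        for term in self.terms.values():
            if term.obsolete:
                continue
            for text in {term.label, *term.synonyms}:
                key = normalize_text(text)
                owner = index.get(key)
                if owner is not None and owner != term.term_id:
                    raise AmbiguousLabelError(
                        f"label/synonym {text!r} maps to both {owner} "
                        f"and {term.term_id}"
                    )
                index[key] = term.term_id
        return index

    # -- queries ---------------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term id {term_id!r}") from None

    def label_of(self, term_id: str) -> str:
        return self.term(term_id).label

    def direct_parents(self, term_id: str) -> set[str]:
        """One-step ``is_a`` parents (never transitive ancestors)."""
        return set(self.term(term_id).parent_ids)

    def direct_children(self, term_id: str) -> set[str]:
        """One-step ``is_a`` children (never transitive descendants)."""
        self.term(term_id)
        return set(self._children[term_id])

    def ancestors(self, term_id: str, include_self: bool = True) -> set[str]:
        """Transitive ``is_a`` closure of a term, by default including it."""
        seen: set[str] = set()
        stack = list(self.term(term_id).parent_ids)
        while stack:
            tid = stack.pop()
            if tid not in seen:
                seen.add(tid)
                stack.extend(self.terms[tid].parent_ids)
        if include_self:
            seen.add(term_id)
        return seen

    def map_text_to_term(self, text: str) -> Optional[str]:
        """Resolve a free-text phenotype against labels and synonyms.

        Exact dictionary lookup after :func:`normalize_text`; returns the
        term id or ``None``.  Obsolete terms never match.
        """
        return self._text_index.get(normalize_text(text))

    def perturbable_terms(self) -> list[str]:
        """Non-root, non-obsolete terms, sorted — the candidate pool for
        spurious phenotype additions."""
        return sorted(
            tid
            for tid, t in self.terms.items()
            if not t.obsolete and tid not in self.roots
        )

    # -- export ----------------------------------------------------------

    def write_edge_list(self, path) -> None:
        """Debug export of the ``is_a`` edges as TSV (child_id, parent_id)."""
        with open(path, "w") as fh:
            fh.write("child_id\tparent_id\n")
            for term in sorted(self.terms.values(), key=lambda t: t.term_id):
                for pid in sorted(term.parent_ids):
                    fh.write(f"{term.term_id}\t{pid}\n")


def map_text_to_term(graph: OntologyGraph, text: str) -> Optional[str]:
    """Module-level alias for :meth:`OntologyGraph.map_text_to_term`."""
    return graph.map_text_to_term(text)


def direct_parents(graph: OntologyGraph, term_id: str) -> set[str]:
    return graph.direct_parents(term_id)


def direct_children(graph: OntologyGraph, term_id: str) -> set[str]:
    return graph.direct_children(term_id)


def _parse_synonym(raw: str) -> str:
    m = _SYNONYM_RE.search(raw)
    return m.group(1) if m else raw.strip()


def load_obo(path) -> OntologyGraph:
    """Load an OBO flat file into an :class:`OntologyGraph`.

    Every ``[Term]`` stanza becomes one :class:`OntologyTerm`; ``is_a``
    tags become parent references.  Obsolete terms are retained (flagged)
    so that identifiers stay resolvable, but they are excluded from text
    lookup.  Raises :class:`OboValidationError` on cycles or dangling
    ``is_a`` targets, and ``OSError`` if the file cannot be read.
    """
    multigraph = obonet.read_obo(str(path), ignore_obsolete=False)

    declared = {
        node for node, data in multigraph.nodes(data=True) if "name" in data
    }
    terms = []
    for node in sorted(declared):
        data = multigraph.nodes[node]
        parents = frozenset(
            target
            for _, target, key in multigraph.out_edges(node, keys=True)
            if key == "is_a"
        )
        dangling = parents - declared
        if dangling:
            raise OboValidationError(
                f"term {node} has dangling is_a target {sorted(dangling)[0]}"
            )
        terms.append(
            OntologyTerm(
                term_id=node,
                label=data["name"],
                synonyms=frozenset(
                    _parse_synonym(s) for s in data.get("synonym", [])
                ),
                parent_ids=parents,
                obsolete=data.get("is_obsolete", "false") == "true",
            )
        )
    return OntologyGraph(terms)
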