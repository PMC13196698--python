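"""Directed-acyclic ontology graphs loaded from OBO flat files.

The graph stores terms keyed by CURIE (e.g. ``HANCESTRO:0004``) and the
``is_a`` subsumption relation.  It underpins every other stage of the
toolkit: curated values are validated against descendant closures of
designated ancestor terms ("dynamic enums"), curated term/ID pairs are
round-trip checked via label lookup, and queries are expanded through
synonyms and descendants.

Only ``is_a`` is traversed.  Other relationship tags present in an OBO
file are parsed and ignored; the harmonization model relies purely on
subsumption hierarchies.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import obonet

__all__ = [
    "CURIE_RE",
    "NOT_FOUND",
    "Term",
    "OntologyGraph",
    "OboLoadReport",
    "load_obo",
    "OntologyError",
    "OntologyCycleError",
    "CurieCollisionError",
]

#: Syntactic shape of a CURIE: ``prefix:local``.
CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*:[A-Za-z0-9_.-]+$")

#: Distinguished marker returned by :meth:`OntologyGraph.lookup_label` for
#: CURIEs absent from the graph.  It is a value, not an error: round-trip
#: validation treats absence as a finding to report.
NOT_FOUND = "<term not found>"

_SYNONYM_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


class OntologyError(Exception):
    """Base class for ontology loading/lookup failures."""


class OntologyCycleError(OntologyError):
    """The is_a relation contains a cycle (names one member)."""


class CurieCollisionError(OntologyError):
    """The same CURIE was defined in more than one merged source."""


def _norm(text: str) -> str:
    """Trim, collapse internal whitespace and case-fold for matching."""
    return " ".join(text.split()).casefold()


@dataclass(frozen=True)
class Term:
    """One ontology term.

    Parameters
    ----------
    curie : str
        Compact identifier, ``prefix:local``.
    label : str
        Primary name.  Non-empty for non-obsolete terms.
    synonyms : frozenset of str
        Alternative names, original casing preserved.
    parents : frozenset of str
        CURIEs of direct ``is_a`` parents.
    obsolete : bool
        Obsolete terms are kept and flagged, but never contribute to
        descendant closures or text matching.
    """

    curie: str
    label: str
    synonyms: frozenset[str] = frozenset()
    parents: frozenset[str] = frozenset()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not CURIE_RE.match(self.curie):
            raise ValueError(f"not a syntactic CURIE: {self.curie!r}")
        if not self.obsolete and not self.label:
            raise ValueError(f"non-obsolete term {self.curie} needs a label")
        if self.curie in self.parents:
            raise ValueError(f"self-parenting term: {self.curie}")

    @property
    def prefix(self) -> str:
        return self.curie.split(":", 1)[0]


@dataclass
class OboLoadReport:
    """Non-fatal findings from an OBO load."""

    dangling_parents: list[tuple[str, str]] = field(default_factory=list)
    """(child CURIE, missing parent CURIE) pairs whose edge was dropped."""

    n_terms: int = 0
    n_obsolete: int = 0


class OntologyGraph:
    """Immutable-ish DAG of :class:`Term` objects under ``is_a``.

    Traversal conventions: *descendants* are transitively subsumed terms
    (children-of closure), *ancestors* are transitively subsuming terms.
    Obsolete terms are excluded from closure results and from text
    matching; an explicitly queried node is still returned when
    ``include_self`` is requested.
    """

    def __init__(self, terms: Iterable[Term]):
        self._terms: dict[str, Term] = {}
        for t in terms:
            if t.curie in self._terms:
                raise CurieCollisionError(f"duplicate term definition: {t.curie}")
            self._terms[t.curie] = t
        # edges run child -> parent; every edge endpoint must resolve
        dag = nx.DiGraph()
        dag.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parents:
                if p not in self._terms:
                    raise OntologyError(
                        f"parent {p} of {t.curie} not in graph; "
                        "resolve or drop dangling edges before construction"
                    )
                dag.add_edge(t.curie, p)
        if not nx.is_directed_acyclic_graph(dag):
            member = nx.find_cycle(dag)[0][0]
            raise OntologyCycleError(f"is_a cycle detected involving {member}")
        self._dag = dag
        self._match_index: dict[str, set[str]] = {}
        for t in self._terms.values():
            if t.obsolete:
                continue
            for text in (t.label, *t.synonyms):
                if text:
                    self._match_index.setdefault(_norm(text), set()).add(t.curie)
        self._depth_cache: dict[str, int] = {}

    # -- basic container protocol ------------------------------------
    def __contains__(self, curie: str) -> bool:
        return curie in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(self._terms)

    @property
    def prefixes(self) -> set[str]:
        return {t.prefix for t in self._terms.values()}

    def terms(self) -> Iterable[Term]:
        return self._terms.values()

    def get(self, curie: str) -> Term | None:
        return self._terms.get(curie)

    def __getitem__(self, curie: str) -> Term:
        return self._terms[curie]

    def roots(self) -> set[str]:
        return {c for c, t in self._terms.items() if not t.parents}

    def children(self, curie: str) -> set[str]:
        """Direct non-obsolete children of *curie*."""
        if curie not in self._terms:
            raise KeyError(curie)
        return {
            c for c in self._dag.predecessors(curie) if not self._terms[c].obsolete
        }

    # -- traversal ----------------------------------------------------
    def descendants(self, root: str, include_self: bool = False) -> set[str]:
        """Transitive closure of children-of; excludes obsolete terms."""
        if root not in self._terms:
            raise KeyError(root)
        # edges run child -> parent, so graph-theoretic ancestors of the
        # node are its ontological descendants
        out = {c for c in nx.ancestors(self._dag, root) if not self._terms[c].obsolete}
        if include_self:
            out.add(root)
        return out

    def ancestors(self, curie: str, include_self: bool = False) -> set[str]:
        """Transitive closure of parent-of; excludes obsolete terms."""
        if curie not in self._terms:
            raise KeyError(curie)
        out = {c for c in nx.descendants(self._dag, curie) if not self._terms[c].obsolete}
        if include_self:
            out.add(curie)
        return out

    def shared_ancestors(self, curies: Iterable[str]) -> set[str]:
        """Intersection of ``ancestors(include_self=True)`` over the inputs."""
        curies = list(curies)
        if not curies:
            raise ValueError("shared_ancestors needs at least one CURIE")
        shared: set[str] | None = None
        for c in curies:
            anc = self.ancestors(c, include_self=True)
            shared = anc if shared is None else shared & anc
        assert shared is not None
        return shared

    def lookup_label(self, curie: str) -> str:
        """Label for *curie*, or :data:`NOT_FOUND` when absent."""
        t = self._terms.get(curie)
        return t.label if t is not None else NOT_FOUND

    def match_terms(self, text: str) -> set[str]:
        """CURIEs whose label, synonym or CURIE equals *text*.

        Comparison is whitespace-trimmed and case-insensitive; obsolete
        terms never match.
        """
        key = _norm(text)
        hits = set(self._match_index.get(key, ()))
        stripped = text.strip()
        for cand in (stripped, stripped.upper(), stripped.lower()):
            t = self._terms.get(cand)
            if t is not None and not t.obsolete:
                hits.add(t.curie)
        # case-insensitive CURIE fallback (rare; linear only on miss)
        if not hits and CURIE_RE.match(stripped):
            folded = stripped.casefold()
            hits.update(
                c
                for c, t in self._terms.items()
                if c.casefold() == folded and not t.obsolete
            )
        return hits

    def term_depth(self, curie: str) -> int:
        """Length of the longest is_a path from *curie* up to any root.

        Longest (not shortest) path scores specificity: in a
        multi-parent DAG a term reachable through a deep branch counts
        as at least that specific, which is what most-specific
        consolidation wants.
        """
        if curie not in self._terms:
            raise KeyError(curie)
        cache = self._depth_cache
        # iterative DFS over the parent relation with memoisation
        stack = [curie]
        while stack:
            node = stack[-1]
            if node in cache:
                stack.pop()
                continue
            parents = self._terms[node].parents
            pending = [p for p in parents if p not in cache]
            if pending:
                stack.extend(pending)
                continue
            cache[node] = 1 + max((cache[p] for p in parents), default=-1)
            stack.pop()
        return cache[curie]

    # -- merge / export ----------------------------------------------
    @classmethod
    def merge(cls, graphs: Iterable["OntologyGraph"]) -> "OntologyGraph":
        """Merge several graphs; CURIE collisions are a hard error."""
        terms: list[Term] = []
        for g in graphs:
            terms.extend(g.terms())
        return cls(terms)

    def to_edge_list(self, path: str | Path) -> None:
        """Write a two-column (child, parent) TSV edge list."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("child\tparent\n")
            for child, parent in sorted(self._dag.edges()):
                fh.write(f"{child}\t{parent}\n")

    def write_obo(self, path: str | Path) -> None:
        """Emit the minimal term-stanza OBO subset this package reads."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("format-version: 1.2\n")
            prefixes = sorted(self.prefixes)
            fh.write(f"ontology: {prefixes[0].lower() if prefixes else 'empty'}\n")
            for curie in sorted(self._terms):
                t = self._terms[curie]
                fh.write(f"\n[Term]\nid: {t.curie}\n")
                if t.label:
                    fh.write(f"name: {t.label}\n")
                for syn in sorted(t.synonyms):
                    fh.write(f'synonym: "{syn}" EXACT []\n')
                for p in sorted(t.parents):
                    lbl = self._terms[p].label
                    fh.write(f"is_a: {p} ! {lbl}\n")
                if t.obsolete:
                    fh.write("is_obsolete: true\n")


def _parse_synonym(raw: str) -> str | None:
    m = _SYNONYM_RE.match(raw.strip())
    if not m:
        return None
    return m.group("text").replace('\\"', '"')


def load_obo(
    *paths: str | Path,
) -> tuple[OntologyGraph, OboLoadReport]:
    """Load one or more OBO flat files into a single merged graph.

    Unknown tags are ignored.  ``is_a`` targets that never appear as a
    stanza of their own are reported as dangling and their edges
    dropped — not fatal, since excerpted ontology files routinely refer
    upward to terms outside the excerpt.

    Raises
    ------
    OntologyError
        Unreadable file.
    OntologyCycleError
        The merged is_a relation is cyclic.
    CurieCollisionError
        The same CURIE is defined by more than one file.
    """
    if not paths:
        raise ValueError("load_obo needs at least one path")
    report = OboLoadReport()
    stanzas: dict[str, dict] = {}
    for path in paths:
        try:
            raw = obonet.read_obo(Path(path), ignore_obsolete=False)
        except OSError as exc:
            raise OntologyError(f"cannot read OBO file {path}: {exc}") from exc
        for node, data in raw.nodes(data=True):
            if "name" not in data and "is_obsolete" not in data:
                continue  # node materialised only as an is_a target
            if node in stanzas:
                raise CurieCollisionError(
                    f"CURIE {node} defined in more than one input file"
                )
            stanzas[node] = data
    terms: dict[str, Term] = {}
    for node in sorted(stanzas):
        data = stanzas[node]
        parents = []
        for p in data.get("is_a", []):
            if p in stanzas:
                parents.append(p)
            else:
                report.dangling_parents.append((node, p))
        synonyms = frozenset(
            s for s in (_parse_synonym(r) for r in data.get("synonym", [])) if s
        )
        terms[node] = Term(
            curie=node,
            label=data.get("name", ""),
            synonyms=synonyms,
            parents=frozenset(parents),
            obsolete=str(data.get("is_obsolete", "")).lower() == "true",
        )
    graph = OntologyGraph(terms.values())
    report.n_terms = len(graph)
    report.n_obsolete = sum(t.obsolete for t in graph.terms())
    return graph, report
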