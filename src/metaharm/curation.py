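"""Curation maps: per-attribute dictionaries from verbatim original
values to (ontology term label, CURIE) pairs.

A map encodes the manual curation work: abbreviations spelled out,
brand names consolidated to the generic compound, typos repaired.
Applying a map to a delimited cell maps each token independently;
tokens that the map sends to the same curated term (e.g. two brand
names of one drug) collapse to a single occurrence, and unmapped
tokens pass through verbatim so no information is destroyed before
review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .issues import IssueKind, Severity, ValidationIssue
from .ontology import CURIE_RE, NOT_FOUND, OntologyGraph
from .util import is_na, join_tokens, norm_token, read_table, split_cell

__all__ = [
    "CurationMapEntry",
    "CurationMap",
    "MapLoadReport",
    "MapResult",
    "CoverageReport",
    "CurationMapError",
    "load_map",
    "apply_map",
    "roundtrip_validate_map",
    "coverage_report",
]


class CurationMapError(Exception):
    """Malformed or internally conflicting curation map."""


@dataclass(frozen=True)
class CurationMapEntry:
    """One ``original value -> ontology term`` pair.

    ``curated_ontology_term`` and ``curated_ontology_term_id`` are both
    present or both None; a None target means the original value was
    reviewed and judged uninterpretable, so applying the map drops it
    to NA.
    """

    original_value: str
    curated_ontology_term: str | None
    curated_ontology_term_id: str | None

    def __post_init__(self) -> None:
        if (self.curated_ontology_term is None) != (
            self.curated_ontology_term_id is None
        ):
            raise CurationMapError(
                f"entry {self.original_value!r}: term and id must both be "
                "present or both NA"
            )

    @property
    def is_na_target(self) -> bool:
        return self.curated_ontology_term is None


@dataclass
class MapLoadReport:
    """Rows set aside during a load (reported, not fatal)."""

    malformed_curies: list[tuple[str, str]] = field(default_factory=list)
    """(original_value, offending id) pairs with non-CURIE ids."""


class CurationMap:
    """Lookup table from normalized original values to curated targets."""

    def __init__(self, attribute: str, entries: Iterable[CurationMapEntry]):
        self.attribute = attribute
        self.entries: list[CurationMapEntry] = []
        self._index: dict[str, CurationMapEntry] = {}
        for e in entries:
            key = norm_token(e.original_value)
            prev = self._index.get(key)
            if prev is not None:
                if (
                    prev.curated_ontology_term == e.curated_ontology_term
                    and prev.curated_ontology_term_id == e.curated_ontology_term_id
                ):
                    continue  # idempotent duplicate
                raise CurationMapError(
                    f"map {attribute!r}: duplicate original value "
                    f"{e.original_value!r} with conflicting targets "
                    f"({prev.curated_ontology_term!r} vs "
                    f"{e.curated_ontology_term!r})"
                )
            self._index[key] = e
            self.entries.append(e)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, token: str) -> CurationMapEntry | None:
        return self._index.get(norm_token(token))

    def __contains__(self, token: str) -> bool:
        return norm_token(token) in self._index

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("original_value\tcurated_ontology_term\tcurated_ontology_term_id\n")
            for e in self.entries:
                fh.write(
                    f"{e.original_value}\t{e.curated_ontology_term or ''}\t"
                    f"{e.curated_ontology_term_id or ''}\n"
                )


def load_map(
    path: str | Path, attribute: str | None = None
) -> tuple[CurationMap, MapLoadReport]:
    """Load a 3-column delimited curation map.

    Expected header: ``original_value``, ``curated_ontology_term``,
    ``curated_ontology_term_id`` (tab- or comma-separated by
    extension).  Rows whose id is present but not a syntactic CURIE are
    collected into the load report and skipped; duplicate original
    values with conflicting targets are a hard error.
    """
    path = Path(path)
    if attribute is None:
        attribute = path.stem
    df = read_table(path)
    required = {"original_value", "curated_ontology_term", "curated_ontology_term_id"}
    missing = required - set(df.columns)
    if missing:
        raise CurationMapError(f"map file {path} lacks columns: {sorted(missing)}")
    report = MapLoadReport()
    entries: list[CurationMapEntry] = []
    for row in df.itertuples(index=False):
        orig = getattr(row, "original_value")
        term = getattr(row, "curated_ontology_term")
        cid = getattr(row, "curated_ontology_term_id")
        if is_na(orig):
            continue
        term = None if is_na(term) else str(term)
        cid = None if is_na(cid) else str(cid)
        if cid is not None and not CURIE_RE.match(cid):
            report.malformed_curies.append((str(orig), cid))
            continue
        entries.append(CurationMapEntry(str(orig), term, cid))
    return CurationMap(attribute, entries), report


@dataclass
class MapResult:
    """Outcome of applying a map to one cell."""

    curated_value: str | None
    curated_ids: str | None
    unmapped: list[str]


def apply_map(cell, cmap: CurationMap, delimiter: str = ";") -> MapResult:
    """Map each token of a delimited cell through *cmap*.

    Mapped tokens are replaced by their curated term; tokens mapping to
    the same curated term collapse to one occurrence (first position
    wins), which is how separately entered brand names consolidate to
    one generic drug.  Unmapped tokens pass through verbatim, are
    reported in ``unmapped``, and carry an empty id slot.  NA in, NA
    out.
    """
    if is_na(cell):
        return MapResult(None, None, [])
    terms: list[str] = []
    ids: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for token in split_cell(cell, delimiter):
        entry = cmap.lookup(token)
        if entry is None:
            out_term, out_id = token, ""
            unmapped.append(token)
        elif entry.is_na_target:
            continue  # reviewed-uninterpretable: drops to NA
        else:
            out_term = entry.curated_ontology_term
            out_id = entry.curated_ontology_term_id or ""
        key = norm_token(out_term)
        if key in seen:
            continue
        seen.add(key)
        terms.append(out_term)
        ids.append(out_id)
    return MapResult(
        join_tokens(terms, delimiter), join_tokens(ids, delimiter), unmapped
    )


def roundtrip_validate_map(
    cmap: CurationMap, graph: OntologyGraph
) -> list[ValidationIssue]:
    """Check every entry's id against the ontology and back.

    For each non-NA entry, the id is looked up in the graph and the
    returned label compared (case-insensitively) with the stored
    curated term.  Kinds of finding: ``id-not-found``,
    ``label-mismatch`` and ``obsolete-target``; a clean map yields an
    empty list.
    """
    issues: list[ValidationIssue] = []
    loc = f"map:{cmap.attribute}"

    def _issue(code: str, entry: CurationMapEntry, detail: str) -> ValidationIssue:
        return ValidationIssue(
            kind=IssueKind.ROUNDTRIP_MISMATCH,
            severity=Severity.ERROR,
            curation_id=loc,
            attribute=cmap.attribute,
            observed=f"{entry.curated_ontology_term} [{entry.curated_ontology_term_id}]",
            detail=detail,
            code=code,
        )

    for entry in cmap.entries:
        if entry.is_na_target:
            continue
        cid = entry.curated_ontology_term_id
        assert cid is not None
        label = graph.lookup_label(cid)
        if label == NOT_FOUND:
            issues.append(_issue("id-not-found", entry, f"{cid} absent from graph"))
            continue
        term = graph.get(cid)
        if term is not None and term.obsolete:
            issues.append(_issue("obsolete-target", entry, f"{cid} is obsolete"))
            continue
        if norm_token(label) != norm_token(entry.curated_ontology_term or ""):
            issues.append(
                _issue(
                    "label-mismatch",
                    entry,
                    f"graph label {label!r} != curated term "
                    f"{entry.curated_ontology_term!r}",
                )
            )
    return issues


@dataclass
class CoverageReport:
    """Token-level map coverage of a raw column."""

    mapped_fraction: float | None
    unmapped_uniques: list[str]


def coverage_report(
    cmap: CurationMap, column: Sequence, delimiter: str = ";"
) -> CoverageReport:
    """Fraction of non-NA tokens of *column* found in the map.

    All-NA columns have no defined fraction and report None.
    """
    n_tokens = 0
    n_mapped = 0
    unmapped: set[str] = set()
    for cell in column:
        for token in split_cell(cell, delimiter):
            n_tokens += 1
            if token in cmap:
                n_mapped += 1
            else:
                unmapped.add(token)
    if n_tokens == 0:
        return CoverageReport(None, [])
    return CoverageReport(n_mapped / n_tokens, sorted(unmapped))
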