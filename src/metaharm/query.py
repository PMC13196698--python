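"""Hierarchy-aware filtering and wide/long reshaping of harmonized tables.

``tree_filter`` answers queries the way a curator thinks: asking for
"Neoplasm" should return samples annotated "Primary Neoplasm" or
"Metastatic Neoplasm" even though no cell literally says "Neoplasm".
Each query term is resolved to ontology terms through labels, synonyms
or CURIEs, expanded to its full descendant closure, and rows are kept
when their delimited tokens intersect the expansion.

``spread_meta`` / ``gather_meta`` transform multi-valued and composite
attributes between their packed single-column form and a wide
per-token / per-subfield form, and are exact inverses of each other on
canonically ordered cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Literal

import pandas as pd

from .engine import HarmonizedTable
from .ontology import OntologyGraph
from .util import is_na, join_tokens, norm_token, split_cell

__all__ = [
    "QuerySpec",
    "tree_filter",
    "spread_meta",
    "gather_meta",
    "canonicalize_tokens",
    "get_metadata",
]

#: Marker used in spread indicator columns for multi-valued attributes.
PRESENT = "yes"


@dataclass
class QuerySpec:
    """One hierarchical query against a harmonized attribute."""

    attribute: str
    terms: list[str]
    logic: Literal["any", "all"] = "any"
    expand: bool = True

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("query needs at least one term")


@dataclass
class _Expansion:
    labels: set[str] = dataclass_field(default_factory=set)  # normalized
    curies: set[str] = dataclass_field(default_factory=set)  # exact

    def matches(self, token: str) -> bool:
        return norm_token(token) in self.labels or token.strip() in self.curies


def _expand_term(term: str, graph: OntologyGraph | None, expand: bool) -> _Expansion:
    exp = _Expansion()
    if not expand or graph is None:
        exp.labels.add(norm_token(term))
        exp.curies.add(term.strip())
        return exp
    matched = graph.match_terms(term)
    if not matched:
        warnings.warn(
            f"query term {term!r} does not resolve in the ontology; "
            "falling back to literal matching",
            stacklevel=3,
        )
        exp.labels.add(norm_token(term))
        exp.curies.add(term.strip())
        return exp
    closure: set[str] = set()
    for curie in matched:
        closure |= graph.descendants(curie, include_self=True)
    for curie in closure:
        t = graph[curie]
        exp.curies.add(curie)
        exp.labels.add(norm_token(t.label))
        exp.labels.update(norm_token(s) for s in t.synonyms)
    return exp


def tree_filter(
    table: HarmonizedTable,
    query: QuerySpec,
    graph: OntologyGraph | None = None,
) -> HarmonizedTable:
    """Keep rows whose attribute tokens hit the query's expansion set.

    With ``expand=True`` each query term contributes its matched
    ontology terms plus all their descendants, realized as labels,
    synonyms and CURIEs; with ``expand=False`` matching degenerates to
    literal (case-insensitive, trimmed) token comparison.  ``logic``
    is per query term: "any" keeps a row that some term's expansion
    hits, "all" requires every term's expansion to hit it.  Row order
    is preserved.
    """
    col = f"curated_{query.attribute}"
    if col not in table.data.columns:
        raise KeyError(col)
    delim = ";"
    if table.config is not None:
        try:
            delim = table.config.attribute(query.attribute).delimiter
        except KeyError:
            pass
    expansions = [_expand_term(t, graph, query.expand) for t in query.terms]

    def keep(cell) -> bool:
        tokens = split_cell(cell, delim)
        if not tokens:
            return False
        hits = (any(e.matches(tok) for tok in tokens) for e in expansions)
        return any(hits) if query.logic == "any" else all(hits)

    mask = table.data[col].map(keep)
    return HarmonizedTable(table.data[mask].reset_index(drop=True), table.config)


def _structure_of(table: HarmonizedTable, attribute: str) -> tuple[str, str, list[str] | None]:
    """(structure, delimiter, subfields) for an anchored attribute."""
    if table.config is not None:
        try:
            spec = table.config.attribute(attribute)
            return spec.structure, spec.delimiter, spec.subfields
        except KeyError:
            pass
    raise ValueError(
        f"attribute {attribute!r} not described by the table's schema; "
        "spread/gather need its structure (multi or composite)"
    )


def spread_meta(table: HarmonizedTable, attribute: str) -> pd.DataFrame:
    """Spread a multi-valued or composite attribute into wide columns.

    Composite cells "CRP:12;IL6:3" become columns
    ``{attribute}_CRP`` = "12", ``{attribute}_IL6`` = "3"; multi-valued
    cells become per-token presence indicators ("yes"/NA).  The packed
    column is replaced in place; row count, row order and every other
    column are untouched.  Single-valued and numeric attributes are an
    argument error.
    """
    structure, delim, subfields = _structure_of(table, attribute)
    if structure not in ("multi", "composite"):
        raise ValueError(
            f"spread_meta needs a multi-valued or composite attribute; "
            f"{attribute!r} is {structure!r}"
        )
    col = f"curated_{attribute}"
    if col not in table.data.columns:
        raise KeyError(col)
    cells = table.data[col]

    # observed keys in canonical order: registry order for composites
    # with a registry, else order of first appearance
    observed: list[str] = []
    per_row: list[dict[str, str]] = []
    for cell in cells:
        row: dict[str, str] = {}
        for tok in split_cell(cell, delim):
            if structure == "composite":
                if ":" not in tok:
                    raise ValueError(
                        f"malformed composite token {tok!r} in {col}"
                    )
                key, value = tok.split(":", 1)
            else:
                key, value = tok, PRESENT
            row[key] = value
            if key not in observed:
                observed.append(key)
        per_row.append(row)
    if structure == "composite" and subfields:
        ordered = [s for s in subfields if s in observed]
        ordered += [k for k in observed if k not in ordered]
        observed = ordered
    elif structure == "multi":
        observed = sorted(observed)
    if not observed:
        warnings.warn(
            f"attribute {attribute!r} is entirely NA; nothing to spread",
            stacklevel=2,
        )

    wide = table.data.drop(columns=[col]).copy()
    insert_at = list(table.data.columns).index(col)
    for offset, key in enumerate(observed):
        new_col = f"{attribute}_{key}"
        wide.insert(
            insert_at + offset,
            new_col,
            [row.get(key) for row in per_row],
        )
    return wide


def gather_meta(
    wide: pd.DataFrame,
    attribute: str,
    structure: Literal["multi", "composite"] = "multi",
    delimiter: str = ";",
) -> pd.DataFrame:
    """Inverse of :func:`spread_meta`.

    Columns named ``{attribute}_{key}`` are packed back into one
    ``curated_{attribute}`` column in column order (the canonical token
    order).  Zero anchored columns, or an anchored column with an empty
    key, is a hard error listing the offenders.
    """
    prefix = f"{attribute}_"
    anchored = [c for c in wide.columns if c.startswith(prefix)]
    malformed = [c for c in anchored if c == prefix]
    if malformed:
        raise ValueError(f"malformed spread column names: {malformed}")
    if not anchored:
        raise ValueError(
            f"no columns with prefix {prefix!r} to gather for {attribute!r}"
        )
    cells = []
    for _, row in wide[anchored].iterrows():
        toks = []
        for c in anchored:
            value = row[c]
            if is_na(value):
                continue
            key = c[len(prefix):]
            if structure == "composite":
                toks.append(f"{key}:{value}")
            else:
                toks.append(key)
        cells.append(join_tokens(toks, delimiter))
    out = wide.drop(columns=anchored).copy()
    insert_at = list(wide.columns).index(anchored[0])
    out.insert(insert_at, f"curated_{attribute}", cells)
    return out


def canonicalize_tokens(table: HarmonizedTable, attribute: str) -> HarmonizedTable:
    """Rewrite an attribute's cells in canonical token order.

    Multi-valued cells are sorted alphabetically; composite cells are
    ordered by the subfield registry.  ``gather_meta(spread_meta(t))``
    is the identity exactly on canonicalized tables, since the wide
    form cannot represent per-row token order.
    """
    structure, delim, subfields = _structure_of(table, attribute)
    col = f"curated_{attribute}"
    out = table.copy()

    def canon(cell):
        toks = split_cell(cell, delim)
        if not toks:
            return None
        if structure == "composite":
            parts = dict(t.split(":", 1) for t in toks)
            order = [s for s in (subfields or []) if s in parts]
            order += [k for k in parts if k not in order]
            return delim.join(f"{k}:{parts[k]}" for k in order)
        return delim.join(sorted(toks))

    out.data[col] = out.data[col].map(canon)
    return out


#: Name of the packaged demonstration table.
DEMO_NAME = "demo"


def get_metadata(source: str | Path) -> HarmonizedTable:
    """Load a harmonized table from a path or a packaged fixture name.

    A TSV written by the harmonization engine is loaded together with
    its schema sidecar; a missing sidecar degrades to a minimal
    inferred schema with a warning.  The packaged name ``"demo"``
    loads the small demonstration table shipped with the package.
    """
    if str(source) == DEMO_NAME:
        path = Path(__file__).parent / "data" / "demo_metadata.tsv"
    else:
        path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"no such metadata table: {source}")
    if not HarmonizedTable.sidecar_path(path).exists():
        warnings.warn(
            f"{path} has no schema sidecar; loading with an inferred "
            "minimal schema",
            stacklevel=2,
        )
    return HarmonizedTable.read(path)
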