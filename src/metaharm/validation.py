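"""Table-level validation: dynamic enums, consistency rules, outliers,
round-trip verification.

Validation only reports; nothing here mutates a table.  The central
idea is the *dynamic enum*: instead of maintaining a hard-coded value
list per attribute, the config names one or more ontology ancestor
terms and the allowed values are, at validation time, the descendant
closure of those nodes.  Values outside the pool are likely wrong or
sitting under the wrong attribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .config import ConsistencyRuleSpec, EnumSpec, HarmonizationConfig
from .engine import HarmonizedTable
from .issues import IssueKind, Severity, ValidationIssue
from .ontology import NOT_FOUND, OntologyGraph
from .util import is_na, norm_token, split_cell

__all__ = [
    "DynamicEnum",
    "allowed_values",
    "validate_enum",
    "check_consistency",
    "detect_outliers",
    "roundtrip_check",
    "validate_table",
]


@dataclass(frozen=True)
class DynamicEnum:
    """A dynamic enumeration bound to one attribute."""

    attribute: str
    nodes: tuple[str, ...]
    include_nodes: bool = False
    allow_combinations: bool = True

    @classmethod
    def from_spec(cls, attribute: str, spec: EnumSpec) -> "DynamicEnum":
        return cls(
            attribute=attribute,
            nodes=tuple(spec.nodes),
            include_nodes=spec.include_nodes,
            allow_combinations=spec.allow_combinations,
        )


def allowed_values(
    enum: DynamicEnum | EnumSpec, graph: OntologyGraph
) -> set[tuple[str, str]]:
    """The enum's value pool: union of descendant closures of its nodes.

    Returns (CURIE, label) pairs.  ``include_nodes`` toggles whether
    the enum nodes themselves belong to the pool.  Unresolved nodes are
    a hard error; an all-leaf enum with ``include_nodes=False`` yields
    an empty pool and a warning, since it can never validate anything.
    """
    nodes = enum.nodes
    include = enum.include_nodes
    pool: set[str] = set()
    for node in nodes:
        if node not in graph:
            raise KeyError(f"dynamic enum node {node} not in ontology graph")
        pool |= graph.descendants(node, include_self=include)
    if not pool:
        warnings.warn(
            f"dynamic enum over {list(nodes)} has an empty value pool "
            "(all nodes are leaves and include_nodes is false)",
            stacklevel=2,
        )
    return {(c, graph.lookup_label(c)) for c in pool}


def validate_enum(
    table: HarmonizedTable,
    attr: str,
    enum: DynamicEnum | EnumSpec,
    graph: OntologyGraph,
) -> list[ValidationIssue]:
    """Flag tokens of ``curated_{attr}`` outside the enum's pool.

    Membership is granted by curated label (case-insensitive) or by
    CURIE (exact), so label-only tables still validate.  Multi-valued
    cells are validated token-wise when the enum allows combinations;
    otherwise a multi-token cell is itself a finding.
    """
    if isinstance(enum, EnumSpec):
        enum = DynamicEnum.from_spec(attr, enum)
    pool = allowed_values(enum, graph)
    pool_labels = {norm_token(label) for _, label in pool}
    pool_curies = {c for c, _ in pool}
    col = f"curated_{attr}"
    if col not in table.data.columns:
        raise KeyError(col)
    delim = _attr_delimiter(table, attr)
    issues: list[ValidationIssue] = []
    for cid, cell in zip(table.data["curation_id"], table.data[col]):
        tokens = split_cell(cell, delim)
        if not tokens:
            continue
        if len(tokens) > 1 and not enum.allow_combinations:
            issues.append(
                ValidationIssue(
                    kind=IssueKind.OUT_OF_POOL,
                    severity=Severity.ERROR,
                    curation_id=str(cid),
                    attribute=attr,
                    observed=str(cell),
                    detail="multi-valued cell but enum forbids combinations",
                )
            )
            continue
        for tok in tokens:
            if norm_token(tok) in pool_labels or tok in pool_curies:
                continue
            issues.append(
                ValidationIssue(
                    kind=IssueKind.OUT_OF_POOL,
                    severity=Severity.ERROR,
                    curation_id=str(cid),
                    attribute=attr,
                    observed=tok,
                    detail=f"not among descendants of {list(enum.nodes)}",
                )
            )
    return issues


def check_consistency(
    table: HarmonizedTable, rules: list[ConsistencyRuleSpec]
) -> list[ValidationIssue]:
    """Apply propositional cross-attribute impossibility rules.

    A row violates a rule when its ``if_attribute`` value lies in
    ``if_values`` and its ``then_attribute`` value lies in
    ``forbidden_values``; NA on either side never matches.  The issue
    is located at the forbidden (``then``) attribute.
    """
    issues: list[ValidationIssue] = []
    for rule in rules:
        if_col = f"curated_{rule.if_attribute}"
        then_col = f"curated_{rule.then_attribute}"
        for col in (if_col, then_col):
            if col not in table.data.columns:
                raise KeyError(col)
        if_set = {norm_token(v) for v in rule.if_values}
        forb_set = {norm_token(v) for v in rule.forbidden_values}
        if_delim = _attr_delimiter(table, rule.if_attribute)
        then_delim = _attr_delimiter(table, rule.then_attribute)
        for cid, if_cell, then_cell in zip(
            table.data["curation_id"], table.data[if_col], table.data[then_col]
        ):
            if_tokens = {norm_token(t) for t in split_cell(if_cell, if_delim)}
            if not if_tokens & if_set:
                continue
            hit = [
                t for t in split_cell(then_cell, then_delim)
                if norm_token(t) in forb_set
            ]
            for tok in hit:
                issues.append(
                    ValidationIssue(
                        kind=IssueKind.INCONSISTENCY,
                        severity=Severity.ERROR,
                        curation_id=str(cid),
                        attribute=rule.then_attribute,
                        observed=f"{if_cell} / {tok}",
                        detail=f"violates rule {rule.name!r}",
                    )
                )
    return issues


def detect_outliers(
    table: HarmonizedTable, attr: str, low: float, high: float
) -> list[ValidationIssue]:
    """Flag numeric values outside the closed interval [low, high].

    The bounds are config-supplied plausibility constants (e.g. a human
    age above 130 years); NA values are skipped.
    """
    if table.config is not None:
        try:
            spec = table.config.attribute(attr)
        except KeyError:
            spec = None
        if spec is not None and spec.structure != "numeric":
            raise ValueError(
                f"detect_outliers needs a numeric attribute, {attr!r} is "
                f"{spec.structure!r}"
            )
    col = f"curated_{attr}"
    if col not in table.data.columns:
        raise KeyError(col)
    issues: list[ValidationIssue] = []
    for cid, cell in zip(table.data["curation_id"], table.data[col]):
        if is_na(cell):
            continue
        try:
            value = float(cell)
        except (TypeError, ValueError):
            issues.append(
                ValidationIssue(
                    kind=IssueKind.NON_INTERPRETABLE,
                    severity=Severity.WARNING,
                    curation_id=str(cid),
                    attribute=attr,
                    observed=str(cell),
                    detail="numeric attribute cell is not a number",
                )
            )
            continue
        if not (low <= value <= high):
            issues.append(
                ValidationIssue(
                    kind=IssueKind.OUTLIER,
                    severity=Severity.ERROR,
                    curation_id=str(cid),
                    attribute=attr,
                    observed=str(cell),
                    detail=f"outside plausibility bounds [{low}, {high}]",
                )
            )
    return issues


def roundtrip_check(
    table: HarmonizedTable, graph: OntologyGraph
) -> list[ValidationIssue]:
    """Verify curated term / ontology id agreement, token-wise.

    For every ``curated_{a}`` / ``curated_{a}_ontology_term_id`` column
    pair, each id token is looked up in the graph and its label
    compared (case-insensitively) with the stored term token.  Findings
    are coded ``id-not-found``, ``obsolete-target`` or
    ``label-mismatch``; empty id slots mark unmapped passthrough tokens
    and are skipped; ragged term/id token counts are reported rather
    than raised.
    """
    issues: list[ValidationIssue] = []
    id_suffix = "_ontology_term_id"
    for id_col in table.data.columns:
        if not (id_col.startswith("curated_") and id_col.endswith(id_suffix)):
            continue
        attr = id_col[len("curated_"): -len(id_suffix)]
        term_col = f"curated_{attr}"
        if term_col not in table.data.columns:
            continue
        delim = _attr_delimiter(table, attr)
        for cid, term_cell, id_cell in zip(
            table.data["curation_id"], table.data[term_col], table.data[id_col]
        ):
            if is_na(id_cell):
                continue
            terms = [t.strip() for t in str(term_cell).split(delim)] if not is_na(term_cell) else []
            ids = [t.strip() for t in str(id_cell).split(delim)]
            if len(terms) != len(ids):
                issues.append(
                    ValidationIssue(
                        kind=IssueKind.NON_INTERPRETABLE,
                        severity=Severity.ERROR,
                        curation_id=str(cid),
                        attribute=attr,
                        observed=f"{term_cell} / {id_cell}",
                        detail=f"{len(terms)} term tokens vs {len(ids)} id tokens",
                    )
                )
                continue
            for term_tok, id_tok in zip(terms, ids):
                if not id_tok:
                    continue  # passthrough token, never curated
                label = graph.lookup_label(id_tok)
                if label == NOT_FOUND:
                    code, detail = "id-not-found", f"{id_tok} absent from graph"
                else:
                    t = graph.get(id_tok)
                    if t is not None and t.obsolete:
                        code, detail = "obsolete-target", f"{id_tok} is obsolete"
                    elif norm_token(label) != norm_token(term_tok):
                        code = "label-mismatch"
                        detail = f"graph label {label!r} != curated term {term_tok!r}"
                    else:
                        continue
                issues.append(
                    ValidationIssue(
                        kind=IssueKind.ROUNDTRIP_MISMATCH,
                        severity=Severity.ERROR,
                        curation_id=str(cid),
                        attribute=attr,
                        observed=f"{term_tok} [{id_tok}]",
                        detail=detail,
                        code=code,
                    )
                )
    return issues


def validate_table(
    table: HarmonizedTable,
    config: HarmonizationConfig,
    graph: OntologyGraph,
) -> list[ValidationIssue]:
    """Run every check the config declares, in a fixed order.

    Order: dynamic enums (schema order), consistency rules, outlier
    bounds, then the table-wide round-trip check.
    """
    issues: list[ValidationIssue] = []
    for spec in config.attributes:
        if spec.enum is not None:
            issues.extend(validate_enum(table, spec.name, spec.enum, graph))
    issues.extend(check_consistency(table, config.consistency_rules))
    for spec in config.attributes:
        if spec.structure == "numeric" and spec.bounds is not None:
            issues.extend(
                detect_outliers(table, spec.name, spec.bounds.low, spec.bounds.high)
            )
    issues.extend(roundtrip_check(table, graph))
    return issues


def _attr_delimiter(table: HarmonizedTable, attr: str) -> str:
    if table.config is not None:
        try:
            return table.config.attribute(attr).delimiter
        except KeyError:
            pass
    return ";"
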