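"""Harmonization engine: execute the merging schema on a raw table.

For every curated attribute the engine gathers its original source
columns left-to-right, recodes missing-data variants to NA, converts
binary presence/absence encodings to descriptive labels, applies the
attribute's curation map token-wise, consolidates granularity through
the ontology, and emits a provenance column family::

    curated_{a}                       harmonized value(s)
    curated_{a}_ontology_term_id      aligned CURIE token(s)
    curated_{a}_source                original column(s) that supplied it
    original_{a}_value                verbatim pre-cleaning content
    curated_{a}_unit                  (numeric attributes only)

plus a per-sample ``curation_id`` key and a run-constant
``last_modified`` timestamp.  Given identical inputs and config the
output is byte-identical apart from that timestamp.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .config import AttributeSpec, BinarySourceSpec, HarmonizationConfig
from .curation import CurationMap, apply_map
from .issues import IssueKind, Severity, ValidationIssue
from .ontology import OntologyGraph
from .util import is_na, join_tokens, norm_token, read_table, split_cell, write_table

__all__ = [
    "SchemaError",
    "HarmonizedTable",
    "HarmonizeResult",
    "normalize_missing",
    "binary_to_descriptive",
    "split_numeric_unit",
    "consolidate_most_specific",
    "make_curation_id",
    "parse_curation_id",
    "build_composite",
    "parse_composite",
    "harmonize_table",
]


class SchemaError(Exception):
    """Schema references that do not resolve against the inputs."""


# ---------------------------------------------------------------- cells


def normalize_missing(cell, na_tokens: Iterable[str]):
    """Recode NA-variant tokens ("NULL", "missing", "-", "999", ...) to NA.

    Comparison is case-insensitive and trimmed; empty/whitespace cells
    are NA; anything else passes through unchanged.
    """
    if is_na(cell):
        return None
    text = str(cell)
    if not text.strip():
        return None
    folded = norm_token(text)
    for tok in na_tokens:
        if folded == norm_token(tok):
            return None
    return text


def binary_to_descriptive(
    column: Sequence,
    positive_tokens: Iterable[str],
    negative_tokens: Iterable[str],
    positive_label: str,
    negative_label: str | None,
    attribute: str = "",
) -> tuple[list, list[ValidationIssue]]:
    """Convert a presence/absence column to descriptive values.

    Positive tokens become ``positive_label``, negative tokens become
    ``negative_label`` (or NA when no negative label is configured, as
    for multi-valued attributes where absence simply contributes
    nothing).  Non-interpretable tokens become NA with a logged issue.
    """
    pos = {norm_token(t) for t in positive_tokens}
    neg = {norm_token(t) for t in negative_tokens}
    out: list = []
    issues: list[ValidationIssue] = []
    for i, cell in enumerate(column):
        if is_na(cell):
            out.append(None)
            continue
        key = norm_token(str(cell))
        if key in pos:
            out.append(positive_label)
        elif key in neg:
            out.append(negative_label)
        else:
            out.append(None)
            issues.append(
                ValidationIssue(
                    kind=IssueKind.NON_INTERPRETABLE,
                    severity=Severity.WARNING,
                    curation_id=f"row:{i}",
                    attribute=attribute,
                    observed=str(cell),
                    detail="binary column token is neither positive nor negative",
                )
            )
    return out, issues


_NUMBER_RE = re.compile(r"[-+]?\d+(?:\.\d+)?")


def split_numeric_unit(cell, default_unit: str) -> tuple[float | None, str | None]:
    """Split "34 years" into (34.0, "years"); bare numbers take the default.

    Only the "." decimal separator is recognized.  Cells with no
    numeric literal yield (NA, NA).
    """
    if is_na(cell):
        return None, None
    text = str(cell).strip()
    m = _NUMBER_RE.search(text)
    if m is None:
        return None, None
    value = float(m.group())
    unit = (text[: m.start()] + " " + text[m.end():]).strip()
    return value, unit if unit else default_unit


def consolidate_most_specific(
    tokens: Sequence[str],
    graph: OntologyGraph,
    curation_id: str = "",
    attribute: str = "",
) -> tuple[str, list[ValidationIssue]]:
    """Pick the most specific term among redundant-granularity CURIEs.

    Ancestors of other tokens are dropped; among the survivors the
    greatest is_a depth wins; depth ties break lexicographically by
    CURIE with a logged tie notice.  Tokens absent from the graph are
    not dropped — they stay candidates (at minimal specificity) and are
    reported.
    """
    issues: list[ValidationIssue] = []
    uniq = list(dict.fromkeys(tokens))
    if not uniq:
        raise ValueError("consolidate_most_specific needs at least one token")
    resolved = [t for t in uniq if t in graph]
    for t in uniq:
        if t not in graph:
            issues.append(
                ValidationIssue(
                    kind=IssueKind.NON_INTERPRETABLE,
                    severity=Severity.WARNING,
                    curation_id=curation_id,
                    attribute=attribute,
                    observed=t,
                    detail="token does not resolve in the ontology",
                )
            )
    # drop any token that is a strict ancestor of another resolved token
    ancestors_of_others: set[str] = set()
    for t in resolved:
        ancestors_of_others |= graph.ancestors(t, include_self=False)
    survivors = [t for t in uniq if t not in ancestors_of_others]
    if not survivors:  # defensive; cannot happen on a DAG
        survivors = uniq

    def depth(tok: str) -> int:
        return graph.term_depth(tok) if tok in graph else -1

    best = max(depth(t) for t in survivors)
    winners = sorted(t for t in survivors if depth(t) == best)
    if len(winners) > 1:
        issues.append(
            ValidationIssue(
                kind=IssueKind.TIE,
                severity=Severity.WARNING,
                curation_id=curation_id,
                attribute=attribute,
                observed=";".join(winners),
                detail=f"equal-depth candidates; kept {winners[0]}",
            )
        )
    return winners[0], issues


# ----------------------------------------------------- curation ids

_ID_SEP = ":"


def _escape_id_part(part: str) -> str:
    return part.replace("%", "%25").replace(_ID_SEP, "%3A")


def _unescape_id_part(part: str) -> str:
    return part.replace("%3A", _ID_SEP).replace("%25", "%")


def make_curation_id(
    study: str, participant: str, sample: str | None = None
) -> str:
    """Compose the unique per-sample key ``study:participant[:sample]``.

    Separator characters inside components are percent-escaped so the
    id parses back unambiguously.
    """
    for name, part in (("study", study), ("participant", participant)):
        if part is None or str(part) == "":
            raise ValueError(f"curation id needs a non-empty {name}")
    parts = [str(study), str(participant)]
    if sample is not None and str(sample) != "":
        parts.append(str(sample))
    return _ID_SEP.join(_escape_id_part(p) for p in parts)


def parse_curation_id(curation_id: str) -> tuple[str, str, str | None]:
    """Inverse of :func:`make_curation_id`."""
    parts = curation_id.split(_ID_SEP)
    if len(parts) not in (2, 3):
        raise ValueError(f"not a curation id: {curation_id!r}")
    study, participant = (_unescape_id_part(p) for p in parts[:2])
    sample = _unescape_id_part(parts[2]) if len(parts) == 3 else None
    return study, participant, sample


def participant_key(curation_id: str) -> str:
    """Participant-level key: the curation id without its sample segment."""
    study, participant, _ = parse_curation_id(curation_id)
    return make_curation_id(study, participant)


# ----------------------------------------------------- composites


def build_composite(
    parts: Mapping[str, object], registry: Sequence[str], delimiter: str = ";"
):
    """Serialize subfield measurements as ``subfield:value`` pairs.

    Pairs are joined by *delimiter* in registry order; NA subfields are
    omitted; an all-NA/empty mapping serializes to NA.  Unregistered
    subfields are a hard error.
    """
    unknown = set(parts) - set(registry)
    if unknown:
        raise SchemaError(f"unregistered composite subfields: {sorted(unknown)}")
    toks = [
        f"{sub}:{str(parts[sub]).strip()}"
        for sub in registry
        if sub in parts and not is_na(parts[sub]) and str(parts[sub]).strip()
    ]
    return join_tokens(toks, delimiter)


def parse_composite(cell, delimiter: str = ";") -> dict[str, str]:
    """Inverse of :func:`build_composite`; NA -> empty dict."""
    out: dict[str, str] = {}
    for tok in split_cell(cell, delimiter):
        if ":" not in tok:
            raise ValueError(f"malformed composite token {tok!r} (expected subfield:value)")
        sub, value = tok.split(":", 1)
        out[sub] = value.strip()
    return out


# ----------------------------------------------------- harmonized table


class HarmonizedTable:
    """A harmonized samples x attributes table plus its schema sidecar.

    Thin wrapper over a pandas DataFrame keyed by ``curation_id``; the
    sidecar carries the per-attribute structure metadata (structure,
    delimiter, subfields) that reshaping and validation need.
    """

    def __init__(self, data: pd.DataFrame, config: HarmonizationConfig | None = None):
        if "curation_id" not in data.columns:
            raise SchemaError("harmonized table must have a curation_id column")
        if data["curation_id"].duplicated().any():
            dupes = data.loc[data["curation_id"].duplicated(), "curation_id"]
            raise SchemaError(f"duplicate curation_id values: {list(dupes[:5])}")
        self.data = data.reset_index(drop=True)
        self.config = config

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "HarmonizedTable":
        return HarmonizedTable(self.data.copy(), self.config)

    def curated_column(self, attribute: str) -> pd.Series:
        col = f"curated_{attribute}"
        if col not in self.data.columns:
            raise KeyError(col)
        return self.data[col]

    def release_view(self) -> pd.DataFrame:
        """Provenance-free view: drops ``original_*`` and ``*_source``."""
        drop = [
            c
            for c in self.data.columns
            if c.startswith("original_") or c.endswith("_source")
        ]
        return self.data.drop(columns=drop)

    # -- persistence (TSV + JSON schema sidecar) ---------------------
    @staticmethod
    def sidecar_path(path: str | Path) -> Path:
        path = Path(path)
        return path.with_name(path.name + ".schema.json")

    def write(self, path: str | Path, sidecar: bool = True) -> None:
        write_table(self.data, path)
        if sidecar and self.config is not None:
            payload = {
                "attributes": [
                    {
                        "name": a.name,
                        "structure": a.structure,
                        "delimiter": a.delimiter,
                        "subfields": a.subfields,
                    }
                    for a in self.config.attributes
                ]
            }
            with open(self.sidecar_path(path), "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def read(cls, path: str | Path) -> "HarmonizedTable":
        from .config import AttributeSpec  # local to avoid confusion at import

        data = read_table(path)
        config = None
        sidecar = cls.sidecar_path(path)
        if sidecar.exists():
            with open(sidecar, encoding="utf-8") as fh:
                payload = json.load(fh)
            attrs = []
            for a in payload.get("attributes", []):
                spec = AttributeSpec(
                    name=a["name"],
                    structure=a["structure"],
                    delimiter=a.get("delimiter", ";"),
                    source_fields=["<unknown>"],
                    subfields=a.get("subfields"),
                    default_unit="" if a["structure"] == "numeric" else None,
                )
                attrs.append(spec)
            config = HarmonizationConfig(attributes=attrs)
        return cls(data, config)


@dataclass
class HarmonizeResult:
    table: HarmonizedTable
    issues: list[ValidationIssue] = field(default_factory=list)


def _fmt_number(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else str(value)


def harmonize_table(
    raw: pd.DataFrame,
    config: HarmonizationConfig,
    maps: Mapping[str, CurationMap] | None = None,
    graph: OntologyGraph | None = None,
    timestamp: str | None = None,
) -> HarmonizeResult:
    """Run the full merging schema over a raw metadata table.

    Deterministic given inputs and config; ``timestamp`` (ISO-8601 UTC)
    may be pinned for reproducible files.  Missing source columns and
    unresolved map references are hard errors.
    """
    maps = maps or {}
    issues: list[ValidationIssue] = []

    id_cols = [config.study_column, config.participant_column]
    if config.sample_column is not None:
        id_cols.append(config.sample_column)
    for col in id_cols:
        if col not in raw.columns:
            raise SchemaError(f"raw table lacks id column {col!r}")
    for spec in config.attributes:
        for f in spec.source_fields:
            if f not in raw.columns:
                raise SchemaError(
                    f"attribute {spec.name!r}: raw table lacks source column {f!r}"
                )
        if spec.map is not None and spec.map not in maps:
            raise SchemaError(
                f"attribute {spec.name!r} references unknown map {spec.map!r}"
            )

    if timestamp is None:
        timestamp = (
            _dt.datetime.now(_dt.timezone.utc).replace(microsecond=0).isoformat()
        )

    out: dict[str, list] = {"curation_id": []}
    for col in id_cols:
        out[col] = list(raw[col].astype(object))
    for _, row in raw.iterrows():
        sample = (
            str(row[config.sample_column])
            if config.sample_column is not None and not is_na(row[config.sample_column])
            else None
        )
        out["curation_id"].append(
            make_curation_id(
                str(row[config.study_column]),
                str(row[config.participant_column]),
                sample,
            )
        )

    for spec in config.attributes:
        cols = _harmonize_attribute(raw, spec, config, maps, graph, out["curation_id"], issues)
        out.update(cols)

    out["last_modified"] = [timestamp] * len(raw)
    table = pd.DataFrame(out, columns=list(out.keys()))
    return HarmonizeResult(HarmonizedTable(table, config), issues)


def _harmonize_attribute(
    raw: pd.DataFrame,
    spec: AttributeSpec,
    config: HarmonizationConfig,
    maps: Mapping[str, CurationMap],
    graph: OntologyGraph | None,
    curation_ids: list[str],
    issues: list[ValidationIssue],
) -> dict[str, list]:
    na_tokens = spec.na_tokens if spec.na_tokens is not None else config.na_tokens
    cmap = maps[spec.map] if spec.map is not None else None
    delim = spec.delimiter

    curated: list = []
    curated_ids: list = []
    sources: list = []
    originals: list = []
    units: list = []

    n = len(raw)
    for i in range(n):
        cid = curation_ids[i]
        # gather per-source cleaned contributions, preserving field order
        contributions: list[tuple[str, str]] = []  # (source field, cleaned value)
        raw_parts: list[str] = []
        for f in spec.source_fields:
            raw_cell = raw[f].iloc[i]
            if not is_na(raw_cell) and str(raw_cell) != "":
                raw_parts.append(str(raw_cell))
            value = normalize_missing(raw_cell, na_tokens)
            if value is None:
                continue
            bspec = spec.binary_sources.get(f)
            if bspec is not None:
                value = _recode_binary(value, bspec, cid, spec.name, issues)
                if value is None:
                    continue
            contributions.append((f, value))

        originals.append(join_tokens(raw_parts, delim))

        if spec.structure == "numeric":
            value_s, unit_s, src = _numeric_value(contributions, spec)
            curated.append(value_s)
            units.append(unit_s)
            curated_ids.append(None)
            sources.append(src)
            continue

        if spec.structure == "composite":
            cell, src = _composite_value(contributions, spec, cmap, delim)
            curated.append(cell)
            curated_ids.append(None)
            sources.append(src)
            continue

        # single / multi: token pipeline through the curation map
        term_tokens: list[str] = []
        id_tokens: list[str] = []
        token_src: list[str] = []
        seen: set[str] = set()
        for f, value in contributions:
            if cmap is not None:
                res = apply_map(value, cmap, delim)
                pair_terms = split_cell(res.curated_value, delim)
                pair_ids = (
                    res.curated_ids.split(delim) if res.curated_ids is not None else []
                )
            else:
                pair_terms = split_cell(value, delim)
                pair_ids = [""] * len(pair_terms)
            for t, tid in zip(pair_terms, pair_ids):
                key = norm_token(t)
                if key in seen:
                    continue
                seen.add(key)
                term_tokens.append(t)
                id_tokens.append(tid)
                token_src.append(f)

        if spec.structure == "single" and len(term_tokens) > 1:
            term_tokens, id_tokens, token_src = _resolve_single(
                term_tokens, id_tokens, token_src, graph, cid, spec.name, issues
            )

        curated.append(join_tokens(term_tokens, delim))
        curated_ids.append(
            join_tokens(id_tokens, delim) if any(id_tokens) else None
        )
        sources.append(join_tokens(list(dict.fromkeys(token_src)), delim))

    out = {
        f"curated_{spec.name}": curated,
        f"curated_{spec.name}_ontology_term_id": curated_ids,
        f"curated_{spec.name}_source": sources,
        f"original_{spec.name}_value": originals,
    }
    if spec.structure == "numeric":
        out[f"curated_{spec.name}_unit"] = units
        del out[f"curated_{spec.name}_ontology_term_id"]
    return out


def _recode_binary(
    value: str,
    bspec: BinarySourceSpec,
    cid: str,
    attribute: str,
    issues: list[ValidationIssue],
) -> str | None:
    key = norm_token(value)
    if key in {norm_token(t) for t in bspec.positive_tokens}:
        return bspec.positive_label
    if key in {norm_token(t) for t in bspec.negative_tokens}:
        return bspec.negative_label
    issues.append(
        ValidationIssue(
            kind=IssueKind.NON_INTERPRETABLE,
            severity=Severity.WARNING,
            curation_id=cid,
            attribute=attribute,
            observed=value,
            detail="binary column token is neither positive nor negative",
        )
    )
    return None


def _numeric_value(
    contributions: list[tuple[str, str]], spec: AttributeSpec
) -> tuple[str | None, str | None, str | None]:
    for f, value in contributions:
        num, unit = split_numeric_unit(value, spec.default_unit or "")
        if num is not None:
            return _fmt_number(num), unit, f
    return None, None, None


def _composite_value(
    contributions: list[tuple[str, str]],
    spec: AttributeSpec,
    cmap: CurationMap | None,
    delim: str,
) -> tuple[str | None, str | None]:
    registry = spec.subfields or []
    parts: dict[str, str] = {}
    srcs: list[str] = []
    for f, value in contributions:
        if cmap is not None:
            res = apply_map(value, cmap, delim)
            if res.curated_value is None:
                continue
            value = res.curated_value
        sub = spec.subfield_name(f)
        if sub in registry:
            parts[sub] = value
        else:
            # source column holding an already-packed composite cell
            try:
                packed = parse_composite(value, delim)
            except ValueError as exc:
                raise SchemaError(
                    f"composite source {f!r} is neither a registered subfield "
                    f"nor a packed composite cell: {exc}"
                ) from exc
            parts.update(packed)
        srcs.append(f)
    cell = build_composite(parts, spec.subfields or [], delim)
    return cell, join_tokens(list(dict.fromkeys(srcs)), delim)


def _resolve_single(
    terms: list[str],
    ids: list[str],
    srcs: list[str],
    graph: OntologyGraph | None,
    cid: str,
    attribute: str,
    issues: list[ValidationIssue],
) -> tuple[list[str], list[str], list[str]]:
    """Pick one value for a single-valued attribute fed by conflicting sources.

    Keep the ontologically most specific candidate when all candidates
    carry resolvable CURIEs; otherwise keep the leftmost (schema-order)
    candidate.  Either way the conflict is logged.
    """
    winner_idx = 0
    used_depth = False
    if graph is not None and all(t and t in graph for t in ids):
        winner_id, _ = consolidate_most_specific(ids, graph, cid, attribute)
        winner_idx = ids.index(winner_id)
        used_depth = True
    issues.append(
        ValidationIssue(
            kind=IssueKind.CONFLICT,
            severity=Severity.WARNING,
            curation_id=cid,
            attribute=attribute,
            observed=";".join(terms),
            detail=(
                "conflicting single-valued sources; kept "
                f"{terms[winner_idx]!r} from {srcs[winner_idx]!r} "
                f"({'most specific' if used_depth else 'leftmost'})"
            ),
        )
    )
    return [terms[winner_idx]], [ids[winner_idx]], [srcs[winner_idx]]
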