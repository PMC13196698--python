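"""Majority-rule resolution of conflicting annotations.

When several samples of one participant disagree on an attribute that
cannot change over time (sex assigned at birth, genetic ancestry), the
modal value wins and overrules the minority; with no unique mode every
member is set to NA; NA members never vote but are filled by a winner,
which is how missing values get inferred from a participant's other
samples.  The resolver refuses attributes not declared time-invariant
— correcting a disease stage or treatment status by consensus across
time points would fabricate data.

Before correcting anything, discrepancies should be triaged for
systematic origin: a single study contributing the bulk of all
discrepancies points at a recording error at the source, which must be
fixed (or the study excluded) before majority correction, lest a
consistent-but-wrong study outvote correct annotations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .config import HarmonizationConfig
from .engine import HarmonizedTable, parse_curation_id, participant_key
from .issues import ValidationIssue
from .util import is_na

__all__ = [
    "ConflictGroup",
    "Resolution",
    "InvariantPolicyError",
    "find_conflicts",
    "majority_resolve",
    "restrict_to_invariant",
    "SystematicErrorReport",
    "systematic_error_report",
    "apply_resolutions",
    "resolve_conflicts",
]


class InvariantPolicyError(Exception):
    """Consensus resolution requested for a non-time-invariant attribute."""


@dataclass
class ConflictGroup:
    """All observations of one attribute for one participant-level key."""

    group_key: str
    attribute: str
    observations: list[tuple[str, str]]
    """(value, curation_id) pairs, NA excluded."""
    na_ids: list[str] = field(default_factory=list)
    """curation_ids of members whose value is NA (inference candidates)."""
    value_ids: dict[str, str] = field(default_factory=dict)
    """value -> ontology id token observed with it (provenance for fills)."""

    @property
    def na_count(self) -> int:
        return len(self.na_ids)

    @property
    def member_ids(self) -> list[str]:
        return [cid for _, cid in self.observations] + list(self.na_ids)


@dataclass
class Resolution:
    """Outcome of majority_resolve for one group."""

    group_key: str
    attribute: str
    value: str | None
    action: Literal["unanimous", "majority-corrected", "inferred", "tie-NA"]
    affected: list[str]
    """curation_ids whose cell changes."""
    value_id: str | None = None
    old_values: dict[str, str | None] = field(default_factory=dict)
    """curation_id -> pre-resolution value, for the provenance note."""


def find_conflicts(
    table: HarmonizedTable,
    attr: str,
    group_key_fields: Sequence[str] | None = None,
) -> list[ConflictGroup]:
    """Group a single-valued attribute by participant and keep the
    groups needing work: >=2 distinct non-NA values, or >=1 value
    alongside >=1 NA (an inference candidate).  Unanimous complete
    groups are excluded.

    ``group_key_fields`` names table columns joined into the group key
    (e.g. ``["participant_id"]`` when the same participant appears
    under several studies); by default the participant-level prefix of
    ``curation_id`` is used.
    """
    if table.config is not None:
        try:
            spec = table.config.attribute(attr)
        except KeyError:
            spec = None
        if spec is not None and spec.structure != "single":
            raise ValueError(
                f"majority resolution is defined for single-valued attributes; "
                f"{attr!r} is {spec.structure!r}"
            )
    col = f"curated_{attr}"
    if col not in table.data.columns:
        raise KeyError(col)
    id_col = f"curated_{attr}_ontology_term_id"
    has_ids = id_col in table.data.columns

    groups: dict[str, ConflictGroup] = {}
    for idx, row in table.data.iterrows():
        cid = str(row["curation_id"])
        if group_key_fields:
            key = ":".join(str(row[f]) for f in group_key_fields)
        else:
            key = participant_key(cid)
        g = groups.setdefault(key, ConflictGroup(key, attr, []))
        cell = row[col]
        if is_na(cell):
            g.na_ids.append(cid)
        else:
            value = str(cell)
            g.observations.append((value, cid))
            if has_ids and not is_na(row[id_col]):
                g.value_ids.setdefault(value, str(row[id_col]))
    out = []
    for g in groups.values():
        distinct = {v for v, _ in g.observations}
        if len(distinct) >= 2 or (len(distinct) >= 1 and g.na_count >= 1):
            out.append(g)
    return out


def majority_resolve(
    group: ConflictGroup, mode: Literal["plurality", "strict"] = "plurality"
) -> Resolution:
    """Resolve one conflict group by majority rule.

    ``plurality`` (default): the unique mode wins — (A,A,B,C) resolves
    to A.  ``strict``: the winner must additionally hold more than half
    of the non-NA votes.  Two or more tied modes (or, in strict mode,
    no absolute majority) set every member to NA.  NA members never
    vote but are filled by a winner.
    """
    counts = Counter(v for v, _ in group.observations)
    if not counts:
        raise ValueError("cannot resolve a group with zero non-NA observations")
    ranked = counts.most_common()
    top_value, top_n = ranked[0]
    tied = [v for v, n in ranked if n == top_n]
    total = sum(counts.values())

    old = {cid: v for v, cid in group.observations}
    old.update({cid: None for cid in group.na_ids})

    no_winner = len(tied) > 1 or (mode == "strict" and top_n * 2 <= total)
    if no_winner:
        affected = [cid for v, cid in group.observations]  # non-NA members -> NA
        return Resolution(
            group_key=group.group_key,
            attribute=group.attribute,
            value=None,
            action="tie-NA",
            affected=affected,
            old_values={cid: old[cid] for cid in affected},
        )

    corrected = [cid for v, cid in group.observations if v != top_value]
    inferred = list(group.na_ids)
    affected = corrected + inferred
    if corrected:
        action = "majority-corrected"
    elif inferred:
        action = "inferred"
    else:
        action = "unanimous"
    return Resolution(
        group_key=group.group_key,
        attribute=group.attribute,
        value=top_value,
        action=action,
        affected=affected,
        value_id=group.value_ids.get(top_value),
        old_values={cid: old[cid] for cid in affected},
    )


def restrict_to_invariant(config: HarmonizationConfig) -> list[str]:
    """Attributes the config declares safe for consensus resolution."""
    return list(config.invariant_attributes)


def _require_invariant(attr: str, config: HarmonizationConfig) -> None:
    allowed = restrict_to_invariant(config)
    if attr not in allowed:
        raise InvariantPolicyError(
            f"attribute {attr!r} is not declared time-invariant "
            f"(allowed: {allowed or 'none'}); consensus across samples is "
            "only valid for attributes that cannot change over time"
        )


@dataclass
class SystematicErrorReport:
    """Per-study discrepancy attribution."""

    counts: dict[str, int]
    total: int
    shares: dict[str, float]
    flagged: list[str]
    threshold: float


def systematic_error_report(
    items: Iterable[ValidationIssue | ConflictGroup],
    study_of: Mapping[str, str] | None = None,
    threshold: float = 0.5,
) -> SystematicErrorReport:
    """Attribute discrepancies to studies and flag suspected systematic ones.

    Each issue counts once, located by its curation_id; each conflict
    group contributes its minority observations (all observations when
    tied).  A study whose share of all discrepancies reaches the
    threshold is flagged as suspected systematic and should be reviewed
    — and excluded from majority correction — before any consensus fix.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")

    def study_for(cid: str) -> str:
        if study_of is not None and cid in study_of:
            return str(study_of[cid])
        return parse_curation_id(cid)[0]

    counts: Counter[str] = Counter()
    for item in items:
        if isinstance(item, ConflictGroup):
            c = Counter(v for v, _ in item.observations)
            if not c:
                continue
            ranked = c.most_common()
            top_n = ranked[0][1]
            tied = [v for v, n in ranked if n == top_n]
            minority = (
                set(c)  # tie: every vote is in dispute
                if len(tied) > 1
                else {v for v in c if v != ranked[0][0]}
            )
            for v, cid in item.observations:
                if v in minority:
                    counts[study_for(cid)] += 1
        else:
            counts[study_for(item.curation_id)] += 1
    total = sum(counts.values())
    shares = {s: n / total for s, n in counts.items()} if total else {}
    flagged = sorted(s for s, share in shares.items() if share >= threshold)
    return SystematicErrorReport(dict(counts), total, shares, flagged, threshold)


def apply_resolutions(
    table: HarmonizedTable, resolutions: Iterable[Resolution]
) -> HarmonizedTable:
    """Write resolutions back into a copy of the table.

    Only cells listed in ``affected`` change; a
    ``curated_{attr}_resolution`` provenance column records the action
    and the pre-resolution value.  Re-applying the same resolutions is
    a no-op; two resolutions disagreeing about one cell are a hard
    error.
    """
    resolutions = list(resolutions)
    seen: dict[tuple[str, str], str | None] = {}
    for r in resolutions:
        for cid in r.affected:
            key = (cid, r.attribute)
            if key in seen and seen[key] != r.value:
                raise ValueError(
                    f"conflicting resolutions for {cid}/{r.attribute}: "
                    f"{seen[key]!r} vs {r.value!r}"
                )
            seen[key] = r.value

    out = table.copy()
    df = out.data
    index_of = {str(cid): i for i, cid in enumerate(df["curation_id"])}
    for r in resolutions:
        col = f"curated_{r.attribute}"
        id_col = f"curated_{r.attribute}_ontology_term_id"
        note_col = f"curated_{r.attribute}_resolution"
        if note_col not in df.columns:
            df[note_col] = None
        for cid in r.affected:
            if cid not in index_of:
                raise KeyError(f"resolution references unknown curation_id {cid}")
            i = index_of[cid]
            df.loc[i, col] = r.value
            if id_col in df.columns:
                df.loc[i, id_col] = r.value_id if r.value is not None else None
            old = r.old_values.get(cid)
            df.loc[i, note_col] = f"{r.action}:was={'NA' if old is None else old}"
    return out


def resolve_conflicts(
    table: HarmonizedTable,
    attr: str,
    config: HarmonizationConfig,
    group_key_fields: Sequence[str] | None = None,
    exclude_studies: Iterable[str] = (),
    mode: Literal["plurality", "strict"] | None = None,
) -> tuple[HarmonizedTable, list[Resolution]]:
    """End-to-end consensus pass: find, resolve and apply.

    Refuses attributes outside the config's invariant list.  Samples
    from ``exclude_studies`` (suspected systematic error sources)
    neither vote nor get corrected.
    """
    _require_invariant(attr, config)
    mode = mode or config.majority_mode
    excluded = set(exclude_studies)
    groups = find_conflicts(table, attr, group_key_fields)
    resolutions: list[Resolution] = []
    for g in groups:
        if excluded:
            g = ConflictGroup(
                g.group_key,
                g.attribute,
                [
                    (v, cid)
                    for v, cid in g.observations
                    if parse_curation_id(cid)[0] not in excluded
                ],
                [cid for cid in g.na_ids if parse_curation_id(cid)[0] not in excluded],
                g.value_ids,
            )
            distinct = {v for v, _ in g.observations}
            if not (len(distinct) >= 2 or (distinct and g.na_count)):
                continue
        r = majority_resolve(g, mode=mode)
        if r.action != "unanimous":
            resolutions.append(r)
    return apply_resolutions(table, resolutions), resolutions
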