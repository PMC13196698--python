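"""Typed, located findings shared by every checker in the toolkit."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["IssueKind", "Severity", "ValidationIssue", "write_issues", "read_issues", "issue_summary"]


class IssueKind(str, Enum):
    OUT_OF_POOL = "out-of-pool"
    INCONSISTENCY = "inconsistency"
    OUTLIER = "outlier"
    ROUNDTRIP_MISMATCH = "roundtrip-mismatch"
    NON_INTERPRETABLE = "non-interpretable"
    CONFLICT = "conflict"
    TIE = "tie"


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class ValidationIssue:
    """One finding: what kind, where, what was seen.

    ``code`` carries a finer-grained label within a kind (e.g. the
    round-trip kinds ``id-not-found``, ``label-mismatch``,
    ``obsolete-target``).  Map-level findings that are not tied to a
    sample use a ``map:<attribute>`` pseudo curation_id.
    """

    kind: IssueKind
    severity: Severity
    curation_id: str
    attribute: str
    observed: str
    detail: str = ""
    code: str = ""

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kind"] = self.kind.value
        d["severity"] = self.severity.value
        return d


def write_issues(issues: Iterable[ValidationIssue], path: str | Path) -> None:
    """Export issues as JSON lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for issue in issues:
            fh.write(json.dumps(issue.to_dict(), sort_keys=True) + "\n")


def read_issues(path: str | Path) -> list[ValidationIssue]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            d["kind"] = IssueKind(d["kind"])
            d["severity"] = Severity(d["severity"])
            out.append(ValidationIssue(**d))
    return out


def issue_summary(issues: Iterable[ValidationIssue]) -> pd.DataFrame:
    """kind x attribute count table (TSV-ready summary)."""
    rows = [(i.kind.value, i.attribute) for i in issues]
    if not rows:
        return pd.DataFrame(columns=["kind", "attribute", "count"])
    df = pd.DataFrame(rows, columns=["kind", "attribute"])
    out = df.value_counts(["kind", "attribute"]).reset_index(name="count")
    return out.sort_values(["kind", "attribute"]).reset_index(drop=True)
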