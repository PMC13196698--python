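"""Harmonization quality metrics and schema/dictionary artifacts.

Four complementary metrics summarize what harmonization did:

* **compression** — how many original columns were merged into each
  curated attribute;
* **consolidation** — the drop in unique values once free text is
  mapped to controlled terms;
* **correction rate** — the fraction of values actually changed by
  curation;
* **completeness** — the fraction of non-NA values per attribute,
  before and after.

The merging-schema table records these before/after statistics per
(original column, curated attribute) pair; the data dictionary
describes the curated attributes themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import HarmonizationConfig
from .engine import HarmonizedTable, SchemaError
from .util import is_na, norm_token, split_cell

__all__ = [
    "AttributeQuality",
    "completeness",
    "unique_values",
    "correction_rate",
    "compression",
    "attribute_quality",
    "build_merging_schema",
    "build_data_dictionary",
]


def completeness(column: Sequence) -> float | None:
    """Fraction of non-NA values; None (undefined) for an empty column."""
    n = len(column)
    if n == 0:
        return None
    return sum(0 if is_na(v) else 1 for v in column) / n


def unique_values(
    column: Sequence, delimiter: str = ";", token_level: bool = True
) -> int:
    """Number of distinct non-NA values.

    ``token_level=True`` splits delimited cells and counts distinct
    tokens (so "a;b" and "b" share the token "b"); otherwise whole
    cells are compared.
    """
    seen: set[str] = set()
    for cell in column:
        if is_na(cell):
            continue
        if token_level:
            seen.update(split_cell(cell, delimiter))
        else:
            seen.add(str(cell))
    return len(seen)


def correction_rate(
    original: Sequence,
    curated: Sequence,
    na_aware: bool = True,
    delimiter: str = ";",
) -> float | None:
    """Fraction of originally present values changed by curation.

    Cells are compared as canonicalized token multisets (trimmed,
    case-folded, order-insensitive), so pure case changes or reordering
    of a multi-valued cell do not count as corrections — the metric
    measures semantic curation.  With ``na_aware`` (default), rows
    whose original value is NA are excluded entirely: filling a blank
    is inference, not correction.  None when no row qualifies.
    """
    if len(original) != len(curated):
        raise ValueError(
            f"column length mismatch: {len(original)} vs {len(curated)}"
        )
    n = 0
    changed = 0
    for o, c in zip(original, curated):
        if is_na(o):
            if na_aware:
                continue
            if is_na(c):
                continue
            n += 1
            changed += 1
            continue
        n += 1
        o_tokens = sorted(norm_token(t) for t in split_cell(o, delimiter))
        c_tokens = sorted(norm_token(t) for t in split_cell(c, delimiter))
        if o_tokens != c_tokens:
            changed += 1
    if n == 0:
        return None
    return changed / n


def compression(config: HarmonizationConfig, curated_field: str) -> int:
    """Number of original columns merged into *curated_field*."""
    spec = config.attribute(curated_field)  # KeyError when unknown
    return len(spec.source_fields)


@dataclass
class AttributeQuality:
    """Per-attribute quality summary."""

    curated_field: str
    n_source_fields: int
    unique_before: int
    unique_after: int
    correction_rate: float | None
    completeness_before: dict[str, float | None]
    completeness_after: float | None

    @property
    def consolidation(self) -> float | None:
        if self.unique_before == 0:
            return None
        return 1 - self.unique_after / self.unique_before


def attribute_quality(
    raw: pd.DataFrame,
    harmonized: HarmonizedTable,
    config: HarmonizationConfig,
    curated_field: str,
) -> AttributeQuality:
    """Compute all four metrics for one curated attribute."""
    spec = config.attribute(curated_field)
    for f in spec.source_fields:
        if f not in raw.columns:
            raise SchemaError(f"raw table lacks source column {f!r}")
    cur_col = harmonized.curated_column(curated_field)
    orig_col = harmonized.data.get(f"original_{curated_field}_value")
    before_tokens: set[str] = set()
    completeness_before: dict[str, float | None] = {}
    for f in spec.source_fields:
        completeness_before[f] = completeness(raw[f])
        for cell in raw[f]:
            before_tokens.update(split_cell(cell, spec.delimiter))
    rate = (
        correction_rate(list(orig_col), list(cur_col), delimiter=spec.delimiter)
        if orig_col is not None
        else None
    )
    return AttributeQuality(
        curated_field=curated_field,
        n_source_fields=len(spec.source_fields),
        unique_before=len(before_tokens),
        unique_after=unique_values(cur_col, spec.delimiter, token_level=True),
        correction_rate=rate,
        completeness_before=completeness_before,
        completeness_after=completeness(cur_col),
    )


def _fmt_fraction(x: float | None) -> str:
    return "" if x is None else f"{x:.4f}"


def build_merging_schema(
    raw: pd.DataFrame,
    harmonized: HarmonizedTable,
    config: HarmonizationConfig,
) -> pd.DataFrame:
    """Six-column before/after summary of the attribute consolidation.

    One row per (original column, curated attribute) pair, ordered by
    curated then original name; completeness and unique-value counts
    are computed per side by the metric functions above.  Row order of
    the input tables does not affect the result.
    """
    rows = []
    for spec in sorted(config.attributes, key=lambda s: s.name):
        for f in sorted(spec.source_fields):
            if f not in raw.columns:
                raise SchemaError(f"raw table lacks source column {f!r}")
            cur_col = harmonized.curated_column(spec.name)
            rows.append(
                {
                    "original_field": f,
                    "original_field_completeness": _fmt_fraction(
                        completeness(raw[f])
                    ),
                    "original_field_unique_values": unique_values(
                        raw[f], spec.delimiter
                    ),
                    "curated_field": spec.name,
                    "curated_field_completeness": _fmt_fraction(
                        completeness(cur_col)
                    ),
                    "curated_field_unique_values": unique_values(
                        cur_col, spec.delimiter
                    ),
                }
            )
    columns = [
        "original_field",
        "original_field_completeness",
        "original_field_unique_values",
        "curated_field",
        "curated_field_completeness",
        "curated_field_unique_values",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return df.sort_values(["curated_field", "original_field"]).reset_index(drop=True)


def build_data_dictionary(
    config: HarmonizationConfig, mode: str = "release"
) -> pd.DataFrame:
    """Describe the curated attributes for curators or end users.

    ``release`` mode emits one row per attribute with composites in
    their grouped form; ``curation`` mode splits each composite into
    one row per subfield to ease detailed editing.
    """
    if mode not in ("curation", "release"):
        raise ValueError(f"mode must be 'curation' or 'release', got {mode!r}")
    rows = []
    for spec in config.attributes:
        base = {
            "attribute": spec.name,
            "structure": spec.structure,
            "delimiter": spec.delimiter,
            "enum_nodes": ";".join(spec.enum.nodes) if spec.enum else "",
            "allowed_values": (
                f"descendants of {';'.join(spec.enum.nodes)}" if spec.enum else ""
            ),
            "details_attribute": spec.details_attribute or "",
            "unit": spec.default_unit or "",
        }
        if mode == "curation" and spec.structure == "composite":
            for sub in spec.subfields or []:
                row = dict(base)
                row["attribute"] = f"{spec.name}.{sub}"
                row["structure"] = "composite-subfield"
                rows.append(row)
        else:
            rows.append(base)
    columns = [
        "attribute",
        "structure",
        "delimiter",
        "enum_nodes",
        "allowed_values",
        "details_attribute",
        "unit",
    ]
    return pd.DataFrame(rows, columns=columns)
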