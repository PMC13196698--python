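"""Declarative harmonization config: merging schema, enums, rules, bounds.

The config is the machine-readable product of exploratory schema work:
it declares, per curated attribute, which original columns feed it, its
value structure (single / multi / composite / numeric), the curation
map and dynamic enum that govern its values, plus table-wide settings
(id columns, NA token set, consistency rules, outlier bounds, the
invariant-attribute list for conflict resolution).  Serialized as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "DEFAULT_NA_TOKENS",
    "BinarySourceSpec",
    "EnumSpec",
    "BoundsSpec",
    "ConsistencyRuleSpec",
    "AttributeSpec",
    "HarmonizationConfig",
    "ConfigError",
]

#: Default tokens recoded to NA.  "unknown" is deliberately absent:
#: attributes like vital status use "Unknown" as a legal category, so
#: recoding it must be an explicit per-attribute opt-in.
DEFAULT_NA_TOKENS = [
    "",
    "na",
    "n/a",
    "nan",
    "null",
    "missing",
    "-",
    "999",
    "not available",
    "not provided",
    "not collected",
]


class ConfigError(Exception):
    """Invalid or internally inconsistent harmonization config."""


class BinarySourceSpec(BaseModel):
    """Presence/absence recoding for one binary-encoded source column."""

    positive_label: str
    negative_label: Optional[str] = None
    positive_tokens: list[str] = ["yes", "y", "true", "1", "present"]
    negative_tokens: list[str] = ["no", "n", "false", "0", "absent"]


class EnumSpec(BaseModel):
    """Dynamic enumeration: allowed values = descendants of the nodes."""

    nodes: list[str] = Field(min_length=1)
    include_nodes: bool = False
    allow_combinations: bool = True


class BoundsSpec(BaseModel):
    """Closed plausibility interval for a numeric attribute."""

    low: float
    high: float

    @model_validator(mode="after")
    def _ordered(self) -> "BoundsSpec":
        if self.low > self.high:
            raise ValueError(f"bounds reversed: low={self.low} > high={self.high}")
        return self


class ConsistencyRuleSpec(BaseModel):
    """Propositional cross-attribute impossibility.

    Reads: when ``if_attribute`` takes a value in ``if_values``, then
    ``then_attribute`` must not take a value in ``forbidden_values``
    (e.g. sex "Female" forbids disease "Prostate Carcinoma").
    """

    name: str
    if_attribute: str
    if_values: list[str] = Field(min_length=1)
    then_attribute: str
    forbidden_values: list[str] = Field(min_length=1)


class AttributeSpec(BaseModel):
    """How one curated attribute is assembled from original columns."""

    name: str
    structure: Literal["single", "multi", "composite", "numeric"]
    source_fields: list[str] = Field(min_length=1)
    delimiter: str = ";"
    map: Optional[str] = None
    details_attribute: Optional[str] = None
    enum: Optional[EnumSpec] = None
    default_unit: Optional[str] = None
    bounds: Optional[BoundsSpec] = None
    subfields: Optional[list[str]] = None
    subfield_of: dict[str, str] = Field(default_factory=dict)
    """Source column -> composite subfield name (defaults to the column name)."""
    binary_sources: dict[str, BinarySourceSpec] = Field(default_factory=dict)
    na_tokens: Optional[list[str]] = None
    """Per-attribute override of the table-wide NA token set."""

    @model_validator(mode="after")
    def _structure_requirements(self) -> "AttributeSpec":
        if self.structure == "numeric" and self.default_unit is None:
            raise ValueError(
                f"numeric attribute {self.name!r} requires default_unit "
                "(its unit column is curated_{name}_unit)"
            )
        if self.structure == "composite" and self.subfields is None:
            self.subfields = [
                self.subfield_of.get(f, f) for f in self.source_fields
            ]
        return self

    @property
    def unit_attribute(self) -> Optional[str]:
        return f"{self.name}_unit" if self.structure == "numeric" else None

    def subfield_name(self, source_field: str) -> str:
        return self.subfield_of.get(source_field, source_field)


class HarmonizationConfig(BaseModel):
    """Top-level config: id columns, schema, rules, thresholds."""

    study_column: str = "study_name"
    participant_column: str = "participant_id"
    sample_column: Optional[str] = "sample_id"
    na_tokens: list[str] = Field(default_factory=lambda: list(DEFAULT_NA_TOKENS))
    delimiter: str = ";"
    attributes: list[AttributeSpec] = Field(default_factory=list)
    consistency_rules: list[ConsistencyRuleSpec] = Field(default_factory=list)
    invariant_attributes: list[str] = Field(default_factory=list)
    systematic_share_threshold: float = 0.5
    majority_mode: Literal["plurality", "strict"] = "plurality"
    maps: dict[str, str] = Field(default_factory=dict)
    """Map name -> TSV path (relative paths resolve against the config file)."""
    ontologies: list[str] = Field(default_factory=list)
    """OBO paths (relative paths resolve against the config file)."""

    @field_validator("systematic_share_threshold")
    @classmethod
    def _threshold_range(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("systematic_share_threshold must lie in (0, 1]")
        return v

    @model_validator(mode="after")
    def _unique_names(self) -> "HarmonizationConfig":
        names = [a.name for a in self.attributes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate curated attribute names: {sorted(dupes)}")
        known = set(names)
        for rule in self.consistency_rules:
            for attr in (rule.if_attribute, rule.then_attribute):
                if attr not in known:
                    raise ValueError(
                        f"rule {rule.name!r} references unknown attribute {attr!r}"
                    )
        for a in self.attributes:
            if a.map is not None and a.map not in self.maps:
                raise ValueError(
                    f"attribute {a.name!r} references undeclared map {a.map!r}"
                )
        return self

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise KeyError(name)

    # -- (de)serialization -------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "HarmonizationConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        try:
            cfg = cls.model_validate(payload)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc
        # resolve relative resource paths against the config location
        base = path.parent
        cfg.maps = {k: str((base / v) if not Path(v).is_absolute() else Path(v))
                    for k, v in cfg.maps.items()}
        cfg.ontologies = [
            str((base / v) if not Path(v).is_absolute() else Path(v))
            for v in cfg.ontologies
        ]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                self.model_dump(exclude_none=True), fh, sort_keys=False
            )
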