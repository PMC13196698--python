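"""Synthetic fixtures: toy ontologies and deliberately corrupted
multi-study metadata with exhaustive ground truth.

The generator emulates the pathologies of real multi-study sample
metadata — typos, curator abbreviations and drug brand names, values
filed under the wrong attribute, mixed NA encodings, binary
presence/absence columns, information dispersed across redundant
sparse source columns, per-participant conflicting annotations of
time-invariant attributes, and study-level systematic flips — while
recording every corruption in an injection log, so each pipeline stage
can be scored against known truth without any external downloads.

All randomness flows from one seed, split into per-corruption-kind
sub-streams, so changing one rate never reshuffles the corruptions of
another kind.  Generated CURIEs use the reserved ``TOY:`` prefix and
can never be mistaken for real ontology terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .config import (
    AttributeSpec,
    BinarySourceSpec,
    BoundsSpec,
    ConsistencyRuleSpec,
    EnumSpec,
    HarmonizationConfig,
)
from .curation import CurationMap, CurationMapEntry
from .engine import HarmonizedTable, make_curation_id
from .issues import IssueKind, ValidationIssue
from .ontology import OntologyGraph, Term
from .util import is_na, join_tokens, split_cell, write_table

__all__ = [
    "ToyOntology",
    "make_toy_ontology",
    "CorruptionProfile",
    "SystematicStudySpec",
    "InjectionRecord",
    "InjectionLog",
    "FixtureBundle",
    "make_messy_metadata",
    "inject_roundtrip_errors",
    "DetectionScore",
    "evaluate_detection",
    "write_fixtures",
]

# --------------------------------------------------------------- ontology

ROOT = "TOY:0000001"
ANCESTRY_NODE = "TOY:0000010"
SEX_NODE = "TOY:0000030"
DISEASE_NODE = "TOY:0000040"
TREATMENT_NODE = "TOY:0000060"
SAMPLE_TYPE_NODE = "TOY:0000100"
FILLER_NODE = "TOY:0000200"
OBSOLETE_TERM = "TOY:0000150"

#: Backbone stanzas in topological order: (curie, label, parents, synonyms).
_BACKBONE: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
    (ROOT, "metadata entity", (), ()),
    # ancestry branch: one category node with exactly eight children
    (ANCESTRY_NODE, "ancestry category", (ROOT,), ()),
    ("TOY:0000011", "European", (ANCESTRY_NODE,), ()),
    ("TOY:0000012", "African", (ANCESTRY_NODE,), ()),
    ("TOY:0000013", "East Asian", (ANCESTRY_NODE,), ()),
    ("TOY:0000014", "South Asian", (ANCESTRY_NODE,), ()),
    ("TOY:0000015", "Latin American", (ANCESTRY_NODE,), ()),
    ("TOY:0000016", "Oceanian", (ANCESTRY_NODE,), ()),
    ("TOY:0000017", "Middle Eastern", (ANCESTRY_NODE,), ()),
    ("TOY:0000018", "Native American", (ANCESTRY_NODE,), ()),
    ("TOY:0000019", "Northern European", ("TOY:0000011",), ()),
    ("TOY:0000020", "Southern European", ("TOY:0000011",), ()),
    # sex branch
    (SEX_NODE, "biological sex", (ROOT,), ()),
    ("TOY:0000031", "Male", (SEX_NODE,), ()),
    ("TOY:0000032", "Female", (SEX_NODE,), ()),
    # disease branch with two sex-linked leaves
    (DISEASE_NODE, "disease", (ROOT,), ()),
    ("TOY:0000041", "Prostate Carcinoma", (DISEASE_NODE,), ()),
    ("TOY:0000042", "Ovarian Carcinoma", (DISEASE_NODE,), ()),
    ("TOY:0000043", "Colorectal Carcinoma", (DISEASE_NODE,), ()),
    ("TOY:0000044", "Type 2 Diabetes Mellitus", (DISEASE_NODE,), ()),
    ("TOY:0000045", "Adenoma", (DISEASE_NODE,), ()),
    ("TOY:0000046", "Crohn Disease", (DISEASE_NODE,), ()),
    # treatment branch (drug classes and compounds)
    (TREATMENT_NODE, "pharmacologic substance", (ROOT,), ()),
    ("TOY:0000061", "Metformin", (TREATMENT_NODE,), ("Glucophage",)),
    ("TOY:0000062", "Sitagliptin", (TREATMENT_NODE,), ()),
    ("TOY:0000063", "Insulin", (TREATMENT_NODE,), ()),
    ("TOY:0000064", "Insulin Glargine", ("TOY:0000063",), ()),
    ("TOY:0000065", "Insulin Aspart", ("TOY:0000063",), ()),
    ("TOY:0000066", "Aspirin", (TREATMENT_NODE,), ("acetylsalicylic acid",)),
    ("TOY:0000067", "statin", (TREATMENT_NODE,), ()),
    ("TOY:0000068", "Clopidogrel", (TREATMENT_NODE,), ()),
    ("TOY:0000069", "Antilipidemic Agent", (TREATMENT_NODE,), ()),
    ("TOY:0000070", "Antihypertensive Agents", (TREATMENT_NODE,), ()),
    ("TOY:0000071", "Anti-diabetic Agent", (TREATMENT_NODE,), ()),
    ("TOY:0000072", "Diuretic", (TREATMENT_NODE,), ()),
    (
        "TOY:0000073",
        "Angiotensin-Converting Enzyme Inhibitors",
        (TREATMENT_NODE,),
        (),
    ),
    ("TOY:0000074", "Beta-Adrenergic Antagonist", (TREATMENT_NODE,), ()),
    ("TOY:0000075", "Calcium Channel Blocker", (TREATMENT_NODE,), ()),
    (
        "TOY:0000076",
        "glucagon-like peptide-1 receptor agonist",
        (TREATMENT_NODE,),
        (),
    ),
    ("TOY:0000077", "Dipeptidyl-Peptidase IV Inhibitors", (TREATMENT_NODE,), ()),
    ("TOY:0000078", "Nitrate", (TREATMENT_NODE,), ()),
    ("TOY:0000079", "Proton Pump Inhibitor", (TREATMENT_NODE,), ()),
    ("TOY:0000080", "Xanthine Oxidase Inhibitor", (TREATMENT_NODE,), ()),
    # sample-type branch: Neoplasm subsumes three specific types
    (SAMPLE_TYPE_NODE, "sample type", (ROOT,), ()),
    ("TOY:0000101", "Neoplasm", (SAMPLE_TYPE_NODE,), ("tumor sample",)),
    ("TOY:0000102", "Primary Neoplasm", ("TOY:0000101",), ()),
    ("TOY:0000103", "Metastatic Neoplasm", ("TOY:0000101",), ()),
    ("TOY:0000104", "Recurrent Neoplasm", ("TOY:0000101",), ()),
    ("TOY:0000105", "Normal Tissue Sample", (SAMPLE_TYPE_NODE,), ()),
    # one obsolete stanza and the filler root
    (OBSOLETE_TERM, "deprecated term", (), ()),
    (FILLER_NODE, "filler category", (ROOT,), ()),
]


@dataclass
class ToyOntology:
    """A toy ontology plus the branch handles the generator relies on."""

    graph: OntologyGraph
    branch_nodes: dict[str, str]
    label_to_curie: dict[str, str]

    def curie_of(self, label: str) -> str:
        return self.label_to_curie[label]


def make_toy_ontology(
    seed: int,
    n_terms: int = 120,
    max_parents: int = 2,
    synonym_rate: float = 0.15,
    obo_path: str | Path | None = None,
) -> ToyOntology:
    """Build a deterministic rooted DAG with the designated branches.

    The backbone (ancestry category with exactly eight children, a
    treatment branch, a disease branch with sex-linked leaves, a
    sample-type branch where "Neoplasm" subsumes the specific types)
    is fixed; remaining terms up to ``n_terms`` are random filler under
    a separate branch, with up to ``max_parents`` parents each and
    synonyms at ``synonym_rate``.  Identical seeds yield byte-identical
    OBO output.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    backbone = _BACKBONE[:n_terms]
    if len(_BACKBONE) > n_terms:
        warnings.warn(
            f"n_terms={n_terms} is below the backbone size "
            f"({len(_BACKBONE)}); designated branches will be incomplete",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(99,)))
    terms: list[Term] = []
    present = {c for c, *_ in backbone}
    for curie, label, parents, synonyms in backbone:
        parents = tuple(p for p in parents if p in present)
        terms.append(
            Term(
                curie=curie,
                label=label,
                synonyms=frozenset(synonyms),
                parents=frozenset(parents),
                obsolete=curie == OBSOLETE_TERM,
            )
        )
    filler_pool = [FILLER_NODE] if FILLER_NODE in present else []
    for i in range(len(backbone), n_terms):
        curie = f"TOY:{200 + i - len(backbone) + 1:07d}"
        if filler_pool:
            k = int(rng.integers(1, max_parents + 1))
            k = min(k, len(filler_pool))
            idx = rng.choice(len(filler_pool), size=k, replace=False)
            parents = frozenset(filler_pool[j] for j in sorted(idx))
        else:
            parents = frozenset()
        synonyms = frozenset(
            [f"synthetic synonym {i}"] if rng.random() < synonym_rate else []
        )
        terms.append(
            Term(
                curie=curie,
                label=f"synthetic term {i}",
                synonyms=synonyms,
                parents=parents,
            )
        )
        filler_pool.append(curie)
    graph = OntologyGraph(terms)
    onto = ToyOntology(
        graph=graph,
        branch_nodes={
            "root": ROOT,
            "ancestry": ANCESTRY_NODE,
            "sex": SEX_NODE,
            "disease": DISEASE_NODE,
            "treatment": TREATMENT_NODE,
            "sample_type": SAMPLE_TYPE_NODE,
            "filler": FILLER_NODE,
        },
        label_to_curie={t.label: t.curie for t in terms if not t.obsolete},
    )
    if obo_path is not None:
        graph.write_obo(obo_path)
    return onto


# --------------------------------------------------------------- profile


class SystematicStudySpec(BaseModel):
    """Study-level systematic corruption: flip one attribute everywhere."""

    study_index: int
    attribute: str = "sex"
    flip_all: bool = True


class CorruptionProfile(BaseModel):
    """Study conditions for one synthetic-fixture run.

    The defaults describe a messy-but-recoverable multi-study
    collection: a handful of studies, a few samples per participant,
    heavy use of abbreviations, occasional typos and misfiled values,
    mixed NA encodings, and a 20% per-sample flip rate on the
    time-invariant sex attribute.
    """

    seed: int = 0
    n_studies: int = 4
    n_participants: int = 200
    samples_per_participant: tuple[int, int] = (3, 5)
    typo_rate: float = Field(0.05, ge=0, le=1)
    abbreviation_rate: float = Field(0.3, ge=0, le=1)
    misplacement_rate: float = Field(0.02, ge=0, le=1)
    na_variant_rate: float = Field(0.3, ge=0, le=1)
    conflict_rate: float = Field(0.2, ge=0, le=1)
    missing_rate: float = Field(0.05, ge=0, le=1)
    """Per-sample chance that the invariant sex annotation is absent,
    making it a candidate for inference by consensus."""
    binary_encode_rate: float = Field(0.3, ge=0, le=1)
    outlier_rate: float = Field(0.01, ge=0, le=1)
    inconsistency_rate: float = Field(0.02, ge=0, le=1)
    cross_study_rate: float = Field(0.0, ge=0, le=1)
    na_tokens: list[str] = ["NULL", "missing", "-", "999"]
    systematic_study: Optional[SystematicStudySpec] = None
    disperse: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorruptionProfile":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


InjectionKind = Literal[
    "typo",
    "abbreviation",
    "misplaced",
    "na-variant",
    "missing",
    "conflict-flip",
    "binary-encoding",
    "systematic-flip",
    "inconsistency",
    "outlier",
    "roundtrip",
]


@dataclass(frozen=True)
class InjectionRecord:
    curation_id: str
    attribute: str
    kind: InjectionKind
    original: str
    corrupted: str


@dataclass
class InjectionLog:
    """Exhaustive record of every injected clean/messy difference."""

    records: list[InjectionRecord] = field(default_factory=list)

    def add(self, cid: str, attr: str, kind: InjectionKind, orig, corr) -> None:
        self.records.append(
            InjectionRecord(cid, attr, kind, "" if orig is None else str(orig),
                            "" if corr is None else str(corr))
        )

    def by_kind(self, kind: InjectionKind) -> list[InjectionRecord]:
        return [r for r in self.records if r.kind == kind]

    def coordinates(self, kinds: Iterable[InjectionKind]) -> set[tuple[str, str, str]]:
        ks = set(kinds)
        return {
            (r.curation_id, r.attribute, r.kind)
            for r in self.records
            if r.kind in ks
        }

    def __len__(self) -> int:
        return len(self.records)


# ------------------------------------------------------- vocabulary maps

#: Curator-style abbreviations inverted by the emitted curation maps.
ABBREVIATIONS: dict[str, str] = {
    "Male": "M",
    "Female": "F",
    "European": "EUR",
    "African": "AFR",
    "East Asian": "EAS",
    "South Asian": "SAS",
    "Latin American": "AMR",
    "Oceanian": "OCE",
    "Middle Eastern": "MDE",
    "Native American": "NAM",
    "Prostate Carcinoma": "prostate_ca",
    "Ovarian Carcinoma": "ovarian_ca",
    "Colorectal Carcinoma": "crc",
    "Type 2 Diabetes Mellitus": "t2d",
    "Crohn Disease": "crohns",
    "Metformin": "metf",
    "Sitagliptin": "sita",
    "Aspirin": "asa",
    "Clopidogrel": "clopi",
    "Diuretic": "diur",
    "Nitrate": "nitr",
    "Primary Neoplasm": "primary",
    "Metastatic Neoplasm": "mets",
    "Recurrent Neoplasm": "recurrent",
    "Normal Tissue Sample": "normal",
    "Neoplasm": "tumor",
}

#: Brand names entered separately in the wild, consolidating to one generic.
BRAND_NAMES: dict[str, tuple[str, ...]] = {
    "Insulin Glargine": ("lantus", "solostar"),
    "Insulin Aspart": ("novorapid",),
}

_ANCESTRIES = [
    "European",
    "African",
    "East Asian",
    "South Asian",
    "Latin American",
    "Oceanian",
    "Middle Eastern",
    "Native American",
]
_SEXES = ["Male", "Female"]
_SEX_LINKED = {"Male": "Prostate Carcinoma", "Female": "Ovarian Carcinoma"}
_NEUTRAL_DISEASES = [
    "Colorectal Carcinoma",
    "Type 2 Diabetes Mellitus",
    "Adenoma",
    "Crohn Disease",
]
_DRUGS = [
    "Aspirin",
    "Clopidogrel",
    "Diuretic",
    "Insulin Aspart",
    "Insulin Glargine",
    "Metformin",
    "Nitrate",
    "Sitagliptin",
    "statin",
]
_SAMPLE_TYPES = [
    "Primary Neoplasm",
    "Metastatic Neoplasm",
    "Recurrent Neoplasm",
    "Neoplasm",
    "Normal Tissue Sample",
]
_SAMPLE_TYPE_P = [0.45, 0.2, 0.1, 0.05, 0.2]
_BIOMARKER_SUBFIELDS = ["CRP", "IL6", "TNF"]

_ATTR_VOCAB = {
    "sex": _SEXES,
    "ancestry": _ANCESTRIES,
    "disease": list(_SEX_LINKED.values()) + _NEUTRAL_DISEASES,
    "treatment": _DRUGS + [d for d in ABBREVIATIONS if d in _DRUGS],
    "sample_type": _SAMPLE_TYPES,
}

_DISPERSAL = {
    "sex": ["sex", "gender"],
    "ancestry": ["ancestry", "ethnicity"],
    "disease": ["disease", "study_condition"],
    "treatment": ["treatment", "medication", "drugs"],
    "sample_type": ["sample_type", "specimen_type"],
    "age": ["age", "age_years"],
}
_BINARY_DRUGS = {"metformin": "Metformin", "aspirin_use": "Aspirin"}


def _stream(seed: int, key: int) -> np.random.Generator:
    """Per-corruption-kind substream of the run's master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class FixtureBundle:
    """Everything one synthetic run produces."""

    clean: pd.DataFrame
    messy: pd.DataFrame
    maps: dict[str, CurationMap]
    config: HarmonizationConfig
    log: InjectionLog
    ontology: ToyOntology


def _make_clean(profile: CorruptionProfile) -> pd.DataFrame:
    rng_struct = _stream(profile.seed, 0)
    rng_val = _stream(profile.seed, 1)
    lo, hi = profile.samples_per_participant
    # a study under systematic suspicion is modelled as an aggregator that
    # re-files samples of participants homed elsewhere, mirroring the
    # same-patient-in-several-studies situation that exposes such errors
    home_choices = list(range(profile.n_studies))
    if profile.systematic_study is not None and profile.n_studies > 1:
        home_choices = [
            s for s in home_choices if s != profile.systematic_study.study_index
        ]
    rows = []
    for p in range(profile.n_participants):
        pid = f"P{p:04d}"
        home = home_choices[p % len(home_choices)]
        sex = _SEXES[int(rng_val.integers(2))]
        n_anc = 1 if rng_val.random() < 0.8 else 2
        anc_idx = sorted(rng_val.choice(len(_ANCESTRIES), size=n_anc, replace=False))
        ancestry = ";".join(_ANCESTRIES[i] for i in anc_idx)
        if rng_val.random() < 0.2:
            disease = _SEX_LINKED[sex]
        else:
            disease = _NEUTRAL_DISEASES[int(rng_val.integers(len(_NEUTRAL_DISEASES)))]
        age = int(rng_val.integers(18, 91))
        k = int(rng_struct.integers(lo, hi + 1))
        for j in range(k):
            study_idx = home
            if profile.cross_study_rate and rng_struct.random() < profile.cross_study_rate:
                study_idx = (home + 1 + int(rng_struct.integers(profile.n_studies - 1))) % profile.n_studies
            study = f"study_{study_idx:02d}"
            if rng_val.random() < 0.9:
                n_drugs = int(rng_val.integers(1, 4))
                drug_idx = sorted(rng_val.choice(len(_DRUGS), size=n_drugs, replace=False))
                treatment = ";".join(_DRUGS[i] for i in drug_idx)
            else:
                treatment = None
            stype = rng_val.choice(_SAMPLE_TYPES, p=_SAMPLE_TYPE_P)
            bm_parts = []
            for sub in _BIOMARKER_SUBFIELDS:
                if rng_val.random() < 0.4:
                    bm_parts.append(f"{sub}:{rng_val.uniform(0.5, 50):.1f}")
            rows.append(
                {
                    "study_name": study,
                    "participant_id": pid,
                    "sample_id": f"S{j + 1:02d}",
                    "sex": sex,
                    "ancestry": ancestry,
                    "disease": disease,
                    "treatment": treatment,
                    "sample_type": str(stype),
                    "age": str(age),
                    "biomarker": join_tokens(bm_parts) if bm_parts else None,
                }
            )
    return pd.DataFrame(rows)


def _make_typo(token: str, rng: np.random.Generator, forbidden: set[str]) -> str:
    """Single-character edit that collides with no known token."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(100):
        pos = int(rng.integers(len(token)))
        op = int(rng.integers(3))
        if op == 0 and len(token) > 2:  # delete
            cand = token[:pos] + token[pos + 1:]
        elif op == 1:  # insert
            cand = token[:pos] + letters[int(rng.integers(26))] + token[pos:]
        else:  # substitute
            cand = token[:pos] + letters[int(rng.integers(26))] + token[pos + 1:]
        if cand.casefold() != token.casefold() and cand.casefold() not in forbidden:
            return cand
    raise RuntimeError(f"could not generate a collision-free typo for {token!r}")


def make_messy_metadata(
    profile: CorruptionProfile, onto: ToyOntology
) -> FixtureBundle:
    """Generate the clean table, its corrupted counterpart, the inverse
    curation maps, the harmonization config and the injection log.

    Corruption kinds are applied in a fixed order, at most one per
    cell, so the log stays unambiguous; the emitted maps invert every
    typo, abbreviation and brand name, which makes the clean values
    recoverable wherever a map inverse exists.
    """
    if profile.conflict_rate >= 0.5:
        warnings.warn(
            f"conflict_rate={profile.conflict_rate} >= 0.5: majority recovery "
            "is not expected to succeed",
            stacklevel=2,
        )
    clean = _make_clean(profile)
    log = InjectionLog()

    rng_typo = _stream(profile.seed, 2)
    rng_abbr = _stream(profile.seed, 3)
    rng_misp = _stream(profile.seed, 4)
    rng_nav = _stream(profile.seed, 5)
    rng_conf = _stream(profile.seed, 6)
    rng_bin = _stream(profile.seed, 7)
    rng_out = _stream(profile.seed, 8)
    rng_inco = _stream(profile.seed, 9)
    rng_disp = _stream(profile.seed, 11)

    cids = [
        make_curation_id(r.study_name, r.participant_id, r.sample_id)
        for r in clean.itertuples(index=False)
    ]

    # working copy of attribute values, corrupted in place before dispersal
    work = clean.copy()
    corrupted_cells: set[tuple[int, str]] = set()  # at-most-one-corruption guard
    typo_entries: dict[str, dict[str, str]] = {a: {} for a in _ATTR_VOCAB}
    forbidden = {v.casefold() for vocab in _ATTR_VOCAB.values() for v in vocab}
    forbidden |= {a.casefold() for a in ABBREVIATIONS.values()}
    forbidden |= {b.casefold() for brands in BRAND_NAMES.values() for b in brands}

    participants = clean.groupby("participant_id", sort=False).indices

    # 1. systematic study-level flip (recording error at the source)
    sys_spec = profile.systematic_study
    if sys_spec is not None:
        sys_study = f"study_{sys_spec.study_index:02d}"
        attr = sys_spec.attribute
        for i in range(len(work)):
            if work.at[i, "study_name"] != sys_study:
                continue
            old = work.at[i, attr]
            if is_na(old):
                continue
            if attr == "sex":
                new = "Female" if old == "Male" else "Male"
            else:
                vocab = [v for v in _ATTR_VOCAB[attr] if v != old]
                new = vocab[0]
            work.at[i, attr] = new
            corrupted_cells.add((i, attr))
            log.add(cids[i], attr, "systematic-flip", old, new)

    # 2. random conflict flips on the invariant sex attribute; participants
    #    with sex-linked diseases are exempt so a flip can never fabricate a
    #    cross-attribute impossibility
    flipped_participants: set[str] = set()
    for pid, idxs in participants.items():
        if clean.loc[idxs[0], "disease"] in _SEX_LINKED.values():
            rng_conf.random(len(idxs))  # keep the stream aligned
            continue
        draws = rng_conf.random(len(idxs))
        for i, u in zip(idxs, draws):
            if u >= profile.conflict_rate or (i, "sex") in corrupted_cells:
                continue
            old = work.at[i, "sex"]
            new = "Female" if old == "Male" else "Male"
            work.at[i, "sex"] = new
            corrupted_cells.add((i, "sex"))
            flipped_participants.add(pid)
            log.add(cids[i], "sex", "conflict-flip", old, new)

    # 2b. dropped annotations of the invariant attribute: these become
    #     inference candidates for the consensus pass
    rng_miss = _stream(profile.seed, 12)
    missing_participants: set[str] = set()
    for pid, idxs in participants.items():
        draws = rng_miss.random(len(idxs))
        for i, u in zip(idxs, draws):
            if u >= profile.missing_rate or (i, "sex") in corrupted_cells:
                continue
            old = work.at[i, "sex"]
            work.at[i, "sex"] = None
            corrupted_cells.add((i, "sex"))
            missing_participants.add(pid)
            log.add(cids[i], "sex", "missing", old, None)

    # 3. planted cross-attribute impossibilities: give an unflipped
    #    participant the disease linked to the opposite sex
    for pid, idxs in participants.items():
        u = rng_inco.random()
        if (
            u >= profile.inconsistency_rate
            or pid in flipped_participants
            or pid in missing_participants
            or clean.loc[idxs[0], "disease"] in _SEX_LINKED.values()
        ):
            continue
        sex = clean.loc[idxs[0], "sex"]
        wrong = _SEX_LINKED["Female" if sex == "Male" else "Male"]
        for i in idxs:
            old = work.at[i, "disease"]
            work.at[i, "disease"] = wrong
            corrupted_cells.add((i, "disease"))
            log.add(cids[i], "disease", "inconsistency", old, wrong)

    # 4. implausible numeric outliers on age
    for i in range(len(work)):
        if rng_out.random() < profile.outlier_rate:
            old = work.at[i, "age"]
            new = str(int(rng_out.integers(131, 200)))
            work.at[i, "age"] = new
            corrupted_cells.add((i, "age"))
            log.add(cids[i], "age", "outlier", old, new)

    # 5. misplaced values: the disease label lands under sample_type
    for i in range(len(work)):
        if rng_misp.random() < profile.misplacement_rate:
            if (i, "sample_type") in corrupted_cells:
                continue
            old = work.at[i, "sample_type"]
            new = work.at[i, "disease"]
            if is_na(new):
                continue
            work.at[i, "sample_type"] = new
            corrupted_cells.add((i, "sample_type"))
            log.add(cids[i], "sample_type", "misplaced", old, new)

    # 6. token-level typos, abbreviations and brand names
    for attr in ("sex", "ancestry", "disease", "treatment", "sample_type"):
        for i in range(len(work)):
            if (i, attr) in corrupted_cells:
                continue
            cell = work.at[i, attr]
            if is_na(cell):
                continue
            tokens = split_cell(cell)
            out_tokens = list(tokens)
            for j, tok in enumerate(tokens):
                u_typo = rng_typo.random()
                u_abbr = rng_abbr.random()
                if u_typo < profile.typo_rate:
                    new = _make_typo(tok, rng_typo, forbidden)
                    typo_entries[attr][new] = tok
                    forbidden.add(new.casefold())
                    out_tokens[j] = new
                    log.add(cids[i], attr, "typo", tok, new)
                elif u_abbr < profile.abbreviation_rate:
                    if tok in BRAND_NAMES:
                        brands = BRAND_NAMES[tok]
                        new = brands[int(rng_abbr.integers(len(brands)))]
                    elif tok in ABBREVIATIONS:
                        new = ABBREVIATIONS[tok]
                    else:
                        continue
                    out_tokens[j] = new
                    log.add(cids[i], attr, "abbreviation", tok, new)
            if out_tokens != tokens:
                work.at[i, attr] = ";".join(out_tokens)

    # 7. binary presence/absence re-encoding of selected drugs
    binary_cols = {col: [None] * len(work) for col in _BINARY_DRUGS}
    for i in range(len(work)):
        if rng_bin.random() >= profile.binary_encode_rate:
            continue
        cell = work.at[i, "treatment"]
        tokens = split_cell(cell)
        for col, drug in _BINARY_DRUGS.items():
            if drug in tokens:
                tokens = [t for t in tokens if t != drug]
                binary_cols[col][i] = "yes"
                log.add(cids[i], "treatment", "binary-encoding", drug, "yes")
            else:
                binary_cols[col][i] = "no"
                log.add(cids[i], "treatment", "binary-encoding", drug, "no")
        work.at[i, "treatment"] = join_tokens(tokens)

    # 8. dispersal across redundant sparse source columns + NA variants
    id_cols = ["study_name", "participant_id", "sample_id"]
    if profile.disperse:
        messy_cols: dict[str, list] = {c: list(clean[c]) for c in id_cols}
        for attr, targets in _DISPERSAL.items():
            for t in targets:
                messy_cols[t] = [None] * len(work)
        for sub in _BIOMARKER_SUBFIELDS:
            messy_cols[sub] = [None] * len(work)
        for col in _BINARY_DRUGS:
            messy_cols[col] = binary_cols[col]
        for i in range(len(work)):
            for attr, targets in _DISPERSAL.items():
                value = work.at[i, attr]
                target = targets[int(rng_disp.integers(len(targets)))]
                if is_na(value):
                    if rng_nav.random() < profile.na_variant_rate:
                        tok = profile.na_tokens[
                            int(rng_nav.integers(len(profile.na_tokens)))
                        ]
                        messy_cols[target][i] = tok
                        log.add(cids[i], attr, "na-variant", None, tok)
                    continue
                if attr == "age" and target == "age" and rng_disp.random() < 0.3:
                    value = f"{value} years"
                messy_cols[target][i] = value
            bm = work.at[i, "biomarker"]
            for tok in split_cell(bm):
                sub, v = tok.split(":", 1)
                messy_cols[sub][i] = v
        messy = pd.DataFrame(messy_cols)
    else:
        messy = work.drop(columns=["biomarker"]).copy()
        messy["biomarker"] = work["biomarker"]
        messy = messy[list(clean.columns)]

    maps = _build_maps(onto, typo_entries)
    config = _build_config(profile, onto, disperse=profile.disperse)
    return FixtureBundle(clean, messy, maps, config, log, onto)


def _build_maps(
    onto: ToyOntology, typo_entries: dict[str, dict[str, str]]
) -> dict[str, CurationMap]:
    """Identity + abbreviation + brand + per-run typo entries, per attribute."""
    maps: dict[str, CurationMap] = {}
    for attr, vocab in _ATTR_VOCAB.items():
        entries = []
        seen: set[str] = set()
        for label in vocab:
            if label in seen:
                continue
            seen.add(label)
            curie = onto.curie_of(label)
            entries.append(CurationMapEntry(label, label, curie))
            abbr = ABBREVIATIONS.get(label)
            if abbr:
                entries.append(CurationMapEntry(abbr, label, curie))
            for brand in BRAND_NAMES.get(label, ()):
                entries.append(CurationMapEntry(brand, label, curie))
        for typo, label in typo_entries.get(attr, {}).items():
            entries.append(CurationMapEntry(typo, label, onto.curie_of(label)))
        maps[attr] = CurationMap(attr, entries)
    return maps


def _build_config(
    profile: CorruptionProfile, onto: ToyOntology, disperse: bool = True
) -> HarmonizationConfig:
    def sources(attr: str) -> list[str]:
        return _DISPERSAL[attr] if disperse else [attr]

    treatment_sources = sources("treatment") + (
        list(_BINARY_DRUGS) if disperse else []
    )
    attributes = [
        AttributeSpec(
            name="sex",
            structure="single",
            source_fields=sources("sex"),
            map="sex",
            enum=EnumSpec(nodes=[SEX_NODE]),
        ),
        AttributeSpec(
            name="ancestry",
            structure="multi",
            source_fields=sources("ancestry"),
            map="ancestry",
            enum=EnumSpec(nodes=[ANCESTRY_NODE]),
        ),
        AttributeSpec(
            name="disease",
            structure="single",
            source_fields=sources("disease"),
            map="disease",
            enum=EnumSpec(nodes=[DISEASE_NODE]),
        ),
        AttributeSpec(
            name="treatment",
            structure="multi",
            source_fields=treatment_sources,
            map="treatment",
            enum=EnumSpec(nodes=[TREATMENT_NODE]),
            binary_sources=(
                {
                    col: BinarySourceSpec(positive_label=drug)
                    for col, drug in _BINARY_DRUGS.items()
                }
                if disperse
                else {}
            ),
        ),
        AttributeSpec(
            name="sample_type",
            structure="single",
            source_fields=sources("sample_type"),
            map="sample_type",
            enum=EnumSpec(nodes=[SAMPLE_TYPE_NODE]),
        ),
        AttributeSpec(
            name="age",
            structure="numeric",
            source_fields=sources("age"),
            default_unit="years",
            bounds=BoundsSpec(low=0, high=130),
        ),
        AttributeSpec(
            name="biomarker",
            structure="composite",
            source_fields=list(_BIOMARKER_SUBFIELDS) if disperse else ["biomarker"],
            subfields=list(_BIOMARKER_SUBFIELDS),
        ),
    ]
    if not disperse:
        # packed composite cells pass through a single source column
        attributes[-1] = AttributeSpec(
            name="biomarker",
            structure="composite",
            source_fields=["biomarker"],
            subfields=list(_BIOMARKER_SUBFIELDS),
        )
    rules = [
        ConsistencyRuleSpec(
            name="female-no-prostate",
            if_attribute="sex",
            if_values=["Female"],
            then_attribute="disease",
            forbidden_values=["Prostate Carcinoma"],
        ),
        ConsistencyRuleSpec(
            name="male-no-ovarian",
            if_attribute="sex",
            if_values=["Male"],
            then_attribute="disease",
            forbidden_values=["Ovarian Carcinoma"],
        ),
    ]
    return HarmonizationConfig(
        na_tokens=list(
            dict.fromkeys(
                [t.lower() for t in profile.na_tokens]
                + ["", "na", "n/a", "null", "missing", "-", "999"]
            )
        ),
        attributes=attributes,
        consistency_rules=rules,
        invariant_attributes=["sex", "ancestry"],
        maps={a: f"maps/{a}.tsv" for a in _ATTR_VOCAB},
        ontologies=["ontology.obo"],
    )


def inject_roundtrip_errors(
    table: HarmonizedTable,
    onto: ToyOntology,
    seed: int,
    n: int = 5,
    attr: str = "disease",
) -> tuple[HarmonizedTable, list[InjectionRecord]]:
    """Corrupt n curated-term/ID pairs in a harmonized table.

    Alternates between replacing a single-token cell's id with a
    sibling term's id (label-mismatch) and with an unknown id
    (id-not-found).  Returns the corrupted copy and the log records.
    """
    rng = _stream(seed, 10)
    out = table.copy()
    df = out.data
    id_col = f"curated_{attr}_ontology_term_id"
    term_col = f"curated_{attr}"
    eligible = [
        i
        for i in range(len(df))
        if not is_na(df.at[i, id_col])
        and ";" not in str(df.at[i, id_col])
        and not is_na(df.at[i, term_col])
    ]
    if len(eligible) < n:
        raise ValueError(f"only {len(eligible)} eligible cells for {n} injections")
    picked = sorted(rng.choice(eligible, size=n, replace=False).tolist())
    records: list[InjectionRecord] = []
    vocab = _ATTR_VOCAB[attr]
    for k, i in enumerate(picked):
        old = str(df.at[i, id_col])
        if k % 2 == 0:
            label = str(df.at[i, term_col])
            others = [onto.curie_of(v) for v in vocab if v != label]
            new = others[int(rng.integers(len(others)))]
        else:
            new = "TOY:9999999"
        df.at[i, id_col] = new
        records.append(
            InjectionRecord(
                str(df.at[i, "curation_id"]), attr, "roundtrip", old, new
            )
        )
    return out, records


# ------------------------------------------------------------- scoring

#: Checker issue kind -> injection kinds it is responsible for.
_KIND_MAP: dict[IssueKind, str] = {
    IssueKind.OUT_OF_POOL: "misplaced",
    IssueKind.INCONSISTENCY: "inconsistency",
    IssueKind.OUTLIER: "outlier",
    IssueKind.ROUNDTRIP_MISMATCH: "roundtrip",
}

DETECTABLE_KINDS: tuple[InjectionKind, ...] = (
    "misplaced",
    "inconsistency",
    "outlier",
    "roundtrip",
)


@dataclass
class DetectionScore:
    precision: float
    recall: float
    confusion: dict[str, dict[str, int]]
    """kind -> {tp, fp, fn} on (curation_id, attribute) coordinates."""


def evaluate_detection(
    issues: Iterable[ValidationIssue],
    log: InjectionLog | Iterable[InjectionRecord],
) -> DetectionScore:
    """Score checker findings against the injection log.

    Findings and injections are matched on (curation_id, attribute,
    compatible kind) coordinates; several issues at one coordinate
    (e.g. a swapped id pair) count as one detection.  Only injection
    kinds that are supposed to surface as issues participate; ETL-level
    corruptions (typos, NA variants, binary encodings, ...) are
    recovered, not reported, and are excluded from the truth set.
    Empty truth and empty findings score as perfect.
    """
    records = log.records if isinstance(log, InjectionLog) else list(log)
    truth = {
        (r.curation_id, r.attribute, r.kind)
        for r in records
        if r.kind in DETECTABLE_KINDS
    }
    predicted: set[tuple[str, str, str]] = set()
    for issue in issues:
        mapped = _KIND_MAP.get(issue.kind)
        if mapped is None:
            continue
        predicted.add((issue.curation_id, issue.attribute, mapped))
    tp_set = predicted & truth
    precision = 1.0 if not predicted else len(tp_set) / len(predicted)
    recall = 1.0 if not truth else len(tp_set) / len(truth)
    confusion: dict[str, dict[str, int]] = {}
    for kind in DETECTABLE_KINDS:
        t = {c for c in truth if c[2] == kind}
        p = {c for c in predicted if c[2] == kind}
        confusion[kind] = {
            "tp": len(t & p),
            "fp": len(p - t),
            "fn": len(t - p),
        }
    return DetectionScore(precision, recall, confusion)


# ------------------------------------------------------------- export


def write_fixtures(bundle: FixtureBundle, outdir: str | Path) -> None:
    """Write ontology.obo, clean.tsv, messy.tsv, maps/*.tsv, config.yml
    and injections.jsonl under *outdir*."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.ontology.graph.write_obo(outdir / "ontology.obo")
    write_table(bundle.clean, outdir / "clean.tsv")
    write_table(bundle.messy, outdir / "messy.tsv")
    (outdir / "maps").mkdir(exist_ok=True)
    for name, cmap in bundle.maps.items():
        cmap.to_tsv(outdir / "maps" / f"{name}.tsv")
    bundle.config.to_yaml(outdir / "config.yml")
    with open(outdir / "injections.jsonl", "w", encoding="utf-8") as fh:
        for r in bundle.log.records:
            fh.write(
                json.dumps(
                    {
                        "curation_id": r.curation_id,
                        "attribute": r.attribute,
                        "kind": r.kind,
                        "original": r.original,
                        "corrupted": r.corrupted,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
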