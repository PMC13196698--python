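"""Shared fixtures: toy ontologies, diamond graphs, golden metrics fixture."""

from __future__ import annotations

import pandas as pd
import pytest

from metaharm.config import AttributeSpec, HarmonizationConfig
from metaharm.curation import CurationMap, CurationMapEntry
from metaharm.ontology import OntologyGraph, Term
from metaharm.simulate import ToyOntology, make_toy_ontology


@pytest.fixture(scope="session")
def toy() -> ToyOntology:
    return make_toy_ontology(seed=1)


@pytest.fixture(scope="session")
def graph(toy) -> OntologyGraph:
    return toy.graph


@pytest.fixture()
def diamond() -> OntologyGraph:
    """A -> {B, C} -> D multi-parent diamond (edges child-of)."""
    return OntologyGraph(
        [
            Term("DIA:A", "a-root"),
            Term("DIA:B", "b-mid", parents=frozenset({"DIA:A"})),
            Term("DIA:C", "c-mid", parents=frozenset({"DIA:A"})),
            Term("DIA:D", "d-leaf", parents=frozenset({"DIA:B", "DIA:C"})),
        ]
    )


@pytest.fixture(scope="session")
def demo_map() -> CurationMap:
    from pathlib import Path

    from metaharm.curation import load_map

    path = Path(__file__).parent.parent / "src" / "metaharm" / "data" / "treatment_map.tsv"
    cmap, report = load_map(path, attribute="treatment")
    assert not report.malformed_curies
    return cmap


# ------------------------------------------------------------------
# golden metrics fixture: a 20-row, 3-attribute raw table small enough
# to recompute every metric by independent brute force
# ------------------------------------------------------------------


def golden_raw() -> pd.DataFrame:
    fruit_a = [
        "apple", "aple", None, "banana", "apple",
        None, "999", "banana", "apple", None,
        "aple", None, "banana", None, "apple",
        None, "banana", None, "aple", None,
    ]
    fruit_b = [
        None, None, "banana", None, None,
        "apple", None, None, None, "aple",
        None, "banana", None, None, None,
        "apple", None, "missing", None, None,
    ]
    drinks = [
        "tea;coffe", "tea", None, "coffe", "tea;tea",
        None, "coffe;tea", None, "tea", None,
        "coffe", None, "tea;coffe", None, None,
        "tea", None, "coffe", None, "tea",
    ]
    age = [
        "34", "40 years", None, "51", "999",
        "28", "77", None, "61", "45",
        None, "33", "59", None, "70",
        "22", None, "48", "36", None,
    ]
    return pd.DataFrame(
        {
            "study_name": ["s1"] * 20,
            "participant_id": [f"P{i:02d}" for i in range(1, 21)],
            "sample_id": ["S1"] * 20,
            "fruit_a": fruit_a,
            "fruit_b": fruit_b,
            "drinks": drinks,
            "age": age,
        }
    )


def golden_config() -> HarmonizationConfig:
    return HarmonizationConfig(
        attributes=[
            AttributeSpec(
                name="fruit",
                structure="single",
                source_fields=["fruit_a", "fruit_b"],
                map="fruit",
            ),
            AttributeSpec(
                name="drink",
                structure="multi",
                source_fields=["drinks"],
                map="drink",
            ),
            AttributeSpec(
                name="age",
                structure="numeric",
                source_fields=["age"],
                default_unit="years",
            ),
        ],
        maps={"fruit": "fruit.tsv", "drink": "drink.tsv"},
    )


def golden_maps() -> dict[str, CurationMap]:
    return {
        "fruit": CurationMap(
            "fruit",
            [
                CurationMapEntry("apple", "Apple", "FRT:0000001"),
                CurationMapEntry("aple", "Apple", "FRT:0000001"),
                CurationMapEntry("banana", "Banana", "FRT:0000002"),
            ],
        ),
        "drink": CurationMap(
            "drink",
            [
                CurationMapEntry("tea", "Tea", "DRK:0000001"),
                CurationMapEntry("coffe", "Coffee", "DRK:0000002"),
            ],
        ),
    }


@pytest.fixture()
def golden():
    return golden_raw(), golden_config(), golden_maps()
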