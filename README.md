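# metaharm

Ontology-grounded harmonization of heterogeneous sample metadata.

Public omics repositories accumulate sample metadata written by hundreds of
independent groups: the same fact appears as `M`, `Male`, or `sex=1`, drugs
are recorded under brand names (`lantus`, `solostar`) instead of the generic
compound, values land under the wrong attribute, missingness is encoded as
any of `NULL`, `missing`, `-`, or `999`, and the same participant may carry
contradictory annotations across samples or studies. `metaharm` is a toolkit
for the retrospective curation of such tables: it executes a declarative
merging schema that consolidates dispersed source columns into curated
attributes, maps free-text values onto ontology terms through per-attribute
curation maps, validates the result against the ontology and cross-attribute
logic, resolves conflicts by consensus, and exposes the harmonized table to
hierarchy-aware queries. It is aimed at data curators and computational
biologists who need repository-scale, auditable metadata clean-up rather than
one-off spreadsheet fixes.

## The method

**Curation maps.** Each attribute has a map of
`original_value → (curated_ontology_term, curated_ontology_term_id)` pairs.
Applying a map to a `;`-delimited cell maps each token independently; tokens
sent to the same curated term collapse to one occurrence (so `lantus` and
`solostar` both become a single `Insulin Glargine`), and unmapped tokens pass
through verbatim so nothing is silently destroyed.

**Dynamic enums.** Instead of a hard-coded value list, an attribute's allowed
values are defined as the descendant closure of designated ontology terms
(e.g. everything below `ancestry category`). Values outside the pool are
flagged as likely misfiled. A complementary *round-trip check* looks up each
stored ontology ID and compares the returned label with the stored term,
catching term/ID mismatches introduced during curation.

**Majority rule.** For attributes that cannot change over time (sex assigned
at birth, genetic ancestry), conflicting annotations across a participant's
samples are resolved to the modal value; with no unique mode every member is
set to NA; NA members do not vote but are filled by the winner, which infers
missing annotations from the participant's other samples. Before any
correction, discrepancies are triaged per study: a study contributing the
bulk of them (share ≥ 0.5 by default) is flagged as a suspected systematic
recording error and excluded from consensus correction until reviewed.

**Quality metrics.** Harmonization is scored by *compression* (original
columns merged per curated attribute), *consolidation* (drop in unique
values), *correction rate* (fraction of values changed), and *completeness*
(fraction of non-NA values), summarized in a six-column merging-schema table
covering each original/curated column pair before and after.

Every curated attribute carries full provenance
(`curated_{a}`, `curated_{a}_ontology_term_id`, `curated_{a}_source`,
`original_{a}_value`), and a synthetic-fixture generator produces corrupted
multi-study tables with an exhaustive injection log so that every stage can
be scored against known ground truth.

## Worked example

```python
from importlib.resources import files
from metaharm import apply_map, load_map

path = files("metaharm") / "data" / "treatment_map.tsv"
cmap, _ = load_map(path, attribute="treatment")

res = apply_map("metformin;sitagliptin;lantus;solostar;novorapid", cmap)
print(res.curated_value)
# Metformin;Sitagliptin;Insulin Glargine;Insulin Aspart
print(res.curated_ids)
# TOY:0000061;TOY:0000062;TOY:0000064;TOY:0000065
```

Five original tokens become four curated terms: the two brand names
consolidate into one generic compound, and each term carries its ontology ID.

The same flow end to end, from a shell:

```bash
metaharm simulate --seed 11 --out fx/
metaharm harmonize --input fx/messy.tsv --config fx/config.yml \
    --out harmonized.tsv --report report.json
metaharm validate --input harmonized.tsv --config fx/config.yml \
    --issues issues.jsonl
metaharm resolve --input harmonized.tsv --attr sex --config fx/config.yml \
    --out resolved.tsv --audit audit.json
metaharm query --input resolved.tsv --attr sample_type --terms "Neoplasm" \
    --ontology fx/ontology.obo --out neoplastic.tsv
```

On the seed-11 fixture this prints, stage by stage:

```
807 samples, 2151 injections -> fx
harmonized 807 rows -> harmonized.tsv
24 issues -> issues.jsonl
114 resolutions -> resolved.tsv
639 of 807 rows -> neoplastic.tsv
```

The query returns rows annotated `Primary Neoplasm`, `Metastatic Neoplasm`
or `Recurrent Neoplasm` even though no cell literally says `Neoplasm` —
the ontology hierarchy expands the query term to all of its descendants.

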