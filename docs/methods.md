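# Methods

This note documents the models, conventions and numerical choices behind
`metaharm`, and what the synthetic-fixture tests do and do not establish
about real metadata.

## Ontology model

Ontologies are loaded from OBO flat-file term stanzas (tags `id`, `name`,
`synonym`, `is_a`, `is_obsolete`; all other tags parsed and ignored) into a
directed acyclic graph keyed by CURIE. Only the `is_a` subsumption relation
is traversed; `part_of` and other relations are out of contract, so
partonomy-heavy hierarchies (e.g. anatomical sites) will under-expand and a
caller who needs them must flatten them into `is_a` beforehand. Cycles are a
hard load error naming one member; `is_a` targets without a stanza of their
own are reported as dangling and their edges dropped, which tolerates
ontology excerpts that point upward out of the excerpt. Merging several files
is supported, but a CURIE defined twice is a hard error — silently preferring
one definition would corrupt round-trip validation downstream.

Obsolete terms are loaded and flagged. They never appear in descendant
closures or text matching, but their labels remain retrievable so that the
round-trip checker can distinguish "ID points at an obsolete term" (its own
finding) from "ID unknown".

**Term depth** is the length of the *longest* `is_a` path to any root. In a
multi-parent DAG the longest path scores a term by the most specific lineage
it participates in, which is the right orientation for most-specific
consolidation: when redundant-granularity values co-occur, ancestors of other
candidates are dropped first, then the maximum depth wins, and residual
equal-depth ties break lexicographically by CURIE with a logged tie notice,
keeping the outcome deterministic.

**Text matching** of labels and synonyms is whitespace-trimmed,
whitespace-collapsed and case-folded; stored casing is preserved. CURIEs
match case-sensitively during table queries (prefixes are identifiers), with
a case-insensitive fallback only in bare `match_terms` lookups.

## Curation maps and the harmonization engine

A curation-map entry maps one verbatim original value to an ontology term and
its CURIE; both present or both NA (an NA target means "reviewed,
uninterpretable", and applying it removes the token). Lookup normalizes
tokens the same way as ontology text matching. Within one cell, tokens
mapping to the same curated term collapse to a single occurrence at the first
position — this is how separately entered brand names consolidate to one
generic compound — and any repetition of a curated term is collapsed, not
only adjacent ones. Unmapped tokens pass through verbatim with an empty ID
slot and are reported, never dropped: information is only removed by an
explicit NA-target map entry.

The engine executes a declarative schema, per curated attribute:

1. gather the attribute's source columns left-to-right;
2. recode NA variants. The default NA token set is
   `"", na, n/a, nan, null, missing, -, 999, not available, not provided,
   not collected` (case-insensitive). `unknown` is deliberately *not* in the
   default set because some attributes use `Unknown` as a legal category
   (e.g. vital status); per-attribute overrides exist;
3. recode binary presence/absence source columns to descriptive labels
   (configured positive/negative token sets; non-interpretable tokens become
   NA with a logged finding);
4. apply the curation map token-wise;
5. resolve structure: single-valued attributes fed by several disagreeing
   sources keep the ontologically most specific candidate when all carry
   resolvable CURIEs, otherwise the leftmost in schema order, and always log
   a conflict finding; numeric attributes are split into value and unit
   (leading/embedded decimal literal, `.` separator only, bare numbers take
   the configured default unit); composite attributes serialize as
   `subfield:value` pairs joined by `;` in registry order, omitting NA
   subfields, with packed composite cells in a source column parsed and
   merged.

Each attribute emits `curated_{a}`, `curated_{a}_ontology_term_id` (aligned
token-wise; empty slot = passthrough token), `curated_{a}_source` (which
source columns supplied the value) and `original_{a}_value` (verbatim
pre-cleaning content of all non-empty sources, `;`-joined). This is
deliberately lossless: the provenance columns suffice to relocate the exact
raw content, which the test suite audits by replaying them against the raw
table. `curation_id` is `study:participant[:sample]` with `:` and `%`
percent-escaped inside components so parsing is unambiguous; `last_modified`
is an ISO-8601 UTC timestamp, constant per run and pinnable for byte-stable
output. The composite serialization and the `;`-joined multi-source
conventions are this package's own documented dialect.

## Validation

*Dynamic enums* define an attribute's allowed values as the union of
descendant closures of configured ontology nodes. `include_nodes` defaults
to false (an ancestry pool means the concrete categories, not the category
node itself). Membership is granted by curated label (case-insensitive) or
CURIE (exact), so label-only tables still validate. *Consistency rules* are
propositional: when the `if` attribute takes a listed value, the `then`
attribute must not take a forbidden value; NA on either side is
non-evidence. Issues are located at the forbidden side. *Outlier bounds* are
config-supplied closed plausibility intervals (default age bound 0–130
years); no distributional estimation is attempted. The *round-trip check*
compares each stored ID's graph label against the stored term token-wise;
ragged term/ID token counts are themselves a finding, not a crash. All
checkers are read-only.

## Conflict resolution

Consensus resolution applies only to attributes the config declares
time-invariant; requesting any other attribute is a refusal error, because a
cross-time consensus on an evolving attribute (disease stage, treatment
status) would fabricate data. "Majority" is strict plurality by default —
the unique mode wins, so (A,A,B,C) resolves to A — with an optional strict
mode requiring more than half of the votes; two or more tied modes set every
member to NA. NA members never vote but are filled by the winner
(inference). Groups are keyed by the participant-level prefix of
`curation_id` by default, or by explicit columns (e.g. bare
`participant_id`) when the same participant appears under several studies.

Systematic-error triage attributes each discrepancy (a validation finding,
or a minority vote inside a conflict group; every vote when tied) to its
study. A study holding at least the configured share (default 0.5, chosen
so that a study with roughly nine-tenths of all discrepancies is
unambiguously flagged) is suspected systematic, and the resolver can be told
to exclude it: excluded samples neither vote nor get corrected, since a
consistently wrong study would otherwise outvote correct annotations.

## Querying and reshaping

`tree_filter` expands each query term through label/synonym/CURIE matching
to ontology terms, then to their full descendant closures, realized as the
set of labels, synonyms and CURIEs; a row is kept when its delimited tokens
intersect the expansion (`any`) or when every term's expansion hits it
(`all`, interpreted per query term). Unresolvable terms fall back to literal
matching with a warning; `expand=False` degenerates to literal token
filtering. Only descendants are expanded; ancestor expansion is not
implemented.

`spread_meta` turns a multi-valued attribute into per-token presence
indicators (`yes`/NA, columns in alphabetical token order) and a composite
attribute into one column per subfield (registry order). `gather_meta` is
its exact inverse on *canonically ordered* cells — sorted tokens for
multi-valued attributes, registry order for composites — because the wide
form cannot represent per-row token order; `canonicalize_tokens` performs
that normalization, and unique-combination counting should be done on
canonicalized cells.

## Synthetic fixtures: what they emulate

The generator builds a deterministic toy ontology (reserved `TOY:` prefix,
fixed backbone: an ancestry category with exactly eight children, sex,
disease with two sex-linked leaves, a drug branch, a sample-type branch
where one term subsumes three specific types, plus seeded random filler) and
a clean multi-study table, then corrupts it at configured rates, logging
every corruption:

| rate | default | emulates |
| --- | --- | --- |
| `typo_rate` | 0.05 | single-character edits, guaranteed collision-free |
| `abbreviation_rate` | 0.30 | curator abbreviations and drug brand names |
| `misplacement_rate` | 0.02 | a disease label filed under sample type |
| `na_variant_rate` | 0.30 | missing data written as `NULL`/`missing`/`-`/`999` |
| `conflict_rate` | 0.20 | per-sample flips of the invariant sex attribute |
| `missing_rate` | 0.05 | dropped sex annotations (inference candidates) |
| `binary_encode_rate` | 0.30 | drugs re-encoded as yes/no presence columns |
| `outlier_rate` | 0.01 | implausible ages (131–199) |
| `inconsistency_rate` | 0.02 | sex-linked disease given to the wrong sex |

Defaults describe a messy-but-recoverable collection: 4 studies, 200
participants, 3–5 samples each. All randomness flows from one seed split
into fixed per-kind substreams, so changing one rate never reshuffles
another kind's corruptions. At most one corruption is applied per cell, and
corruption kinds are kept mutually non-interfering by construction (flips
skip participants with sex-linked diseases; planted inconsistencies use
unflipped participants), so that each injected, detectable corruption is
found by exactly one checker and precision/recall against the log are
meaningful. Attribute values are dispersed across redundant sparse source
columns (e.g. treatment over three columns plus binary drug columns); the
injection log records value-level corruptions, while provably invertible
representation changes (dispersal, `34 years` unit annotation) are not
logged — the test suite instead verifies their inversion cell-by-cell. The
emitted curation maps invert every typo, abbreviation and brand name, which
is what makes the clean table recoverable wherever a map inverse exists.

When a systematic study-level flip is configured, no participant is homed in
that study; it re-files samples of participants homed elsewhere, mirroring
the aggregator situation in which the same participant's samples appear
under several studies and a wholesale recording error becomes detectable.
Even so, a participant with most re-filed samples can make minority-vote
attribution assign a few discrepancies to other studies, so triage
assertions check dominance and flagging, not a 100% share.

**What passing these tests does not show.** Real metadata contains free-text
pathologies the generator does not model: context-dependent meanings,
multilingual entries, compound cells mixing several attributes, genuinely
ambiguous abbreviations, and curation maps that are themselves incomplete or
wrong. Perfect precision/recall on fixtures demonstrates the machinery is
sound, not that real-world detection is complete; on real tables the curation
maps remain the manual, fallible ingredient.

## Problem sizes and determinism

The shipped test suite and the acceptance script run the full pipeline on
fixtures of 200 participants (~800 samples) per seed, 10 seeds for the
recovery and detection sweeps, 100 random ontology/table pairs (≤200 terms,
≤500 rows) for query-oracle equivalence, and 1000 random tables for the
reshape round trip — sizes chosen to exercise every code path with
comfortable margins on a laptop-class machine. Every stage is deterministic
given inputs, config and seed; the only run-varying output is the
`last_modified` timestamp, which can be pinned.

## Known limitations

- `is_a`-only traversal; no OWL reasoning or cross-ontology equivalences.
- No automatic term suggestion: curation maps are produced externally (or by
  the fixture generator); the toolkit applies and audits them.
- The rule engine is propositional over value sets; temporal or arithmetic
  predicates are out of scope.
- Locale handling for numbers is limited to the `.` decimal separator.
- Correction rate compares normalized token multisets, so case-only or
  order-only changes are not counted as corrections; unique-value counts are
  token-level by default (both choices are exposed as parameters).
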