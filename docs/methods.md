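# Methods

`neurorepo` implements a systematic drug-repositioning analysis for
neuroinflammation-linked interventions in autism spectrum disorder (ASD):
it integrates a curated literature layer (treatments, their component
compounds, curated action keywords, reported effects) with three external
knowledge sources (drug→therapeutic-category assignments, drug→protein
target interactions, drug→small-molecule-pathway memberships), and derives
repositioning candidates, shared-target matrices and typed knowledge-graph
views from the integrated registry.

## The knowledge base

Five entity kinds are held in a single registry: compounds, treatments,
therapeutic categories, proteomic targets and pathway records, plus three
deduplicated edge sets (compound–category, compound–target,
compound–pathway). All cross-source matching is by **normalized name**:
lowercase, internal whitespace collapsed to one space, spaces adjacent to
separator punctuation removed (so `5-methoxy-N, N-dimethyltryptamine` and
`5-methoxy-N,N-dimethyltryptamine` unify). Greek letters and hyphens are
preserved — they are semantically load-bearing in protein names
(`alpha-7`, `Prostaglandin G/H synthase 1`). The three toggles behind this
policy are configuration keys and default to on.

Registration is an idempotent upsert: re-registering an entity under any
of its known names merges synonyms and returns the existing identifier;
two different DrugBank-style accessions claiming the same normalized name
is an integrity error rather than a silent merge. Entities without a
recognised accession (`DB#####`, `SMP#####`) receive a local identifier
derived deterministically from the normalized name, so identifiers are
stable across runs and machines without requiring real accessions.

The on-disk store is one SQLite file (one table per entity kind, three
edge tables, `PRAGMA user_version` as schema version). Saves always write
a fresh file with fully sorted inserts, making stores byte-identical for
identical in-memory state — the property the determinism tests rely on. A
TSV export (one file per table) supports plain-text diffing.

Compounds with no external data at all (diets, cell therapies, enzyme
preparations) are full registry records with empty edge sets, never
dropped: absence of data is a reportable result in this analysis, not an
ingestion failure.

## Ingestion

* **DrugBank-dialect XML** is parsed with a streaming `lxml` parse that
  clears each `<drug>` element after processing, so memory is bounded by
  one element, not the file. Records missing their primary ID or name go
  to a rejects report and the parse continues; malformed XML aborts with
  the line number. Only the documented dialect subset (IDs, names,
  synonyms, categories) is read; unknown elements are ignored.
* **Target tables** are tab-separated with quoting disabled, because
  protein names legitimately contain commas and silent CSV re-quoting is a
  classic corruption vector here. Rows are deduplicated on normalized
  (drug, target). Drug names that do not resolve become new local
  compounds: candidate drugs outside the treatment set must be
  representable.
* **Pathway tables** carry one membership per row; two names for one
  pathway ID is an integrity error listing both.

Live retrieval from compound databases is deliberately out of scope; the
parsers define the snapshot contract that any fetcher must satisfy.

## Candidate enumeration

For a treatment T with component set C and an association route R
(categories, targets or pathways), the candidate set is

```
cand_R(T) = { d ∉ C : assoc_R(d) ∩ ⋃_{c∈C} assoc_R(c) ≠ ∅ }
```

with a `via` map recording, per candidate, exactly which shared
associations justify it. Exclusion is scoped to the treatment's own
components only — a compound used by some *other* treatment is a perfectly
good candidate here. Combination treatments therefore satisfy
`cand_R(T) = ⋃_{c∈C} cand_R({c}) \ C`, which is fuzz-tested. Candidates
are enumerated, never ranked: the method makes no claim about relative
promise, and no ADMET or safety filtering is applied.

The count report mirrors the summary-table layout: one row per
(treatment, component) with the component's edge totals and the candidate
counts of its single-compound sub-treatment, plus a Global row holding the
*deduplicated union* across treatments per route. Union semantics are a
deliberate design choice: per-treatment counts overlap heavily, so a
column sum would double-count and is not a meaningful global quantity.

## Shared-target analysis

A treatment's target set is the union over components of their target
edges; the shared-target result of a pair is the intersection, reported as
a count plus sorted names. Target identity is normalized exact-name
matching with no ontology layer: `Prostaglandin G/H synthase 1` and
`Prostaglandin G/H synthase` stay distinct. The packaged fixture preserves
one such near-duplicate pair verbatim (a likely typo in the source
material) rather than merging it. Zero-overlap pairs are retained by
default so downstream consumers get complete matrices; `nonzero_only`
reproduces the tabular presentation that omits them.

## Pathway classification

Compound actions curated from the literature (free-text phrases such as
"inhibiting nuclear factor kappa B") are mapped onto a **closed set of six
global pathways**: inflammation, immune system, oxidative stress,
neurotransmitter regulation, gene expression regulation, gut–brain axis.
The original assignments were made by human raters; reproducibility
demands an explicit artifact, so the package ships a versioned rule table
(TSV: pattern, pathway, provenance) and matches by case-insensitive
substring on normalized text. Design points:

* Cytokine-reduction actions map to *both* inflammation and immune
  system; no finer attribution is defensible from the available evidence.
* One curated sulforaphane action ("increasing neuronal autophagy flux")
  has no published pathway attribution; the default table leaves it
  unmatched rather than guessing. Unmatched keywords are flagged,
  never classified.
* No default rule targets gene expression regulation or the gut–brain
  axis: those labels exist in the enumeration but no curated keyword
  assignment supports a rule, and uncited rules are a validation warning.
* `validate_rules` flags duplicate (pattern, pathway) pairs, shadowed
  rules (a longer pattern that can never add a pathway beyond a contained
  shorter one) and missing provenance.

Classification is keyword-local and monotone
(`classify(k1 ∪ k2) = classify(k1) ∪ classify(k2)`), order-independent and
idempotent — all property-tested.

Two distinct per-compound pathway counts exist and are reported under
distinct names: the number of pathway-database memberships
(`pathways_total` in the count report) and the number of global pathways
from the classifier (in the classification profiles). They answer
different questions and are never conflated.

## Knowledge-graph views

Three typed, layered DAG views are built per treatment with fixed
per-view layer maps:

| view       | layer 0   | 1        | 2                                    | 3                               | 4       |
|------------|-----------|----------|--------------------------------------|---------------------------------|---------|
| categories | treatment | compound | category                             | associated drug                 | effects |
| pathways   | treatment | compound | action keyword / SMPDB pathway / ?   | global pathway / co-member drug | effects |
| targets    | treatment | compound | target                               | associated drug / ?             | effects |

The layer maps differ per view on purpose (the pathway view needs an
extra intermediate tier); they are fixed in code rather than inferred.
Invariants enforced on every build: acyclicity, strictly increasing layer
along every edge, reachability of every node from the treatment node, and
associated drugs never duplicating components. Missing data ("?") is a
first-class `missing_data` node with in-degree ≥ 1 and out-degree 0 —
absence is rendered, not omitted. If a degenerate treatment produces no
path to the effects box (e.g. diet-only treatments with no associations),
the box aggregates directly from the compound layer so the reachability
invariant holds uniformly.

`max_assoc` (default 2) caps associated drugs per anchor node. It is a
display cap, not an analytic parameter — candidate enumeration is never
capped. Selection under the cap is lexicographic by normalized name: the
source material does not state its selection rule, and a deterministic
choice that makes builds byte-reproducible was preferred over guessing an
unstated one.

Exports: GraphML and a JSON graph document (both lossless round trips,
validated by a pydantic schema; a JSON-schema description ships in
`data/graph_schema.json`), plus DOT for rendering. No plotting or layout
engine is included.

## Synthetic data generator

The generator emits a complete mock ecosystem (XML, two TSVs, treatments
JSON) plus a `GroundTruth` computed during generation by independent
brute-force set algebra — double loops over the raw sampled associations,
a separate single-pass keyword matcher reading the rule-table text, and
closed-form node/edge count formulas per graph view. None of it calls the
pipeline.

Association model: each drug owns private category/target/pathway names no
other drug can draw; each association slot is diverted to a shared pool
with probability `overlap_bias ∈ [0, 1]`. At 0 all association sets are
pairwise disjoint (every candidate set and cross-treatment intersection
provably empty); at 1 everything is drawn from the shared pool. Defaults
(50 drugs, 12/30/8 shared categories/targets/pathways, 10 treatments of
1–3 components, bias 0.6) give dense-but-not-degenerate overlap comparable
in spirit to a small neighbourhood of a real drug database; oracle tests
sweep seeds and biases, with knowledge bases up to 200 drugs. What the
generator does **not** emulate: real degree distributions (hub proteins
like CYP3A4 touch hundreds of drugs), synonym noise across sources, and
version skew between databases — so passing oracle tests demonstrates
algebraic correctness of the pipeline, not robustness to real-world name
reconciliation, which is exercised separately by the curated fixture.

## The packaged worked-example fixture

A small, fully synthetic bundle encodes the study's 29 treatments and is
constructed so the published worked-example numbers emerge from the
pipeline's own set algebra. Per-compound target sets follow a
minimal-assumption scheme: each single compound receives exactly the
target names it is reported to share with the cannabidiol treatment, plus
a few private filler targets (so totals are nonzero where the source
reports data); combination rows are *not* encoded anywhere — they emerge
from component unions at query time. The consistency of this scheme is
itself a non-trivial property of the published numbers (e.g. the
memantine and sulforaphane+risperidone shared-name sets are disjoint and
union exactly to the memantine+risperidone row). Pathway availability is
restricted to exactly the 11 compounds reported to have it; the named
graph entities (alfuzosin, acepromazine, 10-hydroxycamptothecin,
5-methoxy-N,N-dimethyltryptamine, calcium, carbon dioxide, inactive
rhomboid protein 2, …) are wired so each appears exactly where the worked
examples place it. All accessions in the bundle are synthetic
placeholders; no licensed database content is included, and absolute
candidate counts against real database releases are explicitly out of
scope (they are version-dependent).

One modelling question the source leaves open: melatonin appears both in
a combination and as a controlled-release mono-treatment; identical
printed totals support modelling it as a single compound, which we do.
Similarly, the prose compound-availability counts (22 with categories, 20
with targets) disagree by one with the per-row table they summarise
(21/19); the package reproduces the table and surfaces the computed
counts in its summary report rather than hard-coding the prose.

## Numerical and degenerate-input choices

* All randomness flows from a single integer seed through `random.Random`;
  nothing reads global RNG state. Seeds derived from user seeds stay below
  2³¹.
* Every iteration over a set that reaches an output file is sorted;
  serialized JSON uses sorted keys. Re-running any stage on unchanged
  inputs is byte-identical.
* Empty inputs are valid everywhere: an empty bundle yields an empty
  registry, an all-zero summary and exit status 0.
* Tie-breaks (cap selection, report ordering) are lexicographic on the
  normalized name, case-insensitive.

## Known limitations

* Substring rule matching can over-match on short patterns; the shipped
  table uses long, specific patterns and the validator warns on shadowing,
  but a rule table with aggressive short patterns is the user's risk.
* No ontology mapping for targets or categories: spelling variants that
  normalization does not unify stay distinct.
* The store is single-writer; no concurrency or migration support.
* Statistical assessment of overlap (is 8 shared targets surprising?) is
  intentionally absent — the method enumerates and describes, it does not
  test hypotheses.
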