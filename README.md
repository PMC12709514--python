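# neurorepo

Knowledge-base construction and drug-repositioning candidate enumeration
for neuroinflammation-targeted interventions in pediatric autism spectrum
disorder (ASD).

Pharmacological options for ASD in children are scattered across small
trials of heterogeneous interventions — antipsychotics, SSRIs,
supplements, diets, cell therapies. `neurorepo` is for computational
pharmacologists and bioinformaticians who want to integrate such a curated
treatment layer with external drug knowledge (therapeutic categories,
protein targets, small-molecule pathways) and systematically ask: *which
other known drugs share biology with what already shows effects?*

## The method

Each treatment T is a set of component compounds C. From three association
tables (drug–category, drug–target, drug–pathway), the package derives,
per route R:

```
cand_R(T) = { d ∉ C : assoc_R(d) ∩ ⋃_{c∈C} assoc_R(c) ≠ ∅ }
```

— every registered drug sharing at least one category, proteomic target or
pathway with a component, excluding the components themselves. Candidates
are enumerated with their justification (the shared associations), never
ranked. Combination treatments behave as unions of their components, so
`cand_R(T) = ⋃_{c∈C} cand_R({c}) \ C`.

Around that core the package provides:

* an idempotent, name-normalizing registry with a deterministic SQLite
  store and TSV export (`neurorepo.kb`);
* streaming parsers for DrugBank-dialect XML, drug–target TSV and
  pathway-membership TSV (`neurorepo.ingest`);
* the curated treatments layer, including a packaged 29-treatment
  worked-example fixture (`neurorepo.treatments`, `neurorepo.curated_fixture`);
* rule-table classification of curated compound actions onto six global
  pathways — inflammation, immune system, oxidative stress,
  neurotransmitter regulation, gene expression regulation, gut–brain axis
  (`neurorepo.pathways`);
* pairwise shared proteomic-target analysis, `|targets(T₁) ∩ targets(T₂)|`
  with name lists (`neurorepo.shared_targets`);
* three typed, layered knowledge-graph views per treatment with
  GraphML/JSON/DOT export (`neurorepo.graphs`);
* a synthetic input-ecosystem generator whose brute-force ground truth
  serves as an independent oracle (`neurorepo.synthetic`);
* an end-to-end pipeline driver, dashboard JSON feed and a thin `neurorepo`
  CLI (`neurorepo.pipeline`, `neurorepo.feed`, `neurorepo.cli`).

See `docs/methods.md` for the model, its assumptions and design choices.

## Worked example

`examples/` contains one short script per capability. For instance,
enumerating repositioning candidates for the sulforaphane + risperidone
combination on the packaged fixture (`examples/02_enumerate_candidates.py`):

```
categories:  7 candidates -> 10-Hydroxycamptothecin, 2-(4-chlorophenyl)-5-quinoxalinecarboxamide, Acepromazine, Alfuzosin, Cyamemazine, Loxapine, Luteolin
targets   : 12 candidates -> 5-methoxy-N, N-dimethyltryptamine, Acepromazine, Atomoxetine, Buspirone, Cannabidiol, Cyamemazine, Fluoxetine, Loxapine, Melatonin, Methylphenidate, Prednisolone, Ubidecarenone
pathways  :  2 candidates -> Calcium, Carbon dioxide
            (no data on this route for: Sulforaphane)

alfuzosin shares: Adrenergic Antagonists, Adrenergic alpha-1 Receptor Antagonists
```

Reading: alfuzosin is proposed because it shares the alpha-1 antagonist
category with risperidone; calcium and carbon dioxide co-occur in
risperidone's metabolism pathway; sulforaphane has no pathway record, so
the pathway route reports explicit missing data for it rather than
silently skipping.

The shared-target analysis (`examples/03_shared_targets.py`) prints, for
the cannabidiol treatment against all 28 others, the 17 nonzero overlap
rows — e.g. cannabidiol ∩ memantine = 8 targets (glycine receptor
subunits, neuronal nicotinic receptor alpha-7, shared CYP enzymes),
overlap that flags the pair for combination-therapy follow-up.

A full pipeline run over any input bundle:

```
neurorepo run-all --drugbank drugbank.xml --targets targets.tsv \
    --pathways pathways.tsv --treatments treatments.json --outdir artifacts
```

writes the store, count report, shared-target matrix, per-treatment graph
exports, summary JSON and the dashboard feed; re-running on unchanged
inputs is byte-identical.

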