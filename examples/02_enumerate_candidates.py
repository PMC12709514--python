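"""Enumerate repositioning candidates for one combination treatment.

A candidate is any registered drug sharing at least one therapeutic
category, proteomic target, or pathway with a treatment component,
excluding the components themselves.
"""

from neurorepo import candidates_by_route, load_curated_fixture

kb = load_curated_fixture()
treatment = kb.resolve_treatment("Sulforaphane+risperidone")

for route in ("categories", "targets", "pathways"):
    cs = candidates_by_route(treatment, kb, route)
    names = [kb.compounds[c].preferred_name for c in cs.sorted_candidates(kb)]
    print(f"{route:10s}: {len(names):2d} candidates -> {', '.join(names)}")
    if cs.missing_components:
        missing = sorted(kb.compounds[c].preferred_name
                         for c in cs.missing_components)
        print(f"{'':10s}  (no data on this route for: {', '.join(missing)})")

# Each candidate is justified by the shared associations recorded in `via`,
# e.g. alfuzosin is listed because it shares the alpha-1 antagonist
# category with risperidone.
cs = candidates_by_route(treatment, kb, "categories")
alf = kb.resolve_name("Alfuzosin")
print("\nalfuzosin shares:",
      ", ".join(sorted(kb.categories[c].name for c in cs.via[alf])))
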