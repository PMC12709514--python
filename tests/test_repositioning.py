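"""Candidate enumeration: worked examples, brute-force equality, set properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorepo import (
    GeneratorParams,
    build_kb,
    candidates_by_category,
    candidates_by_pathway,
    candidates_by_route,
    candidates_by_target,
    count_report,
    generate,
    load_treatments,
)
from neurorepo.kb import Treatment


def _names(kb, cs):
    return {kb.compounds[c].preferred_name for c in cs.candidates}


def test_sulforaphane_risperidone_category_candidates(fixture_kb):
    t = fixture_kb.resolve_treatment("Sulforaphane+risperidone")
    names = _names(fixture_kb, candidates_by_category(t, fixture_kb))
    assert {"Alfuzosin", "10-Hydroxycamptothecin"} <= names
    via = candidates_by_category(t, fixture_kb).via
    alf = fixture_kb.resolve_name("Alfuzosin")
    shared_cats = {fixture_kb.categories[c].name for c in via[alf]}
    assert "Adrenergic alpha-1 Receptor Antagonists" in shared_cats


def test_ketogenic_diet_treatment_has_no_candidates_on_any_route(fixture_kb):
    t = fixture_kb.resolve_treatment(
        "Ketogenic diet+modified Atkins diet+low glycemic index treatments"
    )
    for route in ("categories", "targets", "pathways"):
        cs = candidates_by_route(t, fixture_kb, route)
        assert cs.candidates == set()
        # all three diet components lack data on every route
        assert len(cs.missing_components) == 3


def test_risperidone_pathway_candidates_are_its_smpdb_co_members(fixture_kb):
    t = fixture_kb.resolve_treatment("Sulforaphane+risperidone")
    cs = candidates_by_pathway(t, fixture_kb)
    assert _names(fixture_kb, cs) == {"Calcium", "Carbon dioxide"}
    missing = {fixture_kb.compounds[c].preferred_name for c in cs.missing_components}
    assert missing == {"Sulforaphane"}  # no pathway record: explicit marker


def test_sulforaphane_alone_has_no_target_candidates(fixture_kb):
    t = fixture_kb.resolve_treatment("Sulforaphane")
    assert candidates_by_target(t, fixture_kb).candidates == set()


def test_five_meo_dmt_appears_for_any_risperidone_treatment(fixture_kb):
    for label in ("Fluoxetine+risperidone", "Memantine+risperidone"):
        t = fixture_kb.resolve_treatment(label)
        assert "5-methoxy-N, N-dimethyltryptamine" in _names(
            fixture_kb, candidates_by_target(t, fixture_kb)
        )


def _brute_force(kb, treatment, route):
    """Independent double loop over raw edge tuples."""
    edges = {
        "categories": kb.assoc.category_edges,
        "targets": kb.assoc.target_edges,
        "pathways": kb.assoc.smpdb_edges,
    }[route]
    comps = set(treatment.components)
    mine = {i for d, i in edges if d in comps}
    out = set()
    for d, i in edges:
        if d not in comps and i in mine:
            out.add(d)
    return out


@pytest.mark.parametrize("seed", [0, 7, 17, 99])
def test_pipeline_equals_brute_force_on_synthetic_kbs(tmp_path, seed):
    paths, _ = generate(
        GeneratorParams(n_drugs=60, n_treatments=8, seed=seed), tmp_path / str(seed)
    )
    kb, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])
    load_treatments(paths["treatments"], kb)
    for t in kb.treatments.values():
        for route in ("categories", "targets", "pathways"):
            cs = candidates_by_route(t, kb, route)
            assert cs.candidates == _brute_force(kb, t, route)
            assert not cs.candidates & set(t.components)
            for cand, via in cs.via.items():
                assert via  # every candidate is justified


def test_combination_candidates_are_union_of_components(fixture_kb):
    combo = fixture_kb.resolve_treatment("Fluoxetine+risperidone+melatonin")
    for route in ("categories", "targets", "pathways"):
        combo_set = candidates_by_route(combo, fixture_kb, route).candidates
        union = set()
        for cid in combo.components:
            single = Treatment("tmp", "single", [cid])
            union |= candidates_by_route(single, fixture_kb, route).candidates
        assert combo_set == union - set(combo.components)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_candidates_never_include_components(tmp_path_factory, seed):
    tmp = tmp_path_factory.mktemp("fuzz")
    paths, truth = generate(
        GeneratorParams(n_drugs=25, n_treatments=5, seed=seed), tmp
    )
    kb, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])
    load_treatments(paths["treatments"], kb)
    for t in kb.treatments.values():
        for route in ("categories", "targets", "pathways"):
            cs = candidates_by_route(t, kb, route)
            assert not cs.candidates & set(t.components)


def test_count_report_totals_and_global_row(fixture_kb):
    df = count_report(fixture_kb)
    g = df[df.treatment == "Global"]
    assert len(g) == 1
    per_treatment = df[df.treatment != "Global"]
    # one row per (treatment, component) as laid out in the published table
    assert len(per_treatment) == sum(
        len(t.components) for t in fixture_kb.treatments.values()
    )
    # deduplicated union can never exceed the sum over treatments
    for route in ("categories", "targets", "pathways"):
        col = f"candidates_by_{route}"
        total = sum(
            len(candidates_by_route(t, fixture_kb, route).candidates)
            for t in fixture_kb.treatments.values()
        )
        assert int(g[col].iloc[0]) <= total
    # a compound's printed totals equal its raw edge counts
    risp = fixture_kb.resolve_name("Risperidone")
    row = per_treatment[per_treatment.compound == "Risperidone"].iloc[0]
    assert row.categories_total == sum(
        1 for c, _ in fixture_kb.assoc.category_edges if c == risp
    )
    assert row.targets_total == sum(
        1 for c, _ in fixture_kb.assoc.target_edges if c == risp
    )


def test_count_report_on_edgeless_kb_is_all_zero():
    from neurorepo import KnowledgeBase

    kb = KnowledgeBase()
    cid = kb.register_compound("Lonelyol")
    kb.register_treatment("Lonelyol", [cid])
    df = count_report(kb)
    numeric = df[df.treatment != "Global"].iloc[0]
    assert (
        numeric[
            [
                "categories_total",
                "targets_total",
                "pathways_total",
                "candidates_by_categories",
                "candidates_by_targets",
                "candidates_by_pathways",
            ]
        ]
        == 0
    ).all()
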