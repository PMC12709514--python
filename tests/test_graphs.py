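"""Typed graph views: structure, worked examples, determinism, serialization."""

import re

import networkx as nx
import pytest

from neurorepo import (
    GeneratorParams,
    KnowledgeBase,
    build_category_graph,
    build_kb,
    build_pathway_graph,
    build_target_graph,
    build_view,
    check_graph,
    export_graph,
    generate,
    import_graph,
    load_treatments,
)


@pytest.fixture(scope="module")
def sulf_risp(fixture_kb):
    return fixture_kb.resolve_treatment("Sulforaphane+risperidone")


def test_all_views_satisfy_structural_invariants(fixture_kb, rules):
    for t in fixture_kb.treatments.values():
        for view in ("categories", "pathways", "targets"):
            g = build_view(t, fixture_kb, view, rules, max_assoc=2)
            check_graph(g)  # acyclic, layer-monotone, reachable
            assert nx.is_directed_acyclic_graph(g)


def test_category_graph_worked_example(fixture_kb, sulf_risp):
    g = build_category_graph(sulf_risp, fixture_kb, max_assoc=2)
    assert g.has_edge(
        "compound::Risperidone", "category::Adrenergic alpha-1 Receptor Antagonists"
    )
    assert g.has_edge(
        "category::Adrenergic alpha-1 Receptor Antagonists", "drug::Alfuzosin"
    )
    assert g.has_edge("category::Antineoplastic Agents", "drug::10-Hydroxycamptothecin")
    effects = g.nodes["effects"]
    assert effects["type"] == "effect_box"
    assert "improvements in irritability" in effects["label"]


def test_zero_max_assoc_keeps_skeleton(fixture_kb, sulf_risp):
    g0 = build_category_graph(sulf_risp, fixture_kb, max_assoc=0)
    g2 = build_category_graph(sulf_risp, fixture_kb, max_assoc=2)
    assert not [n for n, d in g0.nodes(data=True) if d["type"] == "associated_drug"]
    skeleton = lambda g: {
        n for n, d in g.nodes(data=True) if d["type"] != "associated_drug"
    }
    assert skeleton(g0) == skeleton(g2)


def test_associated_drug_selection_is_lexicographic():
    kb = KnowledgeBase()
    comp = kb.register_compound("Anchor")
    cat_ids = [kb.register_category(f"Category {i}") for i in range(3)]
    for c in cat_ids:
        kb.add_category_edge(comp, c)
    for i in range(3):
        for j in range(5):
            d = kb.register_compound(f"Drug {i}{j}")
            kb.add_category_edge(d, cat_ids[i])
    tid = kb.register_treatment("Anchor", [comp])
    g = build_category_graph(kb.treatments[tid], kb, max_assoc=2)
    assoc = sorted(
        d["label"] for n, d in g.nodes(data=True) if d["type"] == "associated_drug"
    )
    # the lexicographically first two of each category's five members
    assert assoc == ["Drug 00", "Drug 01", "Drug 10", "Drug 11", "Drug 20", "Drug 21"]


def test_pathway_graph_worked_example(fixture_kb, rules, sulf_risp):
    g = build_pathway_graph(sulf_risp, fixture_kb, rules)
    # compound without pathway data carries an explicit question-mark node
    assert g.nodes["missing::Sulforaphane"]["type"] == "missing_data"
    assert g.has_edge("compound::Sulforaphane", "missing::Sulforaphane")
    # risperidone's curated action reaches the neurotransmitter pathway node
    kw = "kw::Risperidone::inhibiting D2 dopaminergic receptors"
    gp = "gp::Risperidone::neurotransmitter_regulation"
    assert g.has_edge("compound::Risperidone", kw)
    assert g.has_edge(kw, gp)
    # SMPDB co-members appear as associated drugs
    assert g.nodes["drug::Calcium"]["type"] == "associated_drug"


def test_target_graph_worked_example(fixture_kb, sulf_risp):
    g = build_target_graph(sulf_risp, fixture_kb, max_assoc=2)
    assert g.nodes["missing::Inactive rhomboid protein 2"]["type"] == "missing_data"
    assert g.has_edge(
        "target::5-hydroxytryptamine receptor 1A",
        "drug::5-methoxy-N, N-dimethyltryptamine",
    )


def test_compound_without_targets_contributes_no_target_nodes(fixture_kb):
    t = fixture_kb.resolve_treatment("Vitamin D3")
    g = build_target_graph(t, fixture_kb, max_assoc=2)
    assert not [n for n, d in g.nodes(data=True) if d["type"] == "target"]
    check_graph(g)


def test_bare_treatment_pathway_graph_has_minimal_node_types(fixture_kb, rules):
    t = fixture_kb.resolve_treatment("Umbilical cord blood infusion")
    g = build_pathway_graph(t, fixture_kb, rules)
    types = {d["type"] for _, d in g.nodes(data=True)}
    assert types == {"treatment", "compound", "missing_data", "effect_box"}


def test_associated_drugs_never_duplicate_components(fixture_kb, rules):
    for t in fixture_kb.treatments.values():
        comp_names = {fixture_kb.compounds[c].preferred_name for c in t.components}
        for view in ("categories", "pathways", "targets"):
            g = build_view(t, fixture_kb, view, rules, 2)
            assoc = {
                d["label"] for _, d in g.nodes(data=True)
                if d["type"] == "associated_drug"
            }
            assert not assoc & comp_names


def test_builds_are_deterministic_across_runs(fixture_kb, rules, sulf_risp, tmp_path):
    for view in ("categories", "pathways", "targets"):
        a = export_graph(
            build_view(sulf_risp, fixture_kb, view, rules, 2), "json",
            tmp_path / f"a.{view}.json",
        )
        b = export_graph(
            build_view(sulf_risp, fixture_kb, view, rules, 2), "json",
            tmp_path / f"b.{view}.json",
        )
        assert a.read_bytes() == b.read_bytes()


@pytest.mark.parametrize("fmt", ["graphml", "json"])
def test_export_round_trip_is_lossless(fixture_kb, rules, sulf_risp, tmp_path, fmt):
    g = build_view(sulf_risp, fixture_kb, "targets", rules, 2)
    path = export_graph(g, fmt, tmp_path / f"g.{fmt}")
    h = import_graph(fmt, path)
    assert set(g.nodes) == set(h.nodes)
    assert set(g.edges) == set(h.edges)
    for n in g.nodes:
        assert g.nodes[n] == h.nodes[n]
    for e in g.edges:
        assert g.edges[e] == h.edges[e]


_DOT_NODE = re.compile(r'^\s*"[^"]*" \[label=.*\];$')
_DOT_EDGE = re.compile(r'^\s*"[^"]*" -> "[^"]*" \[label=.*\];$')


def test_dot_export_parses_under_simple_grammar(fixture_kb, rules, sulf_risp, tmp_path):
    path = export_graph(
        build_view(sulf_risp, fixture_kb, "categories", rules, 2), "dot",
        tmp_path / "g.dot",
    )
    lines = path.read_text(encoding="utf-8").splitlines()
    assert lines[0].startswith("digraph ") and lines[-1] == "}"
    for line in lines[1:-1]:
        assert _DOT_NODE.match(line) or _DOT_EDGE.match(line), line


def test_unknown_format_is_a_usage_error(fixture_kb, rules, sulf_risp, tmp_path):
    g = build_view(sulf_risp, fixture_kb, "categories", rules, 2)
    with pytest.raises(ValueError, match="format"):
        export_graph(g, "pdf", tmp_path / "g.pdf")


def test_synthetic_graph_counts_match_generator_formula(tmp_path, rules):
    paths, truth = generate(
        GeneratorParams(n_drugs=30, n_treatments=6, seed=5), tmp_path
    )
    kb, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])
    load_treatments(paths["treatments"], kb)
    for label, views in truth.graph_counts.items():
        t = kb.resolve_treatment(label)
        for view, expected in views.items():
            g = build_view(t, kb, view, rules, max_assoc=2)
            assert (len(g.nodes), len(g.edges)) == (
                expected["nodes"],
                expected["edges"],
            ), (label, view)
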