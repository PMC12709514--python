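"""Layered, typed knowledge-graph views per treatment.

Three views are built per treatment, each a DAG flowing from the treatment
node down fixed layers to a reported-effects box:

* ``categories`` — treatment(0) → compound(1) → therapeutic category(2) →
  associated drug(3); categories converge into the effects box(4).
* ``pathways``  — treatment(0) → compound(1) → action keyword / SMPDB
  pathway / missing-data marker(2) → per-compound global pathway or SMPDB
  co-member drug(3); global pathways converge into the effects box(4).
* ``targets``   — treatment(0) → compound(1) → proteomic target(2) →
  target-associated drug or missing-data marker(3) → effects box(4).

Associated drugs are capped at ``max_assoc`` per anchor (a display cap,
default 2), chosen lexicographically by normalized name so builds are
reproducible; treatment components are never listed as associated drugs.
Absent data is rendered explicitly as a ``missing_data`` node (the
"question mark"), never silently dropped.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .kb import KnowledgeBase, Treatment
from .pathways import ClassificationRule, classify_compound

NODE_TYPES = {
    "treatment",
    "compound",
    "category",
    "action_keyword",
    "global_pathway",
    "smpdb_pathway",
    "target",
    "associated_drug",
    "effect_box",
    "missing_data",
}

VIEWS = ("categories", "pathways", "targets")

EFFECT_NODE = "effects"


class GraphInvariantError(Exception):
    pass


def _new_graph(view: str, treatment: Treatment) -> nx.DiGraph:
    g = nx.DiGraph(view=view, treatment=treatment.label)
    g.add_node(
        f"treatment::{treatment.label}",
        type="treatment",
        label=treatment.label,
        layer=0,
    )
    return g


def _add(g, node_id, ntype, label, layer):
    if node_id not in g:
        g.add_node(node_id, type=ntype, label=label, layer=layer)
    return node_id


def _finish(g: nx.DiGraph, treatment: Treatment, effect_layer: int) -> nx.DiGraph:
    label = "; ".join(sorted(treatment.reported_effects))
    _add(g, EFFECT_NODE, "effect_box", label, effect_layer)
    g.nodes[EFFECT_NODE]["label"] = label
    if g.in_degree(EFFECT_NODE) == 0:
        # degenerate treatment with no associations on this view: the
        # effects box still aggregates from the compound layer
        for n, d in sorted(g.nodes(data=True)):
            if d["type"] == "compound":
                g.add_edge(n, EFFECT_NODE, edge_type="reports")
        if g.in_degree(EFFECT_NODE) == 0:
            g.add_edge(f"treatment::{treatment.label}", EFFECT_NODE, edge_type="reports")
    check_graph(g)
    return g


def _assoc_pick(
    kb: KnowledgeBase, members: set[str], components: set[str], max_assoc: int
) -> list[str]:
    """Deterministic lexicographic selection of non-component co-drugs."""
    pool = sorted(
        (kb.compounds[c].preferred_name for c in members - components),
        key=str.lower,
    )
    return pool[:max_assoc]


def build_category_graph(
    treatment: Treatment, kb: KnowledgeBase, max_assoc: int = 2
) -> nx.DiGraph:
    if max_assoc < 0:
        raise ValueError("max_assoc must be >= 0")
    g = _new_graph("categories", treatment)
    troot = f"treatment::{treatment.label}"
    components = set(treatment.components)
    members_of: dict[str, set[str]] = {}
    for d, c in kb.assoc.category_edges:
        members_of.setdefault(c, set()).add(d)
    for cid in treatment.components:
        comp = kb.compounds[cid]
        cnode = _add(g, f"compound::{comp.preferred_name}", "compound",
                     comp.preferred_name, 1)
        g.add_edge(troot, cnode, edge_type="has_component")
        cats = sorted(
            (c for d, c in kb.assoc.category_edges if d == cid),
            key=lambda c: kb.categories[c].name.lower(),
        )
        for cat_id in cats:
            cat = kb.categories[cat_id]
            knode = _add(g, f"category::{cat.name}", "category", cat.name, 2)
            g.add_edge(cnode, knode, edge_type="in_category")
            for name in _assoc_pick(kb, members_of[cat_id], components, max_assoc):
                anode = _add(g, f"drug::{name}", "associated_drug", name, 3)
                g.add_edge(knode, anode, edge_type="shares_category")
    for n, d in list(g.nodes(data=True)):
        if d["type"] == "category":
            _add(g, EFFECT_NODE, "effect_box", "", 4)
            g.add_edge(n, EFFECT_NODE, edge_type="reports")
    return _finish(g, treatment, 4)


def build_pathway_graph(
    treatment: Treatment, kb: KnowledgeBase, rules: list[ClassificationRule]
) -> nx.DiGraph:
    g = _new_graph("pathways", treatment)
    troot = f"treatment::{treatment.label}"
    components = set(treatment.components)
    for cid in treatment.components:
        comp = kb.compounds[cid]
        cnode = _add(g, f"compound::{comp.preferred_name}", "compound",
                     comp.preferred_name, 1)
        g.add_edge(troot, cnode, edge_type="has_component")
        keywords = sorted(kb.compound_keywords.get(cid, set()))
        profile = classify_compound(cid, keywords, rules)
        for kw in keywords:
            knode = _add(g, f"kw::{comp.preferred_name}::{kw}", "action_keyword", kw, 2)
            g.add_edge(cnode, knode, edge_type="has_action")
            for pw in sorted(profile.evidence, key=lambda p: p.value):
                if kw in profile.evidence[pw]:
                    gnode = _add(
                        g,
                        f"gp::{comp.preferred_name}::{pw.value}",
                        "global_pathway",
                        pw.value,
                        3,
                    )
                    g.add_edge(knode, gnode, edge_type="aligns_with")
        smpdb = sorted(
            (p for d, p in kb.assoc.smpdb_edges if d == cid),
            key=lambda p: kb.pathways[p].name.lower(),
        )
        if smpdb:
            for pid in smpdb:
                rec = kb.pathways[pid]
                snode = _add(g, f"smpdb::{pid}", "smpdb_pathway", rec.name, 2)
                g.add_edge(cnode, snode, edge_type="in_pathway")
                for name in sorted(
                    (kb.compounds[d].preferred_name
                     for d in rec.member_drugs - components),
                    key=str.lower,
                ):
                    anode = _add(g, f"drug::{name}", "associated_drug", name, 3)
                    g.add_edge(snode, anode, edge_type="shares_pathway")
        else:
            mnode = _add(
                g, f"missing::{comp.preferred_name}", "missing_data", "?", 2
            )
            g.add_edge(cnode, mnode, edge_type="no_data")
    for n, d in list(g.nodes(data=True)):
        if d["type"] == "global_pathway":
            _add(g, EFFECT_NODE, "effect_box", "", 4)
            g.add_edge(n, EFFECT_NODE, edge_type="reports")
    return _finish(g, treatment, 4)


def build_target_graph(
    treatment: Treatment, kb: KnowledgeBase, max_assoc: int = 2
) -> nx.DiGraph:
    if max_assoc < 0:
        raise ValueError("max_assoc must be >= 0")
    g = _new_graph("targets", treatment)
    troot = f"treatment::{treatment.label}"
    components = set(treatment.components)
    drugs_of: dict[str, set[str]] = {}
    for d, t in kb.assoc.target_edges:
        drugs_of.setdefault(t, set()).add(d)
    for cid in treatment.components:
        comp = kb.compounds[cid]
        cnode = _add(g, f"compound::{comp.preferred_name}", "compound",
                     comp.preferred_name, 1)
        g.add_edge(troot, cnode, edge_type="has_component")
        tgts = sorted(
            (t for d, t in kb.assoc.target_edges if d == cid),
            key=lambda t: kb.targets[t].name.lower(),
        )
        for tgt_id in tgts:
            tgt = kb.targets[tgt_id]
            tnode = _add(g, f"target::{tgt.name}", "target", tgt.name, 2)
            g.add_edge(cnode, tnode, edge_type="targets")
            others = drugs_of[tgt_id] - components
            if not others:
                mnode = _add(g, f"missing::{tgt.name}", "missing_data", "?", 3)
                g.add_edge(tnode, mnode, edge_type="no_data")
            else:
                for name in _assoc_pick(kb, drugs_of[tgt_id], components, max_assoc):
                    anode = _add(g, f"drug::{name}", "associated_drug", name, 3)
                    g.add_edge(tnode, anode, edge_type="shares_target")
    for n, d in list(g.nodes(data=True)):
        if d["type"] == "target":
            _add(g, EFFECT_NODE, "effect_box", "", 4)
            g.add_edge(n, EFFECT_NODE, edge_type="reports")
    return _finish(g, treatment, 4)


def build_view(
    treatment: Treatment,
    kb: KnowledgeBase,
    view: str,
    rules: list[ClassificationRule] | None = None,
    max_assoc: int = 2,
) -> nx.DiGraph:
    if view == "categories":
        return build_category_graph(treatment, kb, max_assoc)
    if view == "targets":
        return build_target_graph(treatment, kb, max_assoc)
    if view == "pathways":
        if rules is None:
            raise ValueError("pathway view needs a rule table")
        return build_pathway_graph(treatment, kb, rules)
    raise ValueError(f"unknown view {view!r}")


def check_graph(g: nx.DiGraph) -> None:
    """Enforce the structural invariants of a typed view graph.

    Acyclic; every edge strictly increases layer; every non-treatment node
    reachable from the treatment node; node types within the closed set;
    missing-data nodes have incoming edges and no outgoing ones.
    """
    if not nx.is_directed_acyclic_graph(g):
        raise GraphInvariantError("graph contains a cycle")
    roots = [n for n, d in g.nodes(data=True) if d["type"] == "treatment"]
    if len(roots) != 1:
        raise GraphInvariantError(f"expected one treatment node, got {len(roots)}")
    for u, v in g.edges():
        if g.nodes[v]["layer"] <= g.nodes[u]["layer"]:
            raise GraphInvariantError(f"edge {u}->{v} does not increase layer")
    reachable = nx.descendants(g, roots[0]) | {roots[0]}
    missing = set(g.nodes) - reachable
    if missing:
        raise GraphInvariantError(f"unreachable nodes: {sorted(missing)}")
    for n, d in g.nodes(data=True):
        if d["type"] not in NODE_TYPES:
            raise GraphInvariantError(f"unknown node type {d['type']!r} on {n}")
        if d["type"] == "missing_data":
            if g.in_degree(n) < 1 or g.out_degree(n) != 0:
                raise GraphInvariantError(f"missing_data node {n} degree violation")


# -- serialization ----------------------------------------------------


def graph_to_json(g: nx.DiGraph) -> dict:
    """Canonical JSON document: sorted nodes and edges, typed attributes."""
    return {
        "view": g.graph["view"],
        "treatment": g.graph["treatment"],
        "directed": True,
        "nodes": [
            {
                "id": n,
                "type": d["type"],
                "label": d["label"],
                "layer": d["layer"],
            }
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v, "edge_type": d.get("edge_type", "")}
            for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))
        ],
    }


def graph_from_json(doc: dict) -> nx.DiGraph:
    g = nx.DiGraph(view=doc["view"], treatment=doc["treatment"])
    for n in doc["nodes"]:
        g.add_node(n["id"], type=n["type"], label=n["label"], layer=int(n["layer"]))
    for e in doc["edges"]:
        g.add_edge(e["source"], e["target"], edge_type=e["edge_type"])
    return g


def _sorted_copy(g: nx.DiGraph) -> nx.DiGraph:
    h = nx.DiGraph(**g.graph)
    for n, d in sorted(g.nodes(data=True)):
        h.add_node(n, **d)
    for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
        h.add_edge(u, v, **d)
    return h


def graph_to_dot(g: nx.DiGraph) -> str:
    """Minimal DOT serialization (typed attributes as quoted strings)."""

    def q(s: str) -> str:
        return '"' + str(s).replace("\\", "\\\\").replace('"', '\\"') + '"'

    lines = [f"digraph {q(g.graph['view'])} {{"]
    for n, d in sorted(g.nodes(data=True)):
        lines.append(
            f"  {q(n)} [label={q(d['label'])}, type={q(d['type'])}, "
            f"layer={q(d['layer'])}];"
        )
    for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1])):
        lines.append(f"  {q(u)} -> {q(v)} [label={q(d.get('edge_type', ''))}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graph(g: nx.DiGraph, fmt: str, path: str | Path) -> Path:
    """Write the graph to *path* in graphml, json or dot form.

    graphml and json round-trip losslessly (types and layers preserved as
    attributes); node ordering is deterministic in every format.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_sorted_copy(g), path)
    elif fmt == "json":
        path.write_text(
            json.dumps(graph_to_json(g), indent=1, sort_keys=True) + "\n",
            encoding="utf-8",
        )
    elif fmt == "dot":
        path.write_text(graph_to_dot(g), encoding="utf-8")
    else:
        raise ValueError(f"unknown format {fmt!r} (expected graphml, json or dot)")
    return path


def import_graph(fmt: str, path: str | Path) -> nx.DiGraph:
    path = Path(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph(view=g.graph.get("view"), treatment=g.graph.get("treatment"))
        for n, d in g.nodes(data=True):
            out.add_node(n, type=d["type"], label=d["label"], layer=int(d["layer"]))
        for u, v, d in g.edges(data=True):
            out.add_edge(u, v, edge_type=d.get("edge_type", ""))
        return out
    if fmt == "json":
        return graph_from_json(json.loads(path.read_text(encoding="utf-8")))
    raise ValueError(f"unknown import format {fmt!r}")
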