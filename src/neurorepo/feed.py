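"""Dashboard JSON feed: the single document an interactive front end consumes.

The feed bundles, per treatment, the candidate lists for each association
route, the full pairwise shared-target matrix, and the three typed graph
documents.  The document is validated against a pydantic schema before it
is returned, and serialized with sorted keys so regeneration from an
unchanged store is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict

from .graphs import build_view, graph_to_json
from .kb import KnowledgeBase
from .pathways import ClassificationRule
from .repositioning import ROUTES, candidates_by_route
from .shared_targets import pairwise_matrix


class GraphNodeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    type: str
    label: str
    layer: int


class GraphEdgeModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    source: str
    target: str
    edge_type: str


class GraphDocModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    view: str
    treatment: str
    directed: bool
    nodes: list[GraphNodeModel]
    edges: list[GraphEdgeModel]


class TreatmentEntryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    components: list[str]
    effects: list[str]
    candidates: dict[str, list[str]]
    graphs: dict[str, GraphDocModel]


class SharedEntryModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    main: str
    comparator: str
    count: int
    target_names: list[str]


class DashboardFeedModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    treatments: list[TreatmentEntryModel]
    shared_targets: list[SharedEntryModel]
    summary: dict[str, int]


def export_dashboard_feed(
    kb: KnowledgeBase,
    rules: list[ClassificationRule],
    max_assoc: int = 2,
) -> dict:
    """Build and schema-validate the full dashboard document."""
    treatments = sorted(kb.treatments.values(), key=lambda t: t.label.lower())
    entries = []
    for t in treatments:
        cands = {}
        for route in ROUTES:
            cs = candidates_by_route(t, kb, route)
            cands[route] = [
                kb.compounds[c].preferred_name for c in cs.sorted_candidates(kb)
            ]
        entries.append(
            {
                "label": t.label,
                "components": [kb.compounds[c].preferred_name for c in t.components],
                "effects": sorted(t.reported_effects),
                "candidates": cands,
                "graphs": {
                    view: graph_to_json(build_view(t, kb, view, rules, max_assoc))
                    for view in ("categories", "pathways", "targets")
                },
            }
        )
    shared_entries = []
    for t in treatments:
        for r in pairwise_matrix(t, [u for u in treatments if u is not t], kb):
            shared_entries.append(
                {
                    "main": r.main_label,
                    "comparator": r.comparator_label,
                    "count": r.count,
                    "target_names": r.target_names,
                }
            )
    cat = {c for c, _ in kb.assoc.category_edges}
    tgt = {c for c, _ in kb.assoc.target_edges}
    pwy = {c for c, _ in kb.assoc.smpdb_edges}
    components = {c for t in treatments for c in t.components}
    feed = {
        "treatments": entries,
        "shared_targets": shared_entries,
        "summary": {
            "n_treatments": len(treatments),
            "n_component_compounds": len(components),
            "n_compounds": len(kb.compounds),
            "n_components_with_categories": len(components & cat),
            "n_components_with_targets": len(components & tgt),
            "n_components_with_smpdb": len(components & pwy),
        },
    }
    DashboardFeedModel.model_validate(feed)
    return feed


def write_feed(feed: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(feed, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path
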