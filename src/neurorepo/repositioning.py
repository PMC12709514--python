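"""Repositioning-candidate enumeration through the three association routes.

A candidate for a treatment is any registered compound that shares at
least one therapeutic category, proteomic target, or pathway with at least
one of the treatment's components, excluding the components themselves.
Combination treatments behave as the union of their components: the
candidate set of a combination equals the union of its components'
candidate sets minus the combination's own components.

Candidates are enumerated, not ranked — no scoring is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .kb import KnowledgeBase, Treatment

ROUTES = ("categories", "targets", "pathways")


@dataclass
class CandidateSet:
    treatment_id: str
    route: str
    candidates: set[str] = field(default_factory=set)
    via: dict[str, set[str]] = field(default_factory=dict)
    # components that carry no association data on this route at all
    # (rendered as "question mark" nodes in the graph views)
    missing_components: set[str] = field(default_factory=set)

    def sorted_candidates(self, kb: KnowledgeBase) -> list[str]:
        """Candidate ids in normalized-name lexicographic order."""
        return sorted(
            self.candidates, key=lambda c: kb.compounds[c].preferred_name.lower()
        )


def _edges_for_route(kb: KnowledgeBase, route: str) -> set[tuple[str, str]]:
    if route == "categories":
        return kb.assoc.category_edges
    if route == "targets":
        return kb.assoc.target_edges
    if route == "pathways":
        return kb.assoc.smpdb_edges
    raise ValueError(f"unknown route {route!r}")


def candidates_by_route(
    treatment: Treatment, kb: KnowledgeBase, route: str
) -> CandidateSet:
    """Shared-association candidate enumeration for one route."""
    edges = _edges_for_route(kb, route)
    components = set(treatment.components)
    assoc_of: dict[str, set[str]] = {}
    for drug, item in edges:
        assoc_of.setdefault(drug, set()).add(item)
    component_items: set[str] = set()
    missing = set()
    for cid in components:
        items = assoc_of.get(cid, set())
        if not items:
            missing.add(cid)
        component_items |= items
    result = CandidateSet(treatment.treatment_id, route, missing_components=missing)
    for drug, items in assoc_of.items():
        if drug in components:
            continue
        shared = items & component_items
        if shared:
            result.candidates.add(drug)
            result.via[drug] = shared
    return result


def candidates_by_category(treatment: Treatment, kb: KnowledgeBase) -> CandidateSet:
    return candidates_by_route(treatment, kb, "categories")


def candidates_by_target(treatment: Treatment, kb: KnowledgeBase) -> CandidateSet:
    return candidates_by_route(treatment, kb, "targets")


def candidates_by_pathway(treatment: Treatment, kb: KnowledgeBase) -> CandidateSet:
    return candidates_by_route(treatment, kb, "pathways")


def count_report(kb: KnowledgeBase) -> pd.DataFrame:
    """Per-(treatment, compound) association totals and candidate counts.

    One row per component compound of each treatment: the compound's edge
    totals on each route plus the candidate count of the single-compound
    sub-treatment (a combination's components are reported individually).
    A final Global row holds, per route, the size of the union over all
    treatments of the treatment-level candidate sets.
    """
    cat_of: dict[str, set[str]] = {}
    for d, c in kb.assoc.category_edges:
        cat_of.setdefault(d, set()).add(c)
    tgt_of: dict[str, set[str]] = {}
    for d, t in kb.assoc.target_edges:
        tgt_of.setdefault(d, set()).add(t)
    pwy_of: dict[str, set[str]] = {}
    for d, p in kb.assoc.smpdb_edges:
        pwy_of.setdefault(d, set()).add(p)

    def single(cid: str, route: str) -> set[str]:
        pseudo = Treatment("tmp", kb.compounds[cid].preferred_name, [cid])
        return candidates_by_route(pseudo, kb, route).candidates

    rows = []
    global_union: dict[str, set[str]] = {r: set() for r in ROUTES}
    for t in sorted(kb.treatments.values(), key=lambda t: t.label.lower()):
        for route in ROUTES:
            global_union[route] |= candidates_by_route(t, kb, route).candidates
        for cid in t.components:
            c = kb.compounds[cid]
            rows.append(
                {
                    "treatment": t.label,
                    "compound": c.preferred_name,
                    "categories_total": len(cat_of.get(cid, ())),
                    "targets_total": len(tgt_of.get(cid, ())),
                    "pathways_total": len(pwy_of.get(cid, ())),
                    "candidates_by_categories": len(single(cid, "categories")),
                    "candidates_by_targets": len(single(cid, "targets")),
                    "candidates_by_pathways": len(single(cid, "pathways")),
                }
            )
    rows.append(
        {
            "treatment": "Global",
            "compound": "All",
            "categories_total": None,
            "targets_total": None,
            "pathways_total": None,
            "candidates_by_categories": len(global_union["categories"]),
            "candidates_by_targets": len(global_union["targets"]),
            "candidates_by_pathways": len(global_union["pathways"]),
        }
    )
    return pd.DataFrame(rows)
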