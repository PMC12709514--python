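"""Curated treatments layer: the manually extracted intervention records.

The treatments file is JSON with one record per intervention::

    {"treatments": [
        {"label": "Sulforaphane+risperidone",
         "components": ["Sulforaphane", "Risperidone"],
         "effects": ["improvements in irritability and ..."],
         "keywords": {"Sulforaphane": ["inhibiting nuclear factor kappa B"]},
         "synonyms": {"Doconexent": ["DHA"]},
         "design": "randomized controlled trial",
         "refs": ["study-12"]}
    ]}

Components are listed explicitly rather than derived by splitting the
label: label-to-compound mapping is many-to-one and irregular (combination
labels use "+", but aliases like "DHA; an omega-3 fatty acid" do not split
mechanically).  Reported effects are free-text phrases as printed — no
controlled vocabulary exists for them.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .ingest import FormatError
from .kb import Compound, KnowledgeBase, Treatment


def load_treatments(path: str | Path, kb: KnowledgeBase) -> list[Treatment]:
    """Register every treatment record from *path* into *kb*.

    Components are resolved against the registry or created as local
    compounds; per-component action keywords are attached for the pathway
    classifier.  Duplicate labels collapse by idempotent upsert.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    records = doc.get("treatments")
    if not isinstance(records, list):
        raise FormatError(f"{Path(path).name}: expected top-level 'treatments' list")
    out: list[Treatment] = []
    seen: set[str] = set()
    for rec in records:
        label = (rec.get("label") or "").strip()
        components = rec.get("components") or []
        if not label:
            raise FormatError("treatment record with empty label")
        if not components:
            raise FormatError(f"treatment {label!r} has empty components")
        synonyms = rec.get("synonyms") or {}
        cids = []
        for name in components:
            cid = kb.resolve_name(name) or kb.register_compound(name)
            if synonyms.get(name):
                kb.register_compound(name, set(synonyms[name]))
            cids.append(cid)
        tid = kb.register_treatment(
            label,
            cids,
            set(rec.get("effects") or ()),
            set(rec.get("refs") or ()),
        )
        for comp_name, kws in (rec.get("keywords") or {}).items():
            cid = kb.resolve_name(comp_name)
            if cid is None:
                raise FormatError(
                    f"treatment {label!r}: keywords for unknown component {comp_name!r}"
                )
            kb.add_keywords(cid, set(kws))
        if tid not in seen:
            seen.add(tid)
            out.append(kb.treatments[tid])
    return out


def expand_components(treatment: Treatment, kb: KnowledgeBase) -> list[Compound]:
    """Component compound records in label order."""
    from .kb import IntegrityError

    out = []
    for cid in treatment.components:
        if cid not in kb.compounds:
            raise IntegrityError(
                f"treatment {treatment.label!r}: dangling component {cid}"
            )
        out.append(kb.compounds[cid])
    return out


def availability_summary(kb: KnowledgeBase) -> pd.DataFrame:
    """Per-compound data-availability flags over the treatment components.

    One row per distinct component compound, flags true iff the compound
    carries at least one edge of the corresponding kind.  A pure function
    of the association tables: recomputation after a store round trip is
    identical.
    """
    cat = {c for c, _ in kb.assoc.category_edges}
    tgt = {c for c, _ in kb.assoc.target_edges}
    pwy = {c for c, _ in kb.assoc.smpdb_edges}
    rows = []
    for cid in sorted(kb.compounds):
        c = kb.compounds[cid]
        if not c.is_kb_component:
            continue
        rows.append(
            {
                "compound_id": cid,
                "name": c.preferred_name,
                "has_categories": cid in cat,
                "has_targets": cid in tgt,
                "has_smpdb": cid in pwy,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["compound_id", "name", "has_categories", "has_targets", "has_smpdb"],
    )
    return df.sort_values("name", key=lambda s: s.str.lower()).reset_index(drop=True)
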