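"""Pairwise shared proteomic-target analysis between treatments.

A treatment's target set is the union of its components' target edges, so
a combination inherits every target of every component.  The shared-target
result for a pair is the intersection of the two unions, reported as a
count plus the sorted target names.  Zero-overlap pairs are kept by
default (downstream consumers need complete matrices); pass
``nonzero_only=True`` to reproduce the tabular presentation that omits
them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kb import KnowledgeBase, Treatment


@dataclass
class SharedTargetResult:
    main_label: str
    comparator_label: str
    count: int
    target_names: list[str]  # sorted, deduplicated after normalization


def _as_treatment(t: Treatment | str, kb: KnowledgeBase) -> Treatment:
    if isinstance(t, Treatment):
        return t
    found = kb.resolve_treatment(t)
    if found is None:
        raise KeyError(f"unknown treatment {t!r}")
    return found


def target_set(treatment: Treatment | str, kb: KnowledgeBase) -> set[str]:
    """Union over components of the component target-edge sets (target ids)."""
    t = _as_treatment(treatment, kb)
    components = set(t.components)
    return {tid for cid, tid in kb.assoc.target_edges if cid in components}


def shared(
    main: Treatment | str, comparator: Treatment | str, kb: KnowledgeBase
) -> SharedTargetResult:
    """Intersection of two treatments' target sets; symmetric in its arguments."""
    m = _as_treatment(main, kb)
    c = _as_treatment(comparator, kb)
    common = target_set(m, kb) & target_set(c, kb)
    names = sorted(kb.targets[t].name for t in common)
    return SharedTargetResult(m.label, c.label, len(names), names)


def pairwise_matrix(
    main: Treatment | str,
    comparators: list[Treatment | str],
    kb: KnowledgeBase,
    nonzero_only: bool = False,
) -> list[SharedTargetResult]:
    """One shared-target result per comparator, main treatment fixed."""
    out = [shared(main, c, kb) for c in comparators]
    if nonzero_only:
        out = [r for r in out if r.count > 0]
    return out
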