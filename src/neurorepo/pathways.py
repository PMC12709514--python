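"""Keyword-to-pathway classifier over the six predefined mechanism classes.

Compound action phrases curated from the literature (e.g. "inhibiting
nuclear factor kappa B") are mapped onto a closed set of six global
pathways through an explicit, versioned rule table.  Matching is
case-insensitive substring matching on normalized text — deliberately
simple so the rule table itself is the complete, auditable artifact.
A keyword matching no rule yields the empty set and an unmatched flag;
the classifier never guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .kb import GlobalPathway
from .normalize import normalize_name


@dataclass(frozen=True)
class ClassificationRule:
    pattern: str  # lowercase substring over normalized keyword text
    pathway: GlobalPathway
    provenance: str = ""

    def __post_init__(self):
        if not self.pattern.strip():
            raise ValueError("rule pattern must be non-empty")


@dataclass
class PathwayProfile:
    compound_id: str
    pathways: set[GlobalPathway] = field(default_factory=set)
    evidence: dict[GlobalPathway, set[str]] = field(default_factory=dict)
    unmatched: set[str] = field(default_factory=set)


def load_rules(path: str | Path) -> list[ClassificationRule]:
    """Load a rule table: TSV with columns pattern, pathway, provenance."""
    rules = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("pattern", "pathway"):
            if col not in idx:
                from .ingest import FormatError

                raise FormatError(f"rule table missing column {col!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            rules.append(
                ClassificationRule(
                    normalize_name(parts[idx["pattern"]]),
                    GlobalPathway(parts[idx["pathway"]]),
                    parts[idx["provenance"]] if "provenance" in idx and len(parts) > idx["provenance"] else "",
                )
            )
    return rules


def default_rules() -> list[ClassificationRule]:
    """The shipped rule table codifying the curated action assignments."""
    ref = resources.files("neurorepo").joinpath("data/default_rules.tsv")
    with resources.as_file(ref) as path:
        return load_rules(path)


def classify_action(keyword: str, rules: list[ClassificationRule]) -> set[GlobalPathway]:
    """Union of pathways over all rules whose pattern occurs in *keyword*.

    Deterministic and keyword-local; empty set when nothing matches.
    """
    text = normalize_name(keyword)
    return {r.pathway for r in rules if r.pattern in text}


def classify_compound(
    compound_id: str, keywords: set[str] | list[str], rules: list[ClassificationRule]
) -> PathwayProfile:
    """Aggregate per-keyword classifications into a compound profile.

    ``profile.pathways`` is the union over keywords; ``evidence`` maps each
    pathway to the keywords that supported it; keywords matching nothing
    are listed under ``unmatched``.
    """
    profile = PathwayProfile(compound_id)
    for kw in sorted(set(keywords)):
        hit = classify_action(kw, rules)
        if not hit:
            profile.unmatched.add(kw)
            continue
        profile.pathways |= hit
        for p in hit:
            profile.evidence.setdefault(p, set()).add(kw)
    return profile


def validate_rules(rules: list[ClassificationRule]) -> list[str]:
    """Static checks on a rule table; empty report means clean.

    Flags exact duplicate (pattern, pathway) pairs, shadowed rules (a
    pattern containing another pattern that already yields the same
    pathway — the longer rule can never add anything), and rules that
    cite no provenance.
    """
    issues: list[str] = []
    seen: set[tuple[str, GlobalPathway]] = set()
    for r in rules:
        key = (r.pattern, r.pathway)
        if key in seen:
            issues.append(f"duplicate rule: {r.pattern!r} -> {r.pathway.value}")
        seen.add(key)
        if not r.provenance.strip():
            issues.append(f"rule {r.pattern!r} -> {r.pathway.value} cites no provenance")
    for a in rules:
        for b in rules:
            if a.pattern != b.pattern and a.pattern in b.pattern and a.pathway == b.pathway:
                issues.append(
                    f"shadowed rule: {b.pattern!r} is unreachable beyond {a.pattern!r} "
                    f"for {a.pathway.value}"
                )
    return issues


def classify_all(kb, rules: list[ClassificationRule]) -> dict[str, PathwayProfile]:
    """Profile every compound carrying curated action keywords."""
    return {
        cid: classify_compound(cid, kws, rules)
        for cid, kws in sorted(kb.compound_keywords.items())
        if kws
    }
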