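"""Relational knowledge base: entity registry, association tables, SQLite store.

The knowledge base holds five entity kinds — compounds, treatments,
therapeutic categories, proteomic targets and small-molecule pathway
records — plus three deduplicated edge sets linking compounds to
categories, targets and pathways.  Registration is an idempotent upsert
keyed on normalized names, so re-ingesting the same sources is a no-op.

The on-disk form is a single SQLite file (one table per entity kind, three
edge tables, an integer schema version pragma) written deterministically:
saving the same in-memory state always produces byte-identical files.
A plain-text TSV export (one file per table) is provided for diffing.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .normalize import Normalizer, is_drugbank_id, is_smpdb_id, local_id, normalize_name

SCHEMA_VERSION = 1


class IntegrityError(Exception):
    """Raised on merges or edges that would corrupt the registry."""


class GlobalPathway(str, Enum):
    """The six literature-predefined neuroinflammation mechanism classes.

    A closed enumeration: classification output never leaves this set.
    """

    INFLAMMATION = "inflammation"
    IMMUNE_SYSTEM = "immune_system"
    OXIDATIVE_STRESS = "oxidative_stress"
    NEUROTRANSMITTER_REGULATION = "neurotransmitter_regulation"
    GENE_EXPRESSION_REGULATION = "gene_expression_regulation"
    GUT_BRAIN_AXIS = "gut_brain_axis"


@dataclass
class Compound:
    compound_id: str
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    is_kb_component: bool = False

    def names(self) -> set[str]:
        return {self.preferred_name} | self.synonyms


@dataclass
class Treatment:
    treatment_id: str
    label: str
    components: list[str]  # compound_ids, label order
    reported_effects: set[str] = field(default_factory=set)
    study_refs: set[str] = field(default_factory=set)


@dataclass
class TherapeuticCategory:
    category_id: str
    name: str


@dataclass
class ProteomicTarget:
    target_id: str
    name: str
    external_ref: str | None = None


@dataclass
class PathwayRecord:
    pathway_id: str
    name: str
    member_drugs: set[str] = field(default_factory=set)


@dataclass
class AssociationTables:
    category_edges: set[tuple[str, str]] = field(default_factory=set)
    target_edges: set[tuple[str, str]] = field(default_factory=set)
    smpdb_edges: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class Violation:
    kind: str
    message: str
    entity_ids: tuple[str, ...] = ()


class KnowledgeBase:
    """In-memory registry with name indexes and association tables."""

    def __init__(self, normalizer: Normalizer | None = None) -> None:
        self._norm = normalizer or Normalizer()
        self.compounds: dict[str, Compound] = {}
        self.treatments: dict[str, Treatment] = {}
        self.categories: dict[str, TherapeuticCategory] = {}
        self.targets: dict[str, ProteomicTarget] = {}
        self.pathways: dict[str, PathwayRecord] = {}
        self.assoc = AssociationTables()
        # per-compound action keywords from the curated treatments layer
        self.compound_keywords: dict[str, set[str]] = {}
        self._compound_names: dict[str, str] = {}  # normalized name -> id
        self._treatment_labels: dict[str, str] = {}
        self._category_names: dict[str, str] = {}
        self._target_names: dict[str, str] = {}

    # -- registration -------------------------------------------------

    def register_compound(
        self,
        name: str,
        synonyms: set[str] | None = None,
        compound_id: str | None = None,
    ) -> str:
        """Idempotent upsert keyed on any of the compound's normalized names.

        Re-registering under a known name merges synonyms and returns the
        existing identifier.  Two different DrugBank-style accessions
        claiming the same name is an integrity error.
        """
        synonyms = set(synonyms or ())
        keys = {self._norm(n) for n in {name} | synonyms}
        hits = {self._compound_names[k] for k in keys if k in self._compound_names}
        if len(hits) > 1:
            raise IntegrityError(
                f"names of {name!r} span multiple compounds: {sorted(hits)}"
            )
        if hits:
            existing = self.compounds[hits.pop()]
            if (
                compound_id
                and is_drugbank_id(compound_id)
                and is_drugbank_id(existing.compound_id)
                and compound_id != existing.compound_id
            ):
                raise IntegrityError(
                    f"conflicting accessions for {name!r}: "
                    f"{existing.compound_id} vs {compound_id}"
                )
            new_names = ({name} | synonyms) - existing.names()
            existing.synonyms |= new_names
            for k in keys:
                self._compound_names[k] = existing.compound_id
            return existing.compound_id
        cid = compound_id if compound_id else local_id("LOCAL", name)
        self.compounds[cid] = Compound(cid, name, synonyms)
        for k in keys:
            self._compound_names[k] = cid
        return cid

    def register_treatment(
        self,
        label: str,
        component_ids: list[str],
        reported_effects: set[str] | None = None,
        study_refs: set[str] | None = None,
    ) -> str:
        if not component_ids:
            raise IntegrityError(f"treatment {label!r} has no components")
        for cid in component_ids:
            if cid not in self.compounds:
                raise IntegrityError(f"treatment {label!r}: unknown component {cid}")
        key = self._norm(label)
        if key in self._treatment_labels:
            tid = self._treatment_labels[key]
            t = self.treatments[tid]
            t.reported_effects |= set(reported_effects or ())
            t.study_refs |= set(study_refs or ())
            return tid
        tid = local_id("TRT", label)
        self.treatments[tid] = Treatment(
            tid, label, list(component_ids),
            set(reported_effects or ()), set(study_refs or ()),
        )
        self._treatment_labels[key] = tid
        for cid in component_ids:
            self.compounds[cid].is_kb_component = True
        return tid

    def register_category(self, name: str) -> str:
        key = self._norm(name)
        if key in self._category_names:
            return self._category_names[key]
        cid = local_id("CAT", name)
        self.categories[cid] = TherapeuticCategory(cid, name)
        self._category_names[key] = cid
        return cid

    def register_target(self, name: str, external_ref: str | None = None) -> str:
        key = self._norm(name)
        if key in self._target_names:
            tid = self._target_names[key]
            if external_ref and not self.targets[tid].external_ref:
                self.targets[tid].external_ref = external_ref
            return tid
        tid = local_id("TGT", name)
        self.targets[tid] = ProteomicTarget(tid, name, external_ref)
        self._target_names[key] = tid
        return tid

    def register_pathway(self, pathway_id: str | None, name: str) -> str:
        pid = pathway_id if pathway_id and is_smpdb_id(pathway_id) else (
            pathway_id or local_id("PWY", name)
        )
        if pid in self.pathways:
            existing = self.pathways[pid]
            if self._norm(existing.name) != self._norm(name):
                raise IntegrityError(
                    f"pathway {pid}: conflicting names "
                    f"{existing.name!r} vs {name!r}"
                )
            return pid
        self.pathways[pid] = PathwayRecord(pid, name)
        return pid

    # -- edges --------------------------------------------------------

    def add_category_edge(self, compound_id: str, category_id: str) -> None:
        if compound_id not in self.compounds or category_id not in self.categories:
            raise IntegrityError(f"dangling edge ({compound_id}, {category_id})")
        self.assoc.category_edges.add((compound_id, category_id))

    def add_target_edge(self, compound_id: str, target_id: str) -> None:
        if compound_id not in self.compounds or target_id not in self.targets:
            raise IntegrityError(f"dangling edge ({compound_id}, {target_id})")
        self.assoc.target_edges.add((compound_id, target_id))

    def add_smpdb_edge(self, compound_id: str, pathway_id: str) -> None:
        if compound_id not in self.compounds or pathway_id not in self.pathways:
            raise IntegrityError(f"dangling edge ({compound_id}, {pathway_id})")
        self.assoc.smpdb_edges.add((compound_id, pathway_id))
        self.pathways[pathway_id].member_drugs.add(compound_id)

    def add_keywords(self, compound_id: str, keywords: set[str]) -> None:
        if compound_id not in self.compounds:
            raise IntegrityError(f"unknown compound {compound_id}")
        self.compound_keywords.setdefault(compound_id, set()).update(keywords)

    # -- lookup -------------------------------------------------------

    def resolve_name(self, name: str) -> str | None:
        """Case-insensitive, whitespace-collapsed compound lookup.

        Returns ``None`` (not an error) for unknown names; raises
        ``ValueError`` for empty input.
        """
        return self._compound_names.get(self._norm(name))

    def resolve_treatment(self, label: str) -> Treatment | None:
        tid = self._treatment_labels.get(self._norm(label))
        return self.treatments.get(tid) if tid else None

    def resolve_category(self, name: str) -> str | None:
        return self._category_names.get(self._norm(name))

    def resolve_target(self, name: str) -> str | None:
        return self._target_names.get(self._norm(name))

    # -- integrity ----------------------------------------------------

    def integrity_check(self) -> list[Violation]:
        """Report every invariant violation; empty list iff the KB is sound."""
        out: list[Violation] = []
        seen: dict[str, str] = {}
        for cid in sorted(self.compounds):
            c = self.compounds[cid]
            if not c.preferred_name.strip():
                out.append(Violation("empty-name", f"compound {cid}", (cid,)))
                continue
            for n in sorted(c.names()):
                k = self._norm(n)
                if k in seen and seen[k] != cid:
                    out.append(
                        Violation(
                            "duplicate-name",
                            f"{n!r} shared by {seen[k]} and {cid}",
                            (seen[k], cid),
                        )
                    )
                else:
                    seen[k] = cid
        component_ids: set[str] = set()
        for tid in sorted(self.treatments):
            t = self.treatments[tid]
            if not t.components:
                out.append(Violation("empty-components", f"treatment {tid}", (tid,)))
            for cid in t.components:
                component_ids.add(cid)
                if cid not in self.compounds:
                    out.append(
                        Violation(
                            "dangling-reference",
                            f"treatment {tid} references missing compound {cid}",
                            (tid, cid),
                        )
                    )
        for cid in sorted(self.compounds):
            flag = self.compounds[cid].is_kb_component
            if flag != (cid in component_ids):
                out.append(
                    Violation(
                        "component-flag",
                        f"compound {cid} is_kb_component={flag} but "
                        f"membership={cid in component_ids}",
                        (cid,),
                    )
                )
        for a, b in sorted(self.assoc.category_edges):
            if a not in self.compounds or b not in self.categories:
                out.append(Violation("dangling-edge", f"category edge ({a},{b})", (a, b)))
        for a, b in sorted(self.assoc.target_edges):
            if a not in self.compounds or b not in self.targets:
                out.append(Violation("dangling-edge", f"target edge ({a},{b})", (a, b)))
        for a, b in sorted(self.assoc.smpdb_edges):
            if a not in self.compounds or b not in self.pathways:
                out.append(Violation("dangling-edge", f"smpdb edge ({a},{b})", (a, b)))
        return out

    # -- persistence --------------------------------------------------

    _DDL = """
    CREATE TABLE compound (compound_id TEXT PRIMARY KEY, preferred_name TEXT,
                           is_kb_component INTEGER);
    CREATE TABLE compound_synonym (compound_id TEXT, synonym TEXT);
    CREATE TABLE treatment (treatment_id TEXT PRIMARY KEY, label TEXT);
    CREATE TABLE treatment_component (treatment_id TEXT, position INTEGER,
                                      compound_id TEXT);
    CREATE TABLE treatment_effect (treatment_id TEXT, effect TEXT);
    CREATE TABLE treatment_ref (treatment_id TEXT, ref TEXT);
    CREATE TABLE category (category_id TEXT PRIMARY KEY, name TEXT);
    CREATE TABLE target (target_id TEXT PRIMARY KEY, name TEXT, external_ref TEXT);
    CREATE TABLE pathway (pathway_id TEXT PRIMARY KEY, name TEXT);
    CREATE TABLE category_edge (compound_id TEXT, category_id TEXT);
    CREATE TABLE target_edge (compound_id TEXT, target_id TEXT);
    CREATE TABLE smpdb_edge (compound_id TEXT, pathway_id TEXT);
    CREATE TABLE compound_keyword (compound_id TEXT, keyword TEXT);
    """

    def save(self, path: str | Path) -> None:
        """Write the store deterministically; replaces any existing file."""
        path = Path(path)
        tmp = path.with_suffix(path.suffix + ".tmp")
        if tmp.exists():
            tmp.unlink()
        con = sqlite3.connect(tmp)
        try:
            con.executescript(self._DDL)
            con.execute(f"PRAGMA user_version = {SCHEMA_VERSION}")
            con.executemany(
                "INSERT INTO compound VALUES (?,?,?)",
                [
                    (c.compound_id, c.preferred_name, int(c.is_kb_component))
                    for c in sorted(self.compounds.values(), key=lambda c: c.compound_id)
                ],
            )
            con.executemany(
                "INSERT INTO compound_synonym VALUES (?,?)",
                sorted(
                    (c.compound_id, s)
                    for c in self.compounds.values()
                    for s in c.synonyms
                ),
            )
            con.executemany(
                "INSERT INTO treatment VALUES (?,?)",
                sorted((t.treatment_id, t.label) for t in self.treatments.values()),
            )
            con.executemany(
                "INSERT INTO treatment_component VALUES (?,?,?)",
                sorted(
                    (t.treatment_id, i, cid)
                    for t in self.treatments.values()
                    for i, cid in enumerate(t.components)
                ),
            )
            con.executemany(
                "INSERT INTO treatment_effect VALUES (?,?)",
                sorted(
                    (t.treatment_id, e)
                    for t in self.treatments.values()
                    for e in t.reported_effects
                ),
            )
            con.executemany(
                "INSERT INTO treatment_ref VALUES (?,?)",
                sorted(
                    (t.treatment_id, r)
                    for t in self.treatments.values()
                    for r in t.study_refs
                ),
            )
            con.executemany(
                "INSERT INTO category VALUES (?,?)",
                sorted((c.category_id, c.name) for c in self.categories.values()),
            )
            con.executemany(
                "INSERT INTO target VALUES (?,?,?)",
                sorted(
                    (t.target_id, t.name, t.external_ref) for t in self.targets.values()
                ),
            )
            con.executemany(
                "INSERT INTO pathway VALUES (?,?)",
                sorted((p.pathway_id, p.name) for p in self.pathways.values()),
            )
            con.executemany(
                "INSERT INTO category_edge VALUES (?,?)",
                sorted(self.assoc.category_edges),
            )
            con.executemany(
                "INSERT INTO target_edge VALUES (?,?)", sorted(self.assoc.target_edges)
            )
            con.executemany(
                "INSERT INTO smpdb_edge VALUES (?,?)", sorted(self.assoc.smpdb_edges)
            )
            con.executemany(
                "INSERT INTO compound_keyword VALUES (?,?)",
                sorted(
                    (cid, k)
                    for cid, kws in self.compound_keywords.items()
                    for k in kws
                ),
            )
            con.commit()
        finally:
            con.close()
        tmp.replace(path)

    @classmethod
    def load(cls, path: str | Path) -> "KnowledgeBase":
        con = sqlite3.connect(Path(path))
        try:
            version = con.execute("PRAGMA user_version").fetchone()[0]
            if version != SCHEMA_VERSION:
                raise IntegrityError(
                    f"store schema version {version}, expected {SCHEMA_VERSION}"
                )
            kb = cls()
            for cid, name, flag in con.execute("SELECT * FROM compound"):
                kb.compounds[cid] = Compound(cid, name, set(), bool(flag))
                kb._compound_names[kb._norm(name)] = cid
            for cid, syn in con.execute("SELECT * FROM compound_synonym"):
                kb.compounds[cid].synonyms.add(syn)
                kb._compound_names[kb._norm(syn)] = cid
            comps: dict[str, list[tuple[int, str]]] = {}
            for tid, pos, cid in con.execute("SELECT * FROM treatment_component"):
                comps.setdefault(tid, []).append((pos, cid))
            effects: dict[str, set[str]] = {}
            for tid, e in con.execute("SELECT * FROM treatment_effect"):
                effects.setdefault(tid, set()).add(e)
            refs: dict[str, set[str]] = {}
            for tid, r in con.execute("SELECT * FROM treatment_ref"):
                refs.setdefault(tid, set()).add(r)
            for tid, label in con.execute("SELECT * FROM treatment"):
                ordered = [c for _, c in sorted(comps.get(tid, []))]
                kb.treatments[tid] = Treatment(
                    tid, label, ordered, effects.get(tid, set()), refs.get(tid, set())
                )
                kb._treatment_labels[kb._norm(label)] = tid
            for cid, name in con.execute("SELECT * FROM category"):
                kb.categories[cid] = TherapeuticCategory(cid, name)
                kb._category_names[kb._norm(name)] = cid
            for tid, name, ref in con.execute("SELECT * FROM target"):
                kb.targets[tid] = ProteomicTarget(tid, name, ref)
                kb._target_names[kb._norm(name)] = tid
            for pid, name in con.execute("SELECT * FROM pathway"):
                kb.pathways[pid] = PathwayRecord(pid, name)
            for a, b in con.execute("SELECT * FROM category_edge"):
                kb.assoc.category_edges.add((a, b))
            for a, b in con.execute("SELECT * FROM target_edge"):
                kb.assoc.target_edges.add((a, b))
            for a, b in con.execute("SELECT * FROM smpdb_edge"):
                kb.assoc.smpdb_edges.add((a, b))
                kb.pathways[b].member_drugs.add(a)
            for cid, k in con.execute("SELECT * FROM compound_keyword"):
                kb.compound_keywords.setdefault(cid, set()).add(k)
            return kb
        finally:
            con.close()

    def export_tsv(self, outdir: str | Path) -> list[Path]:
        """Plain-text export: one UTF-8 TSV per table, header row, LF endings."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables: dict[str, tuple[list[str], list[tuple]]] = {
            "compound": (
                ["compound_id", "preferred_name", "is_kb_component"],
                sorted(
                    (c.compound_id, c.preferred_name, int(c.is_kb_component))
                    for c in self.compounds.values()
                ),
            ),
            "compound_synonym": (
                ["compound_id", "synonym"],
                sorted(
                    (c.compound_id, s)
                    for c in self.compounds.values()
                    for s in c.synonyms
                ),
            ),
            "treatment": (
                ["treatment_id", "label", "components", "effects"],
                sorted(
                    (
                        t.treatment_id,
                        t.label,
                        "|".join(t.components),
                        "|".join(sorted(t.reported_effects)),
                    )
                    for t in self.treatments.values()
                ),
            ),
            "category": (
                ["category_id", "name"],
                sorted((c.category_id, c.name) for c in self.categories.values()),
            ),
            "target": (
                ["target_id", "name", "external_ref"],
                sorted(
                    (t.target_id, t.name, t.external_ref or "")
                    for t in self.targets.values()
                ),
            ),
            "pathway": (
                ["pathway_id", "name"],
                sorted((p.pathway_id, p.name) for p in self.pathways.values()),
            ),
            "category_edge": (
                ["compound_id", "category_id"],
                sorted(self.assoc.category_edges),
            ),
            "target_edge": (
                ["compound_id", "target_id"],
                sorted(self.assoc.target_edges),
            ),
            "smpdb_edge": (
                ["compound_id", "pathway_id"],
                sorted(self.assoc.smpdb_edges),
            ),
        }
        written = []
        for name, (header, rows) in tables.items():
            p = outdir / f"{name}.tsv"
            with open(p, "w", encoding="utf-8", newline="\n") as fh:
                fh.write("\t".join(header) + "\n")
                for row in rows:
                    fh.write("\t".join(str(x) for x in row) + "\n")
            written.append(p)
        return written
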