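"""Parsers for the three external-knowledge inputs.

* DrugBank-dialect XML — drugs with accessions, names, synonyms and
  therapeutic categories, streamed one ``<drug>`` element at a time.
* Drug–target table — tab-separated, one interaction per row (quoting is
  disabled on purpose: protein names legitimately contain commas).
* Pathway table — tab-separated SMPDB-dialect membership rows.

Unparseable records are collected into a rejects report rather than
aborting the run; missing data is the norm in this domain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .kb import KnowledgeBase
from .normalize import is_drugbank_id, normalize_name


class FormatError(Exception):
    """Input file violates the documented dialect."""


@dataclass
class DrugRecord:
    drugbank_id: str | None
    name: str
    synonyms: list[str] = field(default_factory=list)
    categories: list[str] = field(default_factory=list)


@dataclass
class ParseReport:
    accepted: int = 0
    rejects: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.accepted + len(self.rejects)


def _localname(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def parse_drugbank_xml(path: str | Path) -> tuple[list[DrugRecord], ParseReport]:
    """Stream a DrugBank-dialect XML file into drug records.

    Memory use is proportional to one ``<drug>`` element: processed
    elements are cleared as the parse advances.  A drug missing its
    primary ID or name becomes a reject entry; the parse continues.
    Malformed XML raises :class:`FormatError` carrying the line number.
    """
    path = Path(path)
    records: list[DrugRecord] = []
    report = ParseReport()
    try:
        context = etree.iterparse(str(path), events=("end",))
        for _, elem in context:
            if _localname(elem.tag) != "drug":
                continue
            parent = elem.getparent()
            if parent is None or _localname(parent.tag) != "drugbank":
                continue
            primary_id = None
            name = None
            synonyms: list[str] = []
            categories: list[str] = []
            for child in elem:
                ln = _localname(child.tag)
                if ln == "drugbank-id":
                    if child.get("primary") == "true" or primary_id is None:
                        primary_id = (child.text or "").strip() or primary_id
                elif ln == "name":
                    name = (child.text or "").strip() or None
                elif ln == "synonym":
                    if child.text and child.text.strip():
                        synonyms.append(child.text.strip())
                elif ln == "synonyms":
                    for syn in child:
                        if _localname(syn.tag) == "synonym" and syn.text and syn.text.strip():
                            synonyms.append(syn.text.strip())
                elif ln == "categories":
                    for cat in child:
                        if _localname(cat.tag) != "category":
                            continue
                        text = (cat.text or "").strip()
                        for sub in cat:
                            if _localname(sub.tag) == "category-name" and sub.text:
                                text = sub.text.strip()
                        if text:
                            categories.append(text)
            if not primary_id or not name:
                report.rejects.append(
                    f"line {elem.sourceline}: drug element missing "
                    f"{'primary id' if not primary_id else 'name'}"
                )
            else:
                records.append(DrugRecord(primary_id, name, synonyms, categories))
                report.accepted += 1
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML in {path.name}: {exc}") from exc
    return records, report


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", dtype=str, quoting=csv.QUOTE_NONE, keep_default_na=False
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    return df


def read_target_table(path: str | Path) -> list[tuple[str, str, str | None]]:
    """Read drug–target rows, deduplicated on normalized (drug, target).

    Columns: ``drug``, ``target`` (required); ``external_ref``, ``source``
    (optional).  Returns (drug_name, target_name, external_ref) tuples in
    first-seen order.
    """
    df = _read_tsv(path, ["drug", "target"])
    seen: set[tuple[str, str]] = set()
    rows: list[tuple[str, str, str | None]] = []
    for rec in df.itertuples(index=False):
        drug, target = rec.drug.strip(), rec.target.strip()
        if not drug or not target:
            continue
        key = (normalize_name(drug), normalize_name(target))
        if key in seen:
            continue
        seen.add(key)
        ref = getattr(rec, "external_ref", "") or None
        rows.append((drug, target, ref))
    return rows


def read_pathway_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Read SMPDB-dialect membership rows: (pathway_id, pathway_name, drug).

    One membership per row; duplicates collapse.  Two different names for
    one pathway ID is an integrity failure listing both names.
    """
    from .kb import IntegrityError

    df = _read_tsv(path, ["pathway_id", "pathway_name", "drug"])
    names: dict[str, str] = {}
    seen: set[tuple[str, str]] = set()
    rows: list[tuple[str, str, str]] = []
    for rec in df.itertuples(index=False):
        pid, pname, drug = rec.pathway_id.strip(), rec.pathway_name.strip(), rec.drug.strip()
        if not pid:
            continue
        if pid in names and normalize_name(names[pid]) != normalize_name(pname):
            raise IntegrityError(
                f"pathway {pid}: conflicting names {names[pid]!r} vs {pname!r}"
            )
        names.setdefault(pid, pname)
        key = (pid, normalize_name(drug)) if drug else (pid, "")
        if key in seen:
            continue
        seen.add(key)
        rows.append((pid, pname, drug))
    return rows


def ingest_drugbank(kb: KnowledgeBase, path: str | Path) -> ParseReport:
    """Parse DrugBank-dialect XML and register its content into *kb*."""
    records, report = parse_drugbank_xml(path)
    for rec in records:
        cid = kb.register_compound(
            rec.name,
            set(rec.synonyms),
            rec.drugbank_id if is_drugbank_id(rec.drugbank_id or "") else None,
        )
        for cat in rec.categories:
            kb.add_category_edge(cid, kb.register_category(cat))
    return report


def ingest_targets(kb: KnowledgeBase, path: str | Path) -> int:
    """Register drug–target edges; unknown drug names become local compounds.

    Candidate drugs outside the treatment set must be representable, so an
    unresolvable drug name creates a new compound rather than a reject.
    """
    n = 0
    for drug, target, ref in read_target_table(path):
        cid = kb.resolve_name(drug) or kb.register_compound(drug)
        kb.add_target_edge(cid, kb.register_target(target, ref))
        n += 1
    return n


def ingest_pathways(kb: KnowledgeBase, path: str | Path) -> int:
    n = 0
    for pid, pname, drug in read_pathway_table(path):
        pathway = kb.register_pathway(pid, pname)
        if drug:
            cid = kb.resolve_name(drug) or kb.register_compound(drug)
            kb.add_smpdb_edge(cid, pathway)
            n += 1
    return n


def build_kb(
    drugbank: str | Path | None = None,
    targets: str | Path | None = None,
    pathways: str | Path | None = None,
    kb: KnowledgeBase | None = None,
) -> tuple[KnowledgeBase, ParseReport]:
    """Run the full ingestion stage over whichever inputs are present."""
    kb = kb or KnowledgeBase()
    report = ParseReport()
    if drugbank:
        report = ingest_drugbank(kb, drugbank)
    if targets:
        ingest_targets(kb, targets)
    if pathways:
        ingest_pathways(kb, pathways)
    return kb, report
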