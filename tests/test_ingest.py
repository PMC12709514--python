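"""Parser contracts: streaming XML, delimited tables, rejects, order-insensitivity."""

import random

import pytest

from neurorepo import KnowledgeBase, build_kb, parse_drugbank_xml, read_pathway_table, read_target_table
from neurorepo.ingest import FormatError, ingest_targets
from neurorepo.kb import IntegrityError
from neurorepo.normalize import normalize_name

THREE_DRUG_XML = """<?xml version="1.0"?>
<drugbank>
  <drug>
    <drugbank-id primary="true">DB00001</drugbank-id>
    <name>Drug A</name>
    <categories>
      <category><category-name>Cat One</category-name></category>
      <category><category-name>Cat Two</category-name></category>
    </categories>
  </drug>
  <drug>
    <drugbank-id primary="true">DB00002</drugbank-id>
    <name>Drug B</name>
    <categories/>
  </drug>
  <drug>
    <drugbank-id primary="true">DB00003</drugbank-id>
    <name>Drug C</name>
    <unknown-element>ignored</unknown-element>
  </drug>
</drugbank>
"""


def test_parse_three_drug_fixture(tmp_path):
    path = tmp_path / "db.xml"
    path.write_text(THREE_DRUG_XML)
    records, report = parse_drugbank_xml(path)
    assert report.accepted == 3 and not report.rejects
    by_name = {r.name: r for r in records}
    assert by_name["Drug A"].categories == ["Cat One", "Cat Two"]
    assert by_name["Drug B"].categories == []
    kb, _ = build_kb(drugbank=path)
    assert len(kb.compounds) == 3
    assert len(kb.categories) == 2
    assert len(kb.assoc.category_edges) == 2


def test_empty_root_yields_empty_sets(tmp_path):
    path = tmp_path / "db.xml"
    path.write_text("<drugbank/>")
    records, report = parse_drugbank_xml(path)
    assert records == [] and report.total == 0


def test_malformed_xml_raises_format_error(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text("<drugbank><drug></drugbank>")
    with pytest.raises(FormatError, match="line"):
        parse_drugbank_xml(path)


def test_drug_missing_name_is_rejected_not_fatal(tmp_path):
    path = tmp_path / "db.xml"
    path.write_text(
        "<drugbank><drug><drugbank-id primary='true'>DB00001</drugbank-id></drug>"
        "<drug><drugbank-id primary='true'>DB00002</drugbank-id>"
        "<name>Good</name></drug></drugbank>"
    )
    records, report = parse_drugbank_xml(path)
    assert report.accepted == 1
    assert len(report.rejects) == 1
    assert report.total == 2


def test_target_rows_deduplicate(tmp_path):
    path = tmp_path / "t.tsv"
    row = "Risperidone\t5-hydroxytryptamine receptor 1A"
    path.write_text("drug\ttarget\n" + "\n".join([row] * 5) + "\n")
    assert len(read_target_table(path)) == 1


def test_target_table_missing_column_names_it(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("drug\tprotein\nA\tB\n")
    with pytest.raises(FormatError, match="target"):
        read_target_table(path)


def test_comma_bearing_names_survive(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("drug\ttarget\n5-methoxy-N, N-dimethyltryptamine\t5-HT1A\n")
    rows = read_target_table(path)
    assert rows[0][0] == "5-methoxy-N, N-dimethyltryptamine"


def test_random_table_edge_count_matches_brute_force(tmp_path):
    rng = random.Random(42)
    drugs = [f"Drug {i}" for i in range(12)]
    targets = [f"Target {i}" for i in range(8)]
    raw = [(rng.choice(drugs), rng.choice(targets)) for _ in range(100)]
    path = tmp_path / "t.tsv"
    path.write_text(
        "drug\ttarget\n" + "\n".join(f"{d}\t{t}" for d, t in raw) + "\n"
    )
    expected = len({(normalize_name(d), normalize_name(t)) for d, t in raw})
    kb = KnowledgeBase()
    ingest_targets(kb, path)
    assert len(kb.assoc.target_edges) == expected


def test_unresolved_target_drugs_become_local_compounds(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("drug\ttarget\nNovelamine\tSome protein\n")
    kb = KnowledgeBase()
    ingest_targets(kb, path)
    cid = kb.resolve_name("Novelamine")
    assert cid is not None and cid.startswith("LOCAL-")


def test_pathway_rows_group_by_id(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "pathway_id\tpathway_name\tdrug\n"
        "SMP00001\tRisperidone Metabolism Pathway\tRisperidone\n"
        "SMP00001\tRisperidone Metabolism Pathway\tCalcium\n"
    )
    kb, _ = build_kb(pathways=path)
    assert len(kb.pathways) == 1
    assert len(kb.pathways["SMP00001"].member_drugs) == 2


def test_conflicting_pathway_names_raise(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text(
        "pathway_id\tpathway_name\tdrug\n"
        "SMP00001\tName One\tA\nSMP00001\tName Two\tB\n"
    )
    with pytest.raises(IntegrityError, match="Name One"):
        read_pathway_table(path)


def test_empty_pathway_file_yields_zero_records(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("pathway_id\tpathway_name\tdrug\n")
    assert read_pathway_table(path) == []


def _kb_signature(kb):
    name = lambda c: kb.compounds[c].preferred_name
    return (
        {c.preferred_name for c in kb.compounds.values()},
        {(name(a), kb.categories[b].name) for a, b in kb.assoc.category_edges},
        {(name(a), kb.targets[b].name) for a, b in kb.assoc.target_edges},
        {(name(a), b) for a, b in kb.assoc.smpdb_edges},
    )


def test_parse_is_order_insensitive(tmp_path):
    from neurorepo import GeneratorParams, generate

    paths, _ = generate(GeneratorParams(n_drugs=15, n_treatments=4, seed=3),
                        tmp_path / "orig")
    kb1, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])

    shuffled = tmp_path / "shuffled"
    shuffled.mkdir()
    rng = random.Random(0)
    for key in ("targets", "pathways"):
        lines = paths[key].read_text().splitlines()
        body = lines[1:]
        rng.shuffle(body)
        (shuffled / paths[key].name).write_text("\n".join([lines[0]] + body) + "\n")
    from lxml import etree

    tree = etree.parse(str(paths["drugbank"]))
    root = tree.getroot()
    drugs = list(root)
    rng.shuffle(drugs)
    for d in drugs:
        root.remove(d)
    for d in drugs:
        root.append(d)
    tree.write(str(shuffled / "drugbank.xml"))
    kb2, _ = build_kb(
        shuffled / "drugbank.xml", shuffled / "targets.tsv", shuffled / "pathways.tsv"
    )
    assert _kb_signature(kb1) == _kb_signature(kb2)
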