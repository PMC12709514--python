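"""Packaged worked-example fixture: a small, fully synthetic input bundle.

Encodes the curated 29-treatment knowledge layer together with hand-built
association tables chosen so that the published shared-target counts and
graph entities emerge from the pipeline's own set algebra (unions over
combination components, intersections between treatments).  Every
accession in the bundle is a synthetic placeholder — no licensed database
content is included; target and category names are standard protein and
pharmacological class names.

The bundle mirrors the real input layout: ``drugbank.xml`` (categories),
``targets.tsv`` (drug–target edges), ``pathways.tsv`` (pathway
memberships) and ``treatments.json`` (the curated layer, shipped under
``neurorepo/fixtures``).
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path
from xml.sax.saxutils import escape

from .ingest import build_kb
from .kb import KnowledgeBase
from .treatments import load_treatments

# -- proteomic target assignments --------------------------------------
# Single-compound target sets.  Cannabidiol holds the union of every name
# it shares with any comparator plus private filler; each comparator holds
# its shared names plus private filler, so pairwise intersections and
# combination unions reproduce the published counts.

_T = {
    "ABCB1": "ATP-dependent translocase ABCB1",
    "CYP3A4": "Cytochrome P450 3A4",
    "CYP2D6": "Cytochrome P450 2D6",
    "HTR2A": "5-hydroxytryptamine receptor 2A",
    "HTR1A": "5-hydroxytryptamine receptor 1A",
    "HTR1B": "5-hydroxytryptamine receptor 1B",
    "HTR3A": "5-hydroxytryptamine receptor 3A",
    "CYP2C9": "Cytochrome P450 2C9",
    "CYP1A2": "Cytochrome P450 1A2",
    "CYP3A5": "Cytochrome P450 3A5",
    "CYP2C19": "Cytochrome P450 2C19",
    "CYP2B6": "Cytochrome P450 2B6",
    "CYP3A7": "Cytochrome P450 3A7",
    "CYP2A6": "Cytochrome P450 2A6",
    "CYP1A1": "Cytochrome P450 1A1",
    "CYP1B1": "Cytochrome P450 1B1",
    "IDO1": "Indoleamine 2,3-dioxygenase 1",
    "CHRNA7": "Neuronal acetylcholine receptor subunit alpha-7",
    "GLRA1": "Glycine receptor subunit alpha-1",
    "GLRB": "Glycine receptor subunit beta",
    "GLRA3": "Glycine receptor subunit alpha-3",
    "PTGS1": "Prostaglandin G/H synthase 1",
    "PTGS2": "Prostaglandin G/H synthase 2",
    "PPARG": "Peroxisome proliferator-activated receptor gamma",
    "HMGCR": "3-hydroxy-3-methylglutaryl-coenzyme A reductase",
    "RHBDF2": "Inactive rhomboid protein 2",
}

_CBD_SHARED = [
    "ABCB1", "CYP3A4", "CYP2D6", "HTR2A", "HTR1A", "HTR3A",
    "CYP2C9", "CYP1A2", "CYP3A5", "CYP2C19", "CYP2B6", "CYP3A7",
    "CYP2A6", "CYP1A1", "CYP1B1", "IDO1",
    "CHRNA7", "GLRA1", "GLRB", "GLRA3",
    "PTGS1", "PTGS2", "PPARG", "HMGCR",
]

TARGETS: dict[str, list[str]] = {
    "Cannabidiol": [_T[k] for k in _CBD_SHARED] + [
        "Cannabinoid receptor 1",
        "Cannabinoid receptor 2",
        "G-protein coupled receptor 55",
        "Transient receptor potential cation channel subfamily V member 1",
        "Adenosine receptor A1",
    ],
    "Methylphenidate": [
        _T["HTR1A"],
        "Sodium-dependent dopamine transporter",
        "Sodium-dependent noradrenaline transporter",
        "Synaptic vesicular amine transporter",
    ],
    "Memantine": [
        _T[k] for k in ("CHRNA7", "CYP2A6", "GLRA1", "GLRB",
                        "CYP2C19", "CYP2B6", "GLRA3", "HTR3A")
    ] + ["Glutamate receptor ionotropic, NMDA 1"],
    "Atomoxetine": [
        _T["CYP2D6"], _T["CYP2C19"],
        "Sodium-dependent noradrenaline transporter",
    ],
    "Fluoxetine": [
        _T[k] for k in ("CYP2C9", "ABCB1", "CYP1A2", "CYP3A4", "HTR2A",
                        "CYP3A5", "CYP2D6", "CYP2C19", "CYP2B6", "HTR1A")
    ] + ["Sodium-dependent serotonin transporter"],
    "Cyamemazine": [
        _T["HTR2A"], _T["CYP2D6"],
        "Dopamine D2 receptor", "Histamine H1 receptor",
    ],
    "Valproic acid": [],
    "Risperidone": [
        _T[k] for k in ("ABCB1", "CYP3A4", "HTR2A", "CYP2D6", "HTR1A", "HTR1B")
    ] + ["Dopamine D2 receptor"],
    "Loxapine": [
        _T["HTR3A"], _T["CYP1A2"], _T["CYP3A4"], _T["HTR2A"],
        "Dopamine D2 receptor", "Histamine H1 receptor",
    ],
    "Melatonin": [
        _T[k] for k in ("CYP2C9", "IDO1", "CYP1A2", "CYP1A1",
                        "HTR2A", "CYP2C19", "CYP1B1")
    ] + ["Melatonin receptor type 1A", "Melatonin receptor type 1B"],
    "Acetylcysteine": ["Glutamate--cysteine ligase catalytic subunit"],
    "Buspirone": [
        _T[k] for k in ("ABCB1", "CYP3A7", "CYP3A4", "HTR2A",
                        "CYP3A5", "CYP2D6", "HTR3A", "HTR1A")
    ] + ["Dopamine D2 receptor"],
    "Oxytocin": ["Oxytocin receptor", "Oxytocin-neurophysin 1"],
    "Vitamin D3": [],
    "Doconexent": [
        _T["PTGS1"], _T["CYP2C9"], _T["PPARG"], _T["PTGS2"],
        "Fatty acid-binding protein, brain",
    ],
    "Sulforaphane": [_T["RHBDF2"]],
    "Prednisolone": [_T["ABCB1"], _T["CYP3A4"], "Glucocorticoid receptor"],
    "Bumetanide": [
        _T["PTGS2"],
        "Solute carrier family 12 member 1",
        "Solute carrier family 12 member 2",
    ],
    "Ubidecarenone": [
        _T["HMGCR"], _T["ABCB1"],
        "NADH dehydrogenase [ubiquinone] iron-sulfur protein 2",
    ],
    "Luteolin": ["Xanthine dehydrogenase/oxidase", "Matrix metalloproteinase-9"],
    "Lecithin": ["Phosphatidylcholine transfer protein"],
    "Chondroitin sulfate": [],
    # target-route candidate drugs outside the treatment set
    "5-methoxy-N, N-dimethyltryptamine": [_T["HTR1A"], _T["HTR1B"]],
    "Acepromazine": [_T["HTR1A"], _T["HTR1B"]],
}

# -- therapeutic categories ---------------------------------------------
# Membership kept intentionally sparse: the category-graph worked example
# requires the alpha-1 antagonist and antineoplastic co-drugs to be
# exactly the ones rendered in the published figure.

CATEGORIES: dict[str, list[str]] = {
    "Sulforaphane": ["Antineoplastic Agents", "Anticarcinogenic Agents"],
    "Risperidone": [
        "Adrenergic alpha-1 Receptor Antagonists",
        "Adrenergic Antagonists",
        "Antipsychotic Agents",
        "Serotonin Antagonists",
    ],
    "10-Hydroxycamptothecin": ["Antineoplastic Agents"],
    "2-(4-chlorophenyl)-5-quinoxalinecarboxamide": ["Antineoplastic Agents"],
    "Alfuzosin": ["Adrenergic alpha-1 Receptor Antagonists", "Adrenergic Antagonists"],
    "Acepromazine": [
        "Adrenergic alpha-1 Receptor Antagonists",
        "Adrenergic Antagonists",
        "Antipsychotic Agents",
    ],
    "Methylphenidate": ["Central Nervous System Stimulants", "Dopamine Uptake Inhibitors"],
    "Memantine": ["Excitatory Amino Acid Antagonists", "Antiparkinson Agents"],
    "Atomoxetine": ["Adrenergic Uptake Inhibitors", "Central Nervous System Stimulants"],
    "Fluoxetine": ["Serotonin Uptake Inhibitors", "Antidepressive Agents"],
    "Cyamemazine": ["Antipsychotic Agents"],
    "Valproic acid": ["Anticonvulsants", "Antimanic Agents"],
    "Loxapine": ["Antipsychotic Agents"],
    "Melatonin": ["Central Nervous System Depressants", "Antioxidants"],
    "Acetylcysteine": ["Antioxidants", "Expectorants"],
    "Buspirone": ["Anti-Anxiety Agents", "Serotonin Receptor Agonists"],
    "Oxytocin": ["Oxytocics"],
    "Doconexent": ["Fatty Acids, Omega-3"],
    "Cannabidiol": ["Anticonvulsants", "Anti-Anxiety Agents"],
    "Prednisolone": ["Anti-Inflammatory Agents", "Glucocorticoids"],
    "Bumetanide": ["Diuretics", "Sodium Potassium Chloride Symporter Inhibitors"],
    "Ubidecarenone": ["Antioxidants", "Vitamins"],
    "Luteolin": ["Antioxidants", "Anticarcinogenic Agents"],
    "Lecithin": ["Surface-Active Agents"],
    "Chondroitin sulfate": ["Viscosupplements"],
}

# -- SMPDB-dialect pathway memberships ----------------------------------
# Exactly 11 treatment components carry pathway data; calcium and carbon
# dioxide appear only as co-members of the risperidone pathway (the
# pathway-route repositioning candidates).

PATHWAYS: list[tuple[str, str, list[str]]] = [
    ("SMP00441", "Risperidone Metabolism Pathway",
     ["Risperidone", "Calcium", "Carbon dioxide"]),
    ("SMP00442", "Risperidone Action Pathway", ["Risperidone"]),
    ("SMP00431", "Fluoxetine Metabolism Pathway", ["Fluoxetine"]),
    ("SMP00432", "Fluoxetine Action Pathway", ["Fluoxetine"]),
    ("SMP00401", "Memantine Action Pathway", ["Memantine"]),
    ("SMP00421", "Methylphenidate Metabolism Pathway", ["Methylphenidate"]),
    ("SMP00422", "Methylphenidate Action Pathway", ["Methylphenidate"]),
    ("SMP00411", "Atomoxetine Metabolism Pathway", ["Atomoxetine"]),
    ("SMP00461", "Vitamin D Metabolism Pathway", ["Vitamin D3"]),
    ("SMP00451", "Loxapine Metabolism Pathway", ["Loxapine"]),
    ("SMP00471", "Oxytocin Action Pathway", ["Oxytocin"]),
    ("SMP00481", "Bumetanide Action Pathway", ["Bumetanide"]),
    ("SMP00491", "Prednisolone Metabolism Pathway", ["Prednisolone"]),
    ("SMP00492", "Prednisolone Action Pathway", ["Prednisolone"]),
    ("SMP00501", "Alpha Linolenic Acid and Linoleic Acid Metabolism",
     ["Doconexent"]),
]

# drugs appearing in the DrugBank-dialect XML, with synthetic accessions
_XML_DRUGS = sorted(
    set(CATEGORIES) | set(TARGETS) | {"Calcium", "Carbon dioxide"}
)


def _drugbank_xml() -> str:
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<drugbank>"]
    for i, name in enumerate(_XML_DRUGS):
        lines.append("  <drug>")
        lines.append(f'    <drugbank-id primary="true">DB{90000 + i:05d}</drugbank-id>')
        lines.append(f"    <name>{escape(name)}</name>")
        lines.append("    <categories>")
        for cat in CATEGORIES.get(name, []):
            lines.append(
                f"      <category><category-name>{escape(cat)}</category-name>"
                "</category>"
            )
        lines.append("    </categories>")
        lines.append("  </drug>")
    lines.append("</drugbank>")
    return "\n".join(lines) + "\n"


def _targets_tsv() -> str:
    rows = ["drug\ttarget\texternal_ref\tsource"]
    for drug in sorted(TARGETS):
        for target in TARGETS[drug]:
            rows.append(f"{drug}\t{target}\t\tcurated-snapshot")
    return "\n".join(rows) + "\n"


def _pathways_tsv() -> str:
    rows = ["pathway_id\tpathway_name\tdrug"]
    for pid, name, members in PATHWAYS:
        for m in members:
            rows.append(f"{pid}\t{name}\t{m}")
    return "\n".join(rows) + "\n"


def emit_curated_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the complete worked-example input bundle into *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "drugbank": outdir / "drugbank.xml",
        "targets": outdir / "targets.tsv",
        "pathways": outdir / "pathways.tsv",
        "treatments": outdir / "treatments.json",
    }
    paths["drugbank"].write_text(_drugbank_xml(), encoding="utf-8")
    paths["targets"].write_text(_targets_tsv(), encoding="utf-8")
    paths["pathways"].write_text(_pathways_tsv(), encoding="utf-8")
    ref = resources.files("neurorepo").joinpath("fixtures/curated_treatments.json")
    with resources.as_file(ref) as src:
        shutil.copy(src, paths["treatments"])
    return paths


def load_curated_fixture(workdir: str | Path | None = None) -> KnowledgeBase:
    """Build a knowledge base from the packaged worked-example bundle."""
    import tempfile

    if workdir is None:
        with tempfile.TemporaryDirectory() as tmp:
            return load_curated_fixture(tmp)
    paths = emit_curated_fixture(workdir)
    kb, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])
    load_treatments(paths["treatments"], kb)
    return kb
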