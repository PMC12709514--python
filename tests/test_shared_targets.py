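"""Shared-target analysis: published counts, union semantics, symmetry, oracle."""

import pytest

from neurorepo import (
    GeneratorParams,
    build_kb,
    generate,
    load_treatments,
    pairwise_matrix,
    shared,
    target_set,
)
from neurorepo.kb import Treatment

# (comparator treatment, published shared-target count with cannabidiol)
TABLE3_COUNTS = [
    ("Methylphenidate", 1),
    ("Memantine", 8),
    ("Atomoxetine", 2),
    ("Fluoxetine+cyamemazine+valproic acid", 10),
    ("Fluoxetine+risperidone+loxapine", 11),
    ("Fluoxetine+risperidone", 10),
    ("Fluoxetine+risperidone+melatonin", 13),
    ("Controlled-release melatonin", 7),
    ("Buspirone", 8),
    ("DHA; an omega-3 fatty acid", 4),
    ("Vitamin D3+DHA", 4),
    ("Sulforaphane+Risperidone", 5),
    ("Memantine+Risperidone", 13),
    ("Prednisolone", 2),
    ("Bumetanide", 1),
    ("Ubiquinol", 2),
    ("adrenal corticosteroid", 2),
]


@pytest.mark.parametrize("comparator,count", TABLE3_COUNTS)
def test_cannabidiol_shared_counts(fixture_kb, comparator, count):
    assert shared("Cannabidiol", comparator, fixture_kb).count == count


def test_cannabidiol_memantine_names(fixture_kb):
    r = shared("Cannabidiol", "Memantine", fixture_kb)
    assert set(r.target_names) == {
        "Neuronal acetylcholine receptor subunit alpha-7",
        "Cytochrome P450 2A6",
        "Glycine receptor subunit alpha-1",
        "Glycine receptor subunit beta",
        "Cytochrome P450 2C19",
        "Cytochrome P450 2B6",
        "Glycine receptor subunit alpha-3",
        "5-hydroxytryptamine receptor 3A",
    }


def test_cannabidiol_methylphenidate_single_shared_name(fixture_kb):
    r = shared("Cannabidiol", "Methylphenidate", fixture_kb)
    assert r.target_names == ["5-hydroxytryptamine receptor 1A"]


def test_result_invariants(fixture_kb):
    r = shared("Cannabidiol", "Buspirone", fixture_kb)
    assert r.count == len(r.target_names)
    assert r.target_names == sorted(r.target_names)
    assert len(set(r.target_names)) == r.count


def test_symmetry(fixture_kb):
    ab = shared("Cannabidiol", "Memantine+Risperidone", fixture_kb)
    ba = shared("Memantine+Risperidone", "Cannabidiol", fixture_kb)
    assert ab.count == ba.count
    assert ab.target_names == ba.target_names


def test_self_intersection_is_full_target_set(fixture_kb):
    r = shared("Cannabidiol", "Cannabidiol", fixture_kb)
    ts = target_set("Cannabidiol", fixture_kb)
    assert r.count == len(ts)


def test_combination_target_set_is_union_of_components(fixture_kb):
    combo = target_set("Fluoxetine+risperidone+melatonin", fixture_kb)
    union = set()
    for name in ("Fluoxetine", "Risperidone", "Melatonin"):
        cid = fixture_kb.resolve_name(name)
        union |= target_set(Treatment("tmp", name, [cid]), fixture_kb)
    assert combo == union


def test_union_consistency_of_combination_rows(fixture_kb):
    """Combination shared-name lists are recoverable from simpler rows."""
    flx_risp = set(shared("Cannabidiol", "Fluoxetine+risperidone", fixture_kb).target_names)
    melatonin = set(
        shared("Cannabidiol", "Controlled-release melatonin", fixture_kb).target_names
    )
    triple = set(
        shared("Cannabidiol", "Fluoxetine+risperidone+melatonin", fixture_kb).target_names
    )
    assert flx_risp | melatonin == triple
    assert len(triple) == 13

    memantine = set(shared("Cannabidiol", "Memantine", fixture_kb).target_names)
    sulf_risp = set(shared("Cannabidiol", "Sulforaphane+Risperidone", fixture_kb).target_names)
    mem_risp = set(shared("Cannabidiol", "Memantine+Risperidone", fixture_kb).target_names)
    assert memantine | sulf_risp == mem_risp
    assert len(mem_risp) == 13


def test_monotonicity_adding_component_never_decreases_overlap(fixture_kb):
    risp = shared("Cannabidiol", "Sulforaphane+Risperidone", fixture_kb).count
    mem_risp = shared("Cannabidiol", "Memantine+Risperidone", fixture_kb).count
    assert mem_risp >= risp
    flx_risp = shared("Cannabidiol", "Fluoxetine+risperidone", fixture_kb).count
    triple = shared("Cannabidiol", "Fluoxetine+risperidone+melatonin", fixture_kb).count
    assert triple >= flx_risp


def test_matrix_keeps_zero_rows_unless_filtered(fixture_kb):
    others = [
        t for t in fixture_kb.treatments.values() if t.label != "Cannabidiol"
    ]
    full = pairwise_matrix("Cannabidiol", others, fixture_kb)
    assert len(full) == 28
    nonzero = pairwise_matrix("Cannabidiol", others, fixture_kb, nonzero_only=True)
    assert len(nonzero) == 17  # the published table prints only these rows
    assert {(r.comparator_label.lower(), r.count) for r in nonzero} == {
        (label.lower(), n) for label, n in TABLE3_COUNTS
    }


def test_empty_comparator_list_gives_empty_matrix(fixture_kb):
    assert pairwise_matrix("Cannabidiol", [], fixture_kb) == []


def test_matrix_cells_equal_brute_force_on_synthetic_kb(tmp_path):
    paths, truth = generate(
        GeneratorParams(n_drugs=40, n_treatments=8, seed=11), tmp_path
    )
    kb, _ = build_kb(paths["drugbank"], paths["targets"], paths["pathways"])
    load_treatments(paths["treatments"], kb)
    for label, row in truth.shared_counts.items():
        for other, expected in row.items():
            assert shared(label, other, kb).count == expected
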