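"""Synthetic input-ecosystem generator with built-in ground truth.

Generates a complete mock input bundle — DrugBank-dialect XML, drug–target
TSV, pathway TSV and a treatments file — from seeded sampling, together
with a :class:`GroundTruth` computed by direct set algebra inside the
generator (never through the pipeline's own code paths).  The ground truth
is the oracle for equivalence testing.

Association model: every drug owns a *private* block of category, target
and pathway names that no other drug can draw; each association slot is
diverted to a *shared pool* with probability ``overlap_bias``.  At
``overlap_bias=0`` association sets are pairwise disjoint, so every
candidate set and every cross-treatment target intersection is empty; at
1.0 all associations come from the shared pool.  No attempt is made to
match real-database degree distributions — tests need controllable
overlap, not realism.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

# keyword pool: some phrases match the shipped rule table, some do not
_KEYWORD_POOL = [
    "upregulating antioxidants",
    "inhibiting nuclear factor kappa B",
    "reducing interleukin 6 levels",
    "inhibiting D2 dopaminergic receptors",
    "modulating mitochondrial biogenesis",
    "unknown mechanism of action",
]


@dataclass
class GeneratorParams:
    n_drugs: int = 50
    n_categories: int = 12
    n_targets: int = 30
    n_pathways: int = 8
    categories_per_drug: tuple[int, int] = (0, 4)
    targets_per_drug: tuple[int, int] = (0, 6)
    pathways_per_drug: tuple[int, int] = (0, 2)
    n_treatments: int = 10
    components_per_treatment: tuple[int, int] = (1, 3)
    overlap_bias: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_drugs", "n_categories", "n_targets", "n_pathways",
                     "n_treatments"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("categories_per_drug", "targets_per_drug",
                     "pathways_per_drug", "components_per_treatment"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} range {lo}..{hi} is not well-ordered")
        if not 0.0 <= self.overlap_bias <= 1.0:
            raise ValueError("overlap_bias must be in [0, 1]")
        if self.targets_per_drug[1] > self.n_targets:
            raise ValueError("targets_per_drug exceeds n_targets")
        if self.categories_per_drug[1] > self.n_categories:
            raise ValueError("categories_per_drug exceeds n_categories")
        if self.pathways_per_drug[1] > self.n_pathways:
            raise ValueError("pathways_per_drug exceeds n_pathways")
        if self.components_per_treatment[1] > self.n_drugs:
            raise ValueError("components_per_treatment exceeds n_drugs")


@dataclass
class GroundTruth:
    """Brute-force expectations, keyed by treatment label."""

    candidates: dict[str, dict[str, list[str]]]  # label -> route -> drug names
    shared_counts: dict[str, dict[str, int]]  # label -> label -> count
    graph_counts: dict[str, dict[str, dict[str, int]]]  # label -> view -> n/e
    drugs: list[str] = field(default_factory=list)
    associations: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _draw(rng: random.Random, pool: list[str], private_prefix: str,
          count: int, bias: float) -> set[str]:
    out: set[str] = set()
    k = 0
    while len(out) < count:
        if rng.random() < bias:
            out.add(rng.choice(pool))
        else:
            out.add(f"{private_prefix}_{k}")
        k += 1
    return out


def generate(
    params: GeneratorParams, outdir: str | Path
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a bundle into *outdir* and return its paths plus ground truth.

    Deterministic: identical params (including seed) give byte-identical
    files on every run.
    """
    params.validate()
    rng = random.Random(params.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    drugs = [f"drug{i:03d}" for i in range(params.n_drugs)]
    cat_pool = [f"category{i:03d}" for i in range(params.n_categories)]
    tgt_pool = [f"target protein {i:03d}" for i in range(params.n_targets)]
    pwy_pool = [
        (f"SMP{10000 + i:05d}", f"pathway {i:03d}") for i in range(params.n_pathways)
    ]
    pwy_name = dict(pwy_pool)

    cats: dict[str, set[str]] = {}
    tgts: dict[str, set[str]] = {}
    pwys: dict[str, set[str]] = {}
    for d in drugs:
        cats[d] = _draw(rng, cat_pool, f"{d} private category",
                        rng.randint(*params.categories_per_drug), params.overlap_bias)
        tgts[d] = _draw(rng, tgt_pool, f"{d} private target",
                        rng.randint(*params.targets_per_drug), params.overlap_bias)
        n_p = rng.randint(*params.pathways_per_drug)
        chosen: set[str] = set()
        k = 0
        while len(chosen) < n_p:
            if rng.random() < params.overlap_bias:
                chosen.add(rng.choice(pwy_pool)[0])
            else:
                pid = f"SMP{20000 + drugs.index(d) * 10 + k:05d}"
                pwy_name.setdefault(pid, f"{d} private pathway {k}")
                chosen.add(pid)
            k += 1
        pwys[d] = chosen

    treatments: list[dict] = []
    for t in range(params.n_treatments):
        k = rng.randint(*params.components_per_treatment)
        comps = sorted(rng.sample(drugs, k))
        label = "+".join(comps)
        keywords = {
            c: sorted(rng.sample(_KEYWORD_POOL, rng.randint(0, 2)))
            for c in comps
        }
        treatments.append(
            {
                "label": label,
                "components": comps,
                "effects": [f"synthetic effect {t}"],
                "keywords": {c: kws for c, kws in keywords.items() if kws},
            }
        )

    # -- write bundle ---------------------------------------------------
    paths = {
        "drugbank": outdir / "drugbank.xml",
        "targets": outdir / "targets.tsv",
        "pathways": outdir / "pathways.tsv",
        "treatments": outdir / "treatments.json",
        "ground_truth": outdir / "ground_truth.json",
    }
    xml = ['<?xml version="1.0" encoding="UTF-8"?>', "<drugbank>"]
    for i, d in enumerate(drugs):
        xml.append("  <drug>")
        xml.append(f'    <drugbank-id primary="true">DB{10000 + i:05d}</drugbank-id>')
        xml.append(f"    <name>{escape(d)}</name>")
        xml.append("    <categories>")
        for c in sorted(cats[d]):
            xml.append(
                f"      <category><category-name>{escape(c)}</category-name></category>"
            )
        xml.append("    </categories>")
        xml.append("  </drug>")
    xml.append("</drugbank>")
    paths["drugbank"].write_text("\n".join(xml) + "\n", encoding="utf-8")

    rows = ["drug\ttarget"]
    for d in drugs:
        rows.extend(f"{d}\t{t}" for t in sorted(tgts[d]))
    paths["targets"].write_text("\n".join(rows) + "\n", encoding="utf-8")

    rows = ["pathway_id\tpathway_name\tdrug"]
    for d in drugs:
        rows.extend(f"{p}\t{pwy_name[p]}\t{d}" for p in sorted(pwys[d]))
    paths["pathways"].write_text("\n".join(rows) + "\n", encoding="utf-8")

    paths["treatments"].write_text(
        json.dumps({"treatments": treatments}, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )

    truth = _ground_truth(drugs, cats, tgts, pwys, treatments, max_assoc=2)
    paths["ground_truth"].write_text(truth.to_json() + "\n", encoding="utf-8")
    return paths, truth


def _candidates(
    assoc: dict[str, set[str]], comps: set[str], drugs: list[str]
) -> list[str]:
    pool = set().union(*(assoc[c] for c in comps)) if comps else set()
    return sorted(d for d in drugs if d not in comps and assoc[d] & pool)


def _ground_truth(
    drugs: list[str],
    cats: dict[str, set[str]],
    tgts: dict[str, set[str]],
    pwys: dict[str, set[str]],
    treatments: list[dict],
    max_assoc: int,
) -> GroundTruth:
    """Direct double-loop set algebra over the sampled associations."""
    candidates: dict[str, dict[str, list[str]]] = {}
    shared: dict[str, dict[str, int]] = {}
    graph_counts: dict[str, dict[str, dict[str, int]]] = {}
    # keywords accumulate per compound across all treatment records
    keyword_union: dict[str, set[str]] = {}
    for t in treatments:
        for c, kws in (t.get("keywords") or {}).items():
            keyword_union.setdefault(c, set()).update(kws)
    for t in treatments:
        comps = set(t["components"])
        label = t["label"]
        candidates[label] = {
            "categories": _candidates(cats, comps, drugs),
            "targets": _candidates(tgts, comps, drugs),
            "pathways": _candidates(pwys, comps, drugs),
        }
        union_t = set().union(*(tgts[c] for c in comps))
        shared[label] = {}
        for u in treatments:
            union_u = set().union(*(tgts[c] for c in u["components"]))
            shared[label][u["label"]] = len(union_t & union_u)
        graph_counts[label] = {
            "categories": _category_graph_counts(t, cats, max_assoc),
            "targets": _target_graph_counts(t, tgts, max_assoc),
            "pathways": _pathway_graph_counts(t, pwys, keyword_union, drugs),
        }
    return GroundTruth(candidates, shared, graph_counts, drugs,
                       {d: {"categories": sorted(cats[d]),
                            "targets": sorted(tgts[d]),
                            "pathways": sorted(pwys[d])} for d in drugs})


def _category_graph_counts(t: dict, cats: dict[str, set[str]],
                           max_assoc: int) -> dict[str, int]:
    comps = t["components"]
    comp_set = set(comps)
    members: dict[str, set[str]] = {}
    for d, cs in cats.items():
        for c in cs:
            members.setdefault(c, set()).add(d)
    treatment_cats = sorted(set().union(*(cats[c] for c in comps)))
    assoc_nodes: set[str] = set()
    cat_assoc_edges = 0
    for c in treatment_cats:
        picks = sorted(members[c] - comp_set, key=str.lower)[:max_assoc]
        assoc_nodes.update(picks)
        cat_assoc_edges += len(picks)
    comp_cat_edges = sum(len(cats[c]) for c in comps)
    n_nodes = 1 + len(comps) + len(treatment_cats) + len(assoc_nodes) + 1
    n_edges = (
        len(comps) + comp_cat_edges + cat_assoc_edges + len(treatment_cats)
        + (0 if treatment_cats else len(comps))
    )
    return {"nodes": n_nodes, "edges": n_edges}


def _rule_patterns() -> list[tuple[str, str]]:
    """Independent single-pass read of the shipped rule table text."""
    from importlib import resources

    text = (
        resources.files("neurorepo")
        .joinpath("data/default_rules.tsv")
        .read_text(encoding="utf-8")
    )
    out = []
    for line in text.splitlines()[1:]:
        if line.strip():
            pattern, pathway = line.split("\t")[:2]
            out.append((pattern.lower(), pathway))
    return out


def _pathway_graph_counts(
    t: dict,
    pwys: dict[str, set[str]],
    keyword_union: dict[str, set[str]],
    drugs: list[str],
) -> dict[str, int]:
    comps = t["components"]
    comp_set = set(comps)
    patterns = _rule_patterns()
    members: dict[str, set[str]] = {}
    for d in drugs:
        for p in pwys[d]:
            members.setdefault(p, set()).add(d)
    n_kw = n_gp = kw_gp_edges = 0
    for c in comps:
        kws = keyword_union.get(c, set())
        n_kw += len(kws)
        gp_of_comp: set[str] = set()
        for kw in kws:
            hits = {pw for pat, pw in patterns if pat in kw.lower()}
            kw_gp_edges += len(hits)
            gp_of_comp |= hits
        n_gp += len(gp_of_comp)
    smpdb_nodes = set().union(*(pwys[c] for c in comps))
    comp_sp_edges = sum(len(pwys[c]) for c in comps)
    assoc_nodes: set[str] = set()
    sp_assoc_edges = 0
    for p in sorted(smpdb_nodes):
        others = members[p] - comp_set
        assoc_nodes.update(others)
        sp_assoc_edges += len(others)
    n_missing = sum(1 for c in comps if not pwys[c])
    n_nodes = 1 + len(comps) + n_kw + n_gp + len(smpdb_nodes) + len(assoc_nodes) + n_missing + 1
    n_edges = (
        len(comps) + n_kw + kw_gp_edges + comp_sp_edges + sp_assoc_edges
        + n_missing + n_gp + (0 if n_gp else len(comps))
    )
    return {"nodes": n_nodes, "edges": n_edges}


def _target_graph_counts(t: dict, tgts: dict[str, set[str]],
                         max_assoc: int) -> dict[str, int]:
    comps = t["components"]
    comp_set = set(comps)
    drugs_of: dict[str, set[str]] = {}
    for d, ts in tgts.items():
        for tg in ts:
            drugs_of.setdefault(tg, set()).add(d)
    treatment_tgts = sorted(set().union(*(tgts[c] for c in comps)))
    assoc_nodes: set[str] = set()
    missing_nodes = 0
    tgt_out_edges = 0
    for tg in treatment_tgts:
        others = drugs_of[tg] - comp_set
        if not others:
            missing_nodes += 1
            tgt_out_edges += 1
        else:
            picks = sorted(others, key=str.lower)[:max_assoc]
            assoc_nodes.update(picks)
            tgt_out_edges += len(picks)
    comp_tgt_edges = sum(len(tgts[c]) for c in comps)
    n_nodes = 1 + len(comps) + len(treatment_tgts) + len(assoc_nodes) + missing_nodes + 1
    n_edges = (
        len(comps) + comp_tgt_edges + tgt_out_edges + len(treatment_tgts)
        + (0 if treatment_tgts else len(comps))
    )
    return {"nodes": n_nodes, "edges": n_edges}
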