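"""End-to-end pipeline driver: ingest → curate → classify → analyse → export.

``run_all`` executes every stage over a :class:`RunConfig`, writing all
artifacts (store, TSV reports, graphs, summary and dashboard feed) into an
output directory with structured logging.  Re-running on unchanged inputs
produces byte-identical artifacts; every number in the summary is
recomputable from the store by the corresponding module function.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .feed import export_dashboard_feed, write_feed
from .graphs import build_view, export_graph
from .ingest import build_kb
from .kb import KnowledgeBase
from .normalize import Normalizer
from .pathways import classify_all, default_rules, load_rules
from .repositioning import count_report
from .shared_targets import pairwise_matrix
from .treatments import availability_summary, load_treatments

log = logging.getLogger("neurorepo")


@dataclass
class RunConfig:
    drugbank: str | None = None
    targets: str | None = None
    pathways: str | None = None
    treatments: str | None = None
    store: str = "kb.sqlite"
    rules: str | None = None  # default rule table when unset
    max_assoc: int = 2
    outdir: str = "artifacts"
    log_level: str = "INFO"
    seed: int = 0  # forwarded to the synthetic generator only
    # normalization toggles (defaults give case-insensitive,
    # whitespace-collapsed, punctuation-tight matching)
    casefold: bool = True
    collapse_whitespace: bool = True
    collapse_punctuation_spaces: bool = True

    def normalizer(self) -> Normalizer:
        return Normalizer(
            self.casefold, self.collapse_whitespace, self.collapse_punctuation_spaces
        )

    def validate_paths(self) -> None:
        for name in ("drugbank", "targets", "pathways", "treatments", "rules"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"config {name}: no such file {value!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=True), encoding="utf-8"
        )


def run_all(config: RunConfig) -> int:
    """Execute the full pipeline; returns 0 iff no stage errored.

    Stage failures stop the run but keep partial artifacts in place for
    inspection, logging the failing stage name.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(levelname)s %(name)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        config.validate_paths()
        rules = load_rules(config.rules) if config.rules else default_rules()

        stage = "ingest"
        kb, report = build_kb(
            config.drugbank, config.targets, config.pathways,
            kb=KnowledgeBase(config.normalizer()),
        )
        log.info("ingest: %d accepted, %d rejected", report.accepted,
                 len(report.rejects))
        if report.rejects:
            (outdir / "rejects.txt").write_text(
                "\n".join(report.rejects) + "\n", encoding="utf-8"
            )

        stage = "load-treatments"
        if config.treatments:
            loaded = load_treatments(config.treatments, kb)
            log.info("treatments: %d loaded", len(loaded))

        stage = "integrity"
        violations = kb.integrity_check()
        if violations:
            for v in violations:
                log.error("integrity: %s %s", v.kind, v.message)
            raise RuntimeError(f"{len(violations)} integrity violations")
        kb.save(outdir / Path(config.store).name)
        kb.export_tsv(outdir / "tables")

        stage = "classify"
        profiles = classify_all(kb, rules)
        with open(outdir / "pathway_profiles.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("compound\tpathways\tunmatched\n")
            for cid in sorted(profiles, key=lambda c: kb.compounds[c].preferred_name):
                p = profiles[cid]
                fh.write(
                    f"{kb.compounds[cid].preferred_name}\t"
                    f"{'|'.join(sorted(x.value for x in p.pathways))}\t"
                    f"{'|'.join(sorted(p.unmatched))}\n"
                )

        stage = "enumerate"
        report_df = count_report(kb)
        report_df.to_csv(outdir / "count_report.tsv", sep="\t", index=False)

        stage = "shared-targets"
        treatments = sorted(kb.treatments.values(), key=lambda t: t.label.lower())
        with open(outdir / "shared_targets.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("main\tcomparator\tcount\ttarget_names\n")
            for t in treatments:
                for r in pairwise_matrix(t, [u for u in treatments if u is not t], kb):
                    fh.write(
                        f"{r.main_label}\t{r.comparator_label}\t{r.count}\t"
                        f"{'; '.join(r.target_names)}\n"
                    )

        stage = "graphs"
        graph_dir = outdir / "graphs"
        graph_dir.mkdir(exist_ok=True)
        for t in treatments:
            for view in ("categories", "pathways", "targets"):
                g = build_view(t, kb, view, rules, config.max_assoc)
                safe = "".join(ch if ch.isalnum() else "_" for ch in t.label)[:60]
                export_graph(g, "graphml", graph_dir / f"{safe}.{view}.graphml")
                export_graph(g, "json", graph_dir / f"{safe}.{view}.json")

        stage = "report"
        avail = availability_summary(kb)
        summary = {
            "n_treatments": len(kb.treatments),
            "n_compounds": len(kb.compounds),
            "n_component_compounds": int(len(avail)),
            "n_components_with_categories": int(avail["has_categories"].sum()),
            "n_components_with_targets": int(avail["has_targets"].sum()),
            "n_components_with_smpdb": int(avail["has_smpdb"].sum()),
            "global_candidates": {
                route: int(
                    report_df.loc[
                        report_df["treatment"] == "Global", f"candidates_by_{route}"
                    ].iloc[0]
                )
                for route in ("categories", "targets", "pathways")
            },
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
        avail.to_csv(outdir / "availability.tsv", sep="\t", index=False)

        stage = "export-feed"
        feed = export_dashboard_feed(kb, rules, config.max_assoc)
        write_feed(feed, outdir / "dashboard_feed.json")
    except Exception:
        log.exception("pipeline failed at stage %s", stage)
        return 1
    log.info("pipeline complete: artifacts in %s", outdir)
    return 0
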