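"""End-to-end orchestration from a single YAML configuration.

Stages: count -> call -> compare -> clusters -> gdmr -> profile -> overlap.
Every numeric threshold of the analysis lives in :class:`PipelineConfig` so a
run is fully described by its config and seed; each stage writes a TSV and
the run closes with a markdown/html report of per-stage tallies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clusters as clu
from . import comparison as cmp
from . import counting, io, methylation
from .aseg import call_hybrid
from .design import TISSUES, hybrid_designs, parse_hybrid

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class Thresholds:
    min_gene_reads: int = 20
    q_ase: float = 0.05
    tier: int = 9
    cluster_gap: int = 1_000_000
    cluster_perms: int = 2_000
    site_reads: int = 5
    window: int = 200
    step: int = 20
    min_sites: int = 6
    fdr_gdmr: float = 0.01
    min_diff: float = 0.30
    min_hyper: float = 0.40
    merge_gap: int = 200
    flank: int = 2000

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value <= 0:
                raise PipelineError(f"threshold {name} must be positive")


@dataclass
class PipelineConfig:
    gff: str
    counts: str
    outdir: str
    vcf: dict[str, str] = field(default_factory=dict)  # hybrid -> path
    methylation: str | None = None
    methyl_hybrid: str = "MC/CM"
    hybrids: list[str] = field(default_factory=lambda: ["BC/CB"])
    tissues: list[str] = field(default_factory=lambda: list(TISSUES))
    contexts: list[str] = field(default_factory=lambda: ["CG", "CHG"])
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the per-stage summary dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: config %s seed %d", config.digest(),
             config.seed)
    summary: dict = {"config_digest": config.digest(), "seed": config.seed}
    thr = config.thresholds
    stage = "inputs"
    try:
        for path in [config.gff, config.counts, *config.vcf.values()]:
            if not Path(path).exists():
                raise PipelineError(f"input file not found: {path}")
        genes = io.read_gff3(config.gff)
        per_snp = io.read_table(config.counts, kind="counts")

        stage = "count+call"
        calls: dict[tuple[str, str], pd.DataFrame] = {}
        for hybrid in config.hybrids:
            informative = None
            if hybrid in config.vcf:
                informative = counting.informative_snps_from_vcf(
                    config.vcf[hybrid])
            for tissue in config.tissues:
                c = call_hybrid(per_snp, genes, hybrid, tissue,
                                q_threshold=thr.q_ase,
                                tier_required=thr.tier,
                                min_total=thr.min_gene_reads,
                                informative=informative)
                calls[(hybrid, tissue)] = c
        all_calls = pd.concat(calls.values(), ignore_index=True)
        io.write_table(all_calls, out / "aseg_calls.tsv")
        summary["aseg"] = {
            f"{h}:{t}": int((c["status"] == "biased").sum())
            for (h, t), c in calls.items()}

        stage = "compare"
        for hybrid in config.hybrids:
            if not {"embryo", "endosperm"} <= set(config.tissues):
                break
            res = cmp.cross_tissue_table(calls[(hybrid, "embryo")],
                                         calls[(hybrid, "endosperm")],
                                         hybrid)
            frame = cmp.table_frame(res["tables"])
            io.write_table(frame, out /
                           f"comparison_{hybrid.replace('/', '-')}.tsv")
            summary.setdefault("cross_tissue_consistent", {})[hybrid] = \
                res["n_consistent"]
        if len(config.hybrids) >= 2:
            for tissue in config.tissues:
                by_hybrid = {h: calls[(h, tissue)] for h in config.hybrids}
                venn = cmp.cross_hybrid_overlap(by_hybrid, tissue)
                rows = [(k, v) for k, v in venn["venn"].items()]
                io.write_table(pd.DataFrame(rows, columns=["region",
                                                           "count"]),
                               out / f"venn_{tissue}.tsv")
                summary.setdefault("venn_all_hybrids", {})[tissue] = \
                    venn["n_all_hybrids"]

        stage = "clusters"
        cluster_stats = []
        for (hybrid, tissue), c in calls.items():
            biased = c[c["status"] == "biased"].merge(
                genes[["gene_id", "chrom", "start", "end"]], on="gene_id")
            if len(biased) < 2:
                continue
            recs = clu.find_clusters(biased, max_gap=thr.cluster_gap)
            frame = clu.clusters_frame(recs)
            frame.insert(0, "hybrid", hybrid)
            frame.insert(1, "tissue", tissue)
            cluster_stats.append(frame)
            enrich = clu.cluster_enrichment(
                biased["gene_id"], genes[["gene_id", "chrom", "start"]],
                max_gap=thr.cluster_gap, n_perm=thr.cluster_perms,
                seed=config.seed)
            summary.setdefault("clusters", {})[f"{hybrid}:{tissue}"] = {
                "n_clusters": len(recs),
                "mean_distance": (clu.mean_adjacent_distance(biased)
                                  if len(biased) > 1 else None),
                "perm_p": enrich["perm_p"], "fisher_p": enrich["fisher_p"]}
        if cluster_stats:
            io.write_table(pd.concat(cluster_stats, ignore_index=True),
                           out / "clusters.tsv")

        stage = "gdmr"
        gdmrs_all = []
        if config.methylation:
            sites = io.read_table(config.methylation, kind="methylation")
            for context in config.contexts:
                gdmrs, _ = methylation.call_gdmrs(
                    sites, context, window=thr.window, step=thr.step,
                    min_sites=thr.min_sites, min_reads=thr.site_reads,
                    fdr=thr.fdr_gdmr, min_diff=thr.min_diff,
                    min_hyper_level=thr.min_hyper,
                    merge_gap=thr.merge_gap)
                gdmrs_all.append(gdmrs)
                summary.setdefault("gdmrs", {})[context] = len(gdmrs)
            gdmr_frame = pd.concat(gdmrs_all, ignore_index=True)
            io.write_table(gdmr_frame, out / "gdmrs.tsv")
            if len(gdmr_frame):
                io.write_bed(gdmr_frame, out / "gdmrs.bed")

            stage = "profile"
            for context in config.contexts:
                prof = methylation.metagene_profile(
                    sites, genes, flank=thr.flank, context=context,
                    min_reads=thr.site_reads)
                io.write_table(prof, out / f"profile_{context}.tsv")

            stage = "overlap"
            meth_calls = calls.get((config.methyl_hybrid, "endosperm"))
            if meth_calls is not None and len(gdmr_frame):
                ov = methylation.overlap_aseg_gdmr(meth_calls, gdmr_frame,
                                                   genes)
                io.write_table(ov, out / "aseg_gdmr_overlap.tsv")
                summary["aseg_gdmr_overlaps"] = len(ov)
    except PipelineError:
        log.error("stage %s failed", stage)
        raise
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    stage_report = _report(summary)
    (out / "report.md").write_text(stage_report)
    (out / "report.html").write_text(
        "<html><body><pre>\n" + stage_report + "</pre></body></html>\n")
    log.info("pipeline done")
    return summary


def _report(summary: dict) -> str:
    lines = ["# hybridase run report", "",
             f"- config digest: {summary['config_digest']}",
             f"- seed: {summary['seed']}", ""]
    for key in ("aseg", "cross_tissue_consistent", "venn_all_hybrids",
                "clusters", "gdmrs"):
        if key in summary:
            lines.append(f"## {key}")
            lines.append("```")
            lines.append(json.dumps(summary[key], indent=2, default=str))
            lines.append("```")
            lines.append("")
    if "aseg_gdmr_overlaps" in summary:
        lines.append(f"ASEG x gDMR overlaps: {summary['aseg_gdmr_overlaps']}")
        lines.append("")
    return "\n".join(lines)
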