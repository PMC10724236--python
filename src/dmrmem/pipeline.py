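"""End-to-end orchestration: pretreatment, summaries, the three pairwise DMR
calls, annotation, memory classification and expression integration.

Every intermediate is written under the output directory and the run report
records in/out counts for each filtering step, so a re-run with the same
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotate, classify, dmr, io, simulate, summary, transomics
from .core import GenomeAnnotation
from .dmr import DmrParams

log = logging.getLogger("dmrmem")


@dataclass
class PipelineConfig:
    outdir: str = "dmrmem_out"
    seed: int = 0
    #: when set, inputs are simulated; otherwise sample_paths must be given
    simulation: simulate.SimulationConfig | None = field(
        default_factory=simulate.SimulationConfig
    )
    #: group -> list of cytosine-report paths (file-based runs)
    sample_paths: dict | None = None
    chrom_sizes_path: str | None = None
    genes_path: str | None = None
    cgis_path: str | None = None
    expression_path: str | None = None
    expression_groups: dict | None = None
    deg_list_path: str | None = None
    dialect: str = "cytosine_report"
    min_depth: int = 10
    window_size: int = 1000
    window_step: int = 500
    dmr_params: DmrParams = field(default_factory=DmrParams)
    flank: int = 10_000
    promoter_up: int = 2000
    promoter_down: int = 500
    deg_p_threshold: float = 0.05
    deg_lfc_threshold: float = 1.0
    source_group: str = "MEF"
    target_group: str = "ISC"
    reprog_group: str = "iISC"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", "default")
        dp = raw.pop("dmr_params", None)
        cfg = cls(**raw)
        if sim is None:
            cfg.simulation = None
        elif sim != "default":
            cfg.simulation = simulate.SimulationConfig(**sim)
        if dp:
            cfg.dmr_params = DmrParams(**dp)
        return cfg

    def validate(self) -> None:
        if self.simulation is None:
            if not self.sample_paths or not self.chrom_sizes_path:
                raise ValueError(
                    "file-based runs need sample_paths and chrom_sizes_path"
                )
            for group, paths in self.sample_paths.items():
                for p in paths:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"{group}: missing input {p}")
            for p in (self.genes_path, self.cgis_path, self.expression_path,
                      self.deg_list_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(f"missing input {p}")
        self.dmr_params.validate()


def _load_inputs(config: PipelineConfig):
    import pandas as pd

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        annotation = simulate.simulate_annotation(sim)
        truth = simulate.plant_truth(sim, annotation)
        samples = simulate.simulate_samples(sim, annotation, truth)
        expr = simulate.simulate_expression(sim, truth)
        return annotation, samples, expr, truth
    chroms = io.read_chrom_sizes(config.chrom_sizes_path)
    genes = (
        io.read_gene_table(config.genes_path)
        if config.genes_path
        else pd.DataFrame(
            columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exons"]
        )
    )
    cgis = (
        io.read_bed(config.cgis_path, names=("chrom", "start", "end"))
        if config.cgis_path
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    annotation = GenomeAnnotation(chroms=chroms, genes=genes, cgis=cgis)
    samples = []
    for group, paths in config.sample_paths.items():
        for p in paths:
            samples.append(
                io.read_cytosine_report(p, dialect=config.dialect, group=group)
            )
    expr = None
    if config.expression_path:
        expr = io.read_expression_tsv(
            config.expression_path, groups=config.expression_groups or {}
        )
    return annotation, samples, expr, None


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    annotation, samples, expr, truth = _load_inputs(config)
    io.write_chrom_sizes(annotation, out / "chrom_sizes.tsv")
    io.write_gene_table(annotation, out / "genes.tsv")
    io.write_bed(annotation.cgis, out / "cgis.bed")
    if truth is not None:
        io.write_bed(
            truth.regions.rename(columns={"class_label": "name"}),
            out / "planted_truth.bed",
            name_col="name",
        )
    for s in samples:
        io.write_cytosine_report(s, out / f"{s.sample_id}.cytosine_report.tsv")
    report["stages"]["inputs"] = {
        "n_samples": len(samples),
        "groups": {g: sum(s.group == g for s in samples) for g in
                   {s.group for s in samples}},
    }

    # pretreatment: strand merge + depth/autosome filter
    merged = [io.merge_cpg_strands(s) for s in samples]
    treated = [io.pretreat(s, annotation, config.min_depth) for s in merged]
    report["stages"]["pretreat"] = {
        s.sample_id: {"in": len(m.calls), "out": len(t.calls)}
        for s, m, t in zip(samples, merged, treated)
    }
    log.info("pretreat: %s", report["stages"]["pretreat"])

    # summaries
    windows = summary.make_windows(annotation, config.window_size, config.window_step)
    global_levels = {}
    corr = {}
    for ctx in ("CpG", "CHH", "CHG"):
        vectors = [summary.window_levels(s, windows, context=ctx) for s in treated]
        mat = summary.pairwise_correlation(vectors)
        mat.to_csv(out / f"correlation_{ctx}.tsv", sep="\t")
        corr[ctx] = mat
        for s in treated:
            try:
                global_levels.setdefault(s.sample_id, {})[ctx] = summary.global_level(
                    s, ctx
                )
            except ValueError:
                global_levels.setdefault(s.sample_id, {})[ctx] = None
    report["stages"]["summary"] = {
        "n_windows": len(windows),
        "global_levels": global_levels,
    }

    # three pairwise DMR calls (focal group listed first)
    by_group: dict = {}
    for s in treated:
        by_group.setdefault(s.group, []).append(s)
    src, tgt, rep = config.source_group, config.target_group, config.reprog_group
    comparisons = {
        f"{src}_vs_{tgt}": (by_group[src], by_group[tgt]),
        f"{src}_vs_{rep}": (by_group[src], by_group[rep]),
        f"{rep}_vs_{tgt}": (by_group[rep], by_group[tgt]),
    }
    dmr_sets = {}
    for name, (ga, gb) in comparisons.items():
        cands = dmr.call_candidates(ga, gb, annotation, config.dmr_params)
        retained = dmr.apply_retention_filter(cands, config.dmr_params)
        dmr.write_dmr_bed(retained, out / f"dmrs_{name}.bed")
        dmr_sets[name] = retained
        report["stages"].setdefault("dmr", {})[name] = {
            "candidates": len(cands),
            "retained": len(retained),
        }
        log.info("dmr %s: %d candidates, %d retained", name, len(cands), len(retained))

    # annotation of every comparison's DMRs
    assoc_by_comparison = {}
    for name, dmrs in dmr_sets.items():
        ann = annotate.annotate_dmrs(
            dmrs, annotation, config.promoter_up, config.promoter_down
        )
        ann.to_csv(out / f"dmrs_{name}.annotated.tsv", sep="\t", index=False)
        assoc = annotate.associated_genes(dmrs, annotation.genes, config.flank)
        assoc_by_comparison[name] = assoc
        report["stages"].setdefault("annotation", {})[name] = {
            "n_dmrs": len(dmrs),
            "n_associations": len(assoc),
        }

    # memory classification of the focal comparison
    focal_name = f"{rep}_vs_{tgt}"
    reference_name = f"{src}_vs_{tgt}"
    classified = classify.classify_memory(
        dmr_sets[focal_name], dmr_sets[reference_name]
    )
    classify.classified_to_frame(classified).to_csv(
        out / "dmrs_classified.tsv", sep="\t", index=False
    )
    counts = classify.class_counts(classified)
    matrix = classify.dmr_sample_matrix(dmr_sets[focal_name], treated)
    matrix.to_csv(out / "dmr_sample_matrix.tsv", sep="\t")
    report["stages"]["classification"] = counts

    # trans-omics
    if expr is not None:
        if config.deg_list_path:
            degs = transomics.read_deg_list(config.deg_list_path)
        else:
            degs = transomics.derive_degs(
                expr, focal=rep, reference=tgt,
                p_threshold=config.deg_p_threshold,
                lfc_threshold=config.deg_lfc_threshold, seed=config.seed,
            )
        transomics.write_deg_list(degs, out / "degs.tsv")
        gene_by_index = {}
        for a in assoc_by_comparison[focal_name]:
            gene_by_index.setdefault(a.dmr_index, set()).add(a.gene_id)
        overlaps = {}
        gene_classes = []
        for direction in ("hyper", "hypo"):
            genes = set()
            for i, c in enumerate(classified):
                if c.dmr.direction == direction:
                    for g in gene_by_index.get(i, ()):
                        genes.add(g)
                        gene_classes.append((g, c.memory_class))
            overlaps[direction] = transomics.intersect_dmr_deg(genes, degs)
        scatter = transomics.fc_scatter_table(
            gene_classes, expr, degs, focal=rep, target=tgt, source=src
        )
        scatter.to_csv(out / "fc_scatter.tsv", sep="\t", index=False)
        io.write_expression_tsv(expr, out / "expression.tsv")
        report["stages"]["transomics"] = {
            "n_degs": len(degs.all),
            "overlap": {
                d: {k: v for k, v in o.items() if not k.startswith("genes")}
                for d, o in overlaps.items()
            },
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
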