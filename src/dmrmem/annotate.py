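"""Genomic annotation of DMRs: position classes, TSS distances, and
gene association within a flanking window.

Classification uses the DMR midpoint with precedence
promoter > exon > intron > intergenic; CGI overlap is a separate boolean
overlay (any shared base). Distances are signed in gene orientation:
negative means the DMR midpoint lies upstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeAnnotation
from .dmr import DMR

PRIMARY_CLASSES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class PositionClass:
    primary: str
    cgi_overlap: bool


@dataclass
class GeneAssociation:
    dmr_index: int
    gene_id: str
    signed_distance_bp: int


def _midpoint(dmr: DMR) -> int:
    return (dmr.start + dmr.end) // 2


def _signed_distance(mid: int, tss: int, strand: str) -> int:
    return mid - tss if strand == "+" else tss - mid


def classify_position(
    dmr: DMR,
    annotation: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> PositionClass:
    """Assign a DMR to promoter/exon/intron/intergenic, with CGI overlay.

    The promoter window is [-promoter_up, +promoter_down] around the TSS in
    gene orientation, inclusive on both bounds.
    """
    mid = _midpoint(dmr)
    genes = annotation.genes[annotation.genes["chrom"] == dmr.chrom]
    primary = "intergenic"
    in_exon = in_intron = in_promoter = False
    for g in genes.itertuples(index=False):
        sd = _signed_distance(mid, g.tss, g.strand)
        if -promoter_up <= sd <= promoter_down:
            in_promoter = True
        if g.tx_start <= mid < g.tx_end:
            if any(s <= mid < e for s, e in g.exons):
                in_exon = True
            else:
                in_intron = True
    if in_promoter:
        primary = "promoter"
    elif in_exon:
        primary = "exon"
    elif in_intron:
        primary = "intron"
    cgis = annotation.cgis[annotation.cgis["chrom"] == dmr.chrom]
    cgi_overlap = bool(
        ((cgis["start"] < dmr.end) & (dmr.start < cgis["end"])).any()
    ) if len(cgis) else False
    return PositionClass(primary=primary, cgi_overlap=cgi_overlap)


def tss_signed_distance(dmr: DMR, genes: pd.DataFrame) -> tuple:
    """Nearest TSS by absolute midpoint distance; ties take the smaller
    gene id. Returns (gene_id, signed_distance_bp)."""
    sub = genes[genes["chrom"] == dmr.chrom]
    if len(sub) == 0:
        raise ValueError(f"no genes on chromosome {dmr.chrom}")
    mid = _midpoint(dmr)
    best = None
    for g in sub.sort_values("gene_id").itertuples(index=False):
        sd = _signed_distance(mid, g.tss, g.strand)
        if best is None or abs(sd) < abs(best[1]):
            best = (g.gene_id, sd)
    return best


def associated_genes(
    dmrs: list, genes: pd.DataFrame, flank: int = 10_000
) -> list:
    """All (DMR, gene) pairs with |signed midpoint-TSS distance| <= flank.

    A DMR may associate with several genes and vice versa.
    """
    out = []
    by_chrom = dict(tuple(genes.groupby("chrom", sort=False)))
    for i, dmr in enumerate(dmrs):
        sub = by_chrom.get(dmr.chrom)
        if sub is None:
            continue
        mid = _midpoint(dmr)
        for g in sub.itertuples(index=False):
            sd = _signed_distance(mid, g.tss, g.strand)
            if abs(sd) <= flank:
                out.append(GeneAssociation(i, g.gene_id, int(sd)))
    return out


def distance_histogram(distances, bins) -> np.ndarray:
    """Counts of signed TSS distances per bin (numpy histogram semantics:
    half-open bins, right edge inclusive in the last bin)."""
    counts, _ = np.histogram(np.asarray(list(distances)), bins=np.asarray(bins))
    return counts


def annotate_dmrs(
    dmrs: list,
    annotation: GenomeAnnotation,
    promoter_up: int = 2000,
    promoter_down: int = 500,
) -> pd.DataFrame:
    """Tabular annotation: BED columns + class + CGI + nearest gene/distance."""
    rows = []
    has_genes = len(annotation.genes) > 0
    for d in dmrs:
        pc = classify_position(d, annotation, promoter_up, promoter_down)
        gene, sd = (None, None)
        if has_genes and (annotation.genes["chrom"] == d.chrom).any():
            gene, sd = tss_signed_distance(d, annotation.genes)
        rows.append(
            {
                "chrom": d.chrom, "start": d.start, "end": d.end, "name": d.name,
                "n_cpgs": d.n_cpgs, "mean_diff": d.mean_diff, "q_value": d.q_value,
                "direction": d.direction, "position_class": pc.primary,
                "cgi_overlap": pc.cgi_overlap, "nearest_gene": gene,
                "tss_distance": sd,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "name", "n_cpgs", "mean_diff", "q_value",
            "direction", "position_class", "cgi_overlap", "nearest_gene",
            "tss_distance",
        ],
    )
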