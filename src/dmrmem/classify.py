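"""Memory-vs-specific classification of reprogramming DMRs and per-sample
DMR methylation matrices.

A focal DMR (reprogrammed vs target comparison) is classified as memory
("mDNA": a source-cell signature abnormally retained) when it overlaps any
reference DMR from the source-vs-target comparison, and as specific
("sDNA": acquired or erased only in the reprogrammed cells) otherwise.
The partition is exhaustive and exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dmr import DMR
from .summary import region_mean_level

MEMORY = "mDNA"
SPECIFIC = "sDNA"


@dataclass
class ClassifiedDMR:
    dmr: DMR
    memory_class: str  # 'mDNA' or 'sDNA'


def classify_memory(
    dmrs_focal: list, dmrs_reference: list, min_overlap_bp: int = 1
) -> list:
    """Split focal DMRs by overlap with the reference DMR set.

    Half-open interval arithmetic: abutting regions share zero bases and
    classify as specific at the default 1 bp threshold.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ref_by_chrom: dict = {}
    for r in dmrs_reference:
        ref_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out = []
    for d in dmrs_focal:
        overlap = 0
        for s, e in ref_by_chrom.get(d.chrom, ()):
            overlap = max(overlap, min(d.end, e) - max(d.start, s))
        cls = MEMORY if overlap >= min_overlap_bp else SPECIFIC
        out.append(ClassifiedDMR(dmr=d, memory_class=cls))
    return out


def class_counts(classified: list) -> dict:
    """Counts of the four direction x memory classes (sum = input size)."""
    counts = {
        "hyper_mDNA": 0, "hyper_sDNA": 0, "hypo_mDNA": 0, "hypo_sDNA": 0,
    }
    for c in classified:
        counts[f"{c.dmr.direction}_{c.memory_class}"] += 1
    return counts


def dmr_sample_matrix(
    dmrs: list,
    samples: list,
    min_reads: int = 5,
    min_cytosines: int = 5,
) -> pd.DataFrame:
    """Per-sample mean methylation over each DMR (heatmap input).

    Rows are DMRs, columns samples; entries follow the >= min_reads /
    >= min_cytosines region rule and are NaN when a sample lacks coverage.
    """
    regions = pd.DataFrame(
        [(d.chrom, d.start, d.end) for d in dmrs], columns=["chrom", "start", "end"]
    )
    data = {}
    for s in samples:
        data[s.sample_id] = region_mean_level(
            s, regions, min_reads=min_reads, min_cytosines=min_cytosines
        )
    return pd.DataFrame(data, index=[d.name for d in dmrs])


def classified_to_frame(classified: list) -> pd.DataFrame:
    from .dmr import dmrs_to_frame

    df = dmrs_to_frame([c.dmr for c in classified])
    df["memory_class"] = [c.memory_class for c in classified]
    return df
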