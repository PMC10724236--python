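"""Differential methylation region (DMR) calling between two groups.

The caller follows the metilene family of segmentation methods: CpG sites
covered in both groups are cut into blocks at large inter-CpG gaps, each
block is recursively bisected at the change-point maximising the difference
between the two sub-segments' mean group differences, recursion stops once
neither sub-segment is more significant than its parent, and the emitted
maximal segments are tested (two-sided Mann-Whitney U on the per-site
pooled group levels) with genome-wide Benjamini-Hochberg correction.
Retention applies the standard filter: >= 20 CpGs, q < 0.05, and an
absolute mean methylation difference > 10%.

One deliberate simplification relative to the published metilene tool: the
candidate significance test (also used for the recursion stop) is a
Mann-Whitney U on per-site group levels rather than a 2D
Kolmogorov-Smirnov statistic — simpler, testable against a closed form,
and the retention filter dominates behaviour in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomeAnnotation

_EPS = 1e-12


@dataclass
class DmrParams:
    max_gap_bp: int = 300
    min_cpgs_candidate: int = 10
    min_cpgs_retain: int = 20
    min_diff: float = 0.10
    q_threshold: float = 0.05
    min_shared_depth: int = 10

    def validate(self) -> None:
        if min(self.max_gap_bp, self.min_cpgs_candidate, self.min_cpgs_retain,
               self.min_shared_depth) <= 0:
            raise ValueError("DmrParams integers must be positive")
        if self.min_diff <= 0 or self.q_threshold <= 0:
            raise ValueError("min_diff and q_threshold must be positive")
        if self.min_cpgs_retain < self.min_cpgs_candidate:
            raise ValueError("min_cpgs_retain must be >= min_cpgs_candidate")


@dataclass
class DMR:
    """A contiguous differentially methylated region.

    mean_diff is signed (group A mean minus group B mean, averaged over
    CpGs); direction is 'hyper' when group A is the more methylated.
    """

    chrom: str
    start: int
    end: int
    n_cpgs: int
    mean_diff: float
    p_value: float
    q_value: float
    direction: str

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def per_cpg_group_levels(
    samples_a: list,
    samples_b: list,
    annotation: GenomeAnnotation,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Pooled per-CpG levels for two groups on shared, well-covered sites.

    Counts are summed across replicates per group; sites are kept when the
    pooled depth reaches ``min_shared_depth`` in both groups and the site is
    autosomal. Returns columns chrom, pos, level_a, level_b, diff.
    """
    params = params or DmrParams()
    params.validate()

    def pooled(samples):
        frames = [
            s.subset_context("CpG")[["chrom", "pos", "meth", "total"]] for s in samples
        ]
        cat = pd.concat(frames, ignore_index=True)
        return cat.groupby(["chrom", "pos"], sort=True, as_index=False).sum()

    a, b = pooled(samples_a), pooled(samples_b)
    a = a[a["total"] >= params.min_shared_depth]
    b = b[b["total"] >= params.min_shared_depth]
    m = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"), how="inner")
    m = m[m["chrom"].isin(annotation.autosomes)]
    m = m.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    m["level_a"] = m["meth_a"] / m["total_a"]
    m["level_b"] = m["meth_b"] / m["total_b"]
    m["diff"] = m["level_a"] - m["level_b"]
    return m[["chrom", "pos", "level_a", "level_b", "diff"]]


def presegment(sites: pd.DataFrame, params: DmrParams) -> list:
    """Cut the site table into blocks at inter-CpG gaps > max_gap_bp.

    Returns (chrom, lo, hi) index triples into ``sites``; blocks with fewer
    than ``min_cpgs_candidate`` sites are dropped.
    """
    blocks = []
    for chrom, sub in sites.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if len(pos) == 0:
            continue
        gaps = np.diff(pos)
        cuts = np.where(gaps > params.max_gap_bp)[0]
        starts = np.concatenate([[0], cuts + 1])
        ends = np.concatenate([cuts + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s >= params.min_cpgs_candidate:
                blocks.append((chrom, int(idx[s]), int(idx[e - 1]) + 1))
    return blocks


def segment_block(levels_a, levels_b, params: DmrParams) -> list:
    """Recursive binary segmentation of one block of per-site group levels.

    Every breakpoint leaving both sides with at least ``min_cpgs_candidate``
    sites is scored by the absolute difference of the two sub-segments' mean
    per-site group differences (the change-point criterion of the metilene
    family); the best breakpoint (leftmost on ties) is taken only while at
    least one sub-segment tests more significant than its parent, so
    segments that are homogeneous in effect are emitted whole rather than
    fragmented by noise.

    Returns (lo, hi, p_value) triples relative to the block, left to right;
    p_value is the Mann-Whitney p of the emitted segment.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("group level vectors must have equal length")
    n = len(a)
    if n == 0:
        return []
    d = a - b
    prefix = np.concatenate([[0.0], np.cumsum(d)])
    m = params.min_cpgs_candidate
    out = []
    stack = [(0, n, None)]
    while stack:
        lo, hi, p = stack.pop()
        if p is None:
            p = test_candidate(a[lo:hi], b[lo:hi])
        if hi - lo >= 2 * m:
            ks = np.arange(lo + m, hi - m + 1)
            mean_left = (prefix[ks] - prefix[lo]) / (ks - lo)
            mean_right = (prefix[hi] - prefix[ks]) / (hi - ks)
            score = np.abs(mean_left - mean_right)
            j = int(np.argmax(score))  # first occurrence -> leftmost tie-break
            k = int(ks[j])
            p_left = test_candidate(a[lo:k], b[lo:k])
            p_right = test_candidate(a[k:hi], b[k:hi])
            if min(p_left, p_right) < p - _EPS:
                stack.append((k, hi, p_right))
                stack.append((lo, k, p_left))
                continue
        out.append((lo, hi, p))
    return sorted(out)


def test_candidate(levels_a, levels_b) -> float:
    """Two-sided Mann-Whitney U on per-site pooled levels of the two groups.

    Degenerate candidates (fewer than two sites, or all values identical)
    return p = 1.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return 1.0
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)
    return min(max(p, np.finfo(float).tiny), 1.0)


def apply_retention_filter(candidates: list, params: DmrParams) -> list:
    """Keep candidates with >= min_cpgs_retain CpGs, q < q_threshold and
    |mean_diff| > min_diff."""
    return [
        c
        for c in candidates
        if c.n_cpgs >= params.min_cpgs_retain
        and c.q_value < params.q_threshold
        and abs(c.mean_diff) > params.min_diff
    ]


def call_candidates(
    samples_a: list,
    samples_b: list,
    annotation: GenomeAnnotation,
    params: DmrParams | None = None,
) -> list:
    """Run levels -> presegmentation -> segmentation -> testing -> BH.

    Returns every tested candidate as a DMR record (before retention
    filtering), sorted by (chrom, start).
    """
    params = params or DmrParams()
    params.validate()
    if len(samples_a) < 1 or len(samples_b) < 1:
        raise ValueError("each group needs at least one replicate")
    sites = per_cpg_group_levels(samples_a, samples_b, annotation, params)
    blocks = presegment(sites, params)
    pos = sites["pos"].to_numpy()
    la = sites["level_a"].to_numpy()
    lb = sites["level_b"].to_numpy()
    diff = sites["diff"].to_numpy()
    cands = []
    for chrom, blo, bhi in blocks:
        for lo, hi, p in segment_block(la[blo:bhi], lb[blo:bhi], params):
            s, e = blo + lo, blo + hi
            md = float(diff[s:e].mean())
            cands.append(
                DMR(
                    chrom=chrom,
                    start=int(pos[s]),
                    end=int(pos[e - 1]) + 1,
                    n_cpgs=e - s,
                    mean_diff=md,
                    p_value=p,
                    q_value=np.nan,
                    direction="hyper" if md > 0 else "hypo",
                )
            )
    if cands:
        q = multipletests([c.p_value for c in cands], method="fdr_bh")[1]
        for c, qv in zip(cands, q):
            c.q_value = float(qv)
    cands.sort(key=lambda c: (c.chrom, c.start))
    return cands


def call_dmrs(
    samples_a: list,
    samples_b: list,
    annotation: GenomeAnnotation,
    params: DmrParams | None = None,
) -> list:
    """Full DMR call between group A (focal) and group B (comparator)."""
    params = params or DmrParams()
    cands = call_candidates(samples_a, samples_b, annotation, params)
    return apply_retention_filter(cands, params)


def dmrs_to_frame(dmrs: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "name": d.name,
                "n_cpgs": d.n_cpgs,
                "mean_diff": d.mean_diff,
                "p_value": d.p_value,
                "q_value": d.q_value,
                "direction": d.direction,
            }
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "name", "n_cpgs", "mean_diff",
            "p_value", "q_value", "direction",
        ],
    )


def write_dmr_bed(dmrs: list, path) -> None:
    """BED6+ with score = -log10 q and extra columns
    (n_cpgs, mean_diff, p, q, direction)."""
    with open(path, "w") as fh:
        for d in dmrs:
            score = -np.log10(max(d.q_value, np.finfo(float).tiny))
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\t{score:.4f}\t.\t"
                f"{d.n_cpgs}\t{d.mean_diff:.6f}\t{d.p_value:.6g}\t"
                f"{d.q_value:.6g}\t{d.direction}\n"
            )


def read_dmr_bed(path) -> list:
    dmrs = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            dmrs.append(
                DMR(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), n_cpgs=int(f[6]),
                    mean_diff=float(f[7]), p_value=float(f[8]), q_value=float(f[9]),
                    direction=f[10],
                )
            )
    return dmrs
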