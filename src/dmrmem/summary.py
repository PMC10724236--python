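"""Global, per-feature and windowed methylation summaries with pairwise
Pearson correlation.

Levels are read-weighted (sum of methylated reads over sum of total reads),
so the level of a concatenation equals the read-weighted mean of its parts.
Region levels follow the >=5 reads / >=5 covered cytosines rule by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, MethylomeSample


@dataclass
class WindowVector:
    """Per-window methylation levels for one sample (NaN = missing)."""

    windows: pd.DataFrame  # chrom, start, end
    levels: np.ndarray
    context: str
    label: str = ""


def global_level(sample: MethylomeSample, context: str = "CpG") -> float:
    """Read-weighted total methylation level for one context."""
    calls = sample.subset_context(context)
    total = int(calls["total"].sum())
    if total == 0:
        raise ValueError(f"no covered cytosines in context {context!r}")
    return float(calls["meth"].sum()) / total


def _region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, pd.DataFrame):
        return regions
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


def region_mean_level(
    sample: MethylomeSample,
    regions,
    min_reads: int = 5,
    min_cytosines: int = 5,
    context: str = "CpG",
) -> np.ndarray:
    """Read-weighted level per region, NaN unless the region has
    >= min_reads total reads and >= min_cytosines covered cytosines."""
    regions = _region_frame(regions)
    calls = sample.subset_context(context)
    out = np.full(len(regions), np.nan)
    by_chrom = {}
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = np.concatenate([[0], np.cumsum(sub["meth"].to_numpy())])
        total = np.concatenate([[0], np.cumsum(sub["total"].to_numpy())])
        covered = np.concatenate([[0], np.cumsum((sub["total"].to_numpy() > 0).astype(int))])
        by_chrom[chrom] = (pos, meth, total, covered)
    for i, r in enumerate(regions.itertuples(index=False)):
        if r.chrom not in by_chrom:
            continue
        pos, meth, total, covered = by_chrom[r.chrom]
        lo = np.searchsorted(pos, r.start, side="left")
        hi = np.searchsorted(pos, r.end, side="left")
        t = total[hi] - total[lo]
        n_cov = covered[hi] - covered[lo]
        if t >= min_reads and n_cov >= min_cytosines and t > 0:
            out[i] = (meth[hi] - meth[lo]) / t
    return out


def make_windows(
    annotation: GenomeAnnotation, size: int = 1000, step: int = 500
) -> pd.DataFrame:
    """Sliding half-open windows per chromosome.

    Windows start at multiples of ``step``; the final window is truncated at
    the chromosome end and generation stops with it, so a chromosome shorter
    than ``size`` yields the single window [0, length).
    """
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    rows = []
    for c in annotation.chroms.itertuples(index=False):
        k = 0
        while True:
            start = k * step
            if start >= c.length:
                break
            end = min(start + size, c.length)
            rows.append((c.name, start, end))
            if start + size > c.length:
                break
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_levels(
    sample: MethylomeSample,
    windows: pd.DataFrame,
    context: str = "CpG",
    min_reads: int = 5,
    min_cytosines: int = 5,
) -> WindowVector:
    levels = region_mean_level(sample, windows, min_reads, min_cytosines, context)
    return WindowVector(
        windows=windows, levels=levels, context=context, label=sample.sample_id
    )


def pairwise_correlation(vectors: list) -> pd.DataFrame:
    """Pearson R matrix over shared non-missing windows (complete-pairs).

    Entries with fewer than 3 shared windows are NaN; the diagonal is 1.
    """
    if not vectors:
        return pd.DataFrame()
    n_win = len(vectors[0].levels)
    ctx = vectors[0].context
    for v in vectors:
        if len(v.levels) != n_win or v.context != ctx:
            raise ValueError("vectors must share window set and context")
    labels = [v.label for v in vectors]
    mat = np.full((len(vectors), len(vectors)), np.nan)
    for i in range(len(vectors)):
        mat[i, i] = 1.0
        for j in range(i + 1, len(vectors)):
            a, b = vectors[i].levels, vectors[j].levels
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 3:
                continue
            x, y = a[ok], b[ok]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def write_window_bedgraph(vector: WindowVector, path) -> None:
    """Export a window vector as bedGraph (missing windows omitted)."""
    with open(path, "w") as fh:
        for (row, level) in zip(vector.windows.itertuples(index=False), vector.levels):
            if not np.isnan(level):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{level:.6f}\n")


def _merge_intervals(intervals) -> tuple[np.ndarray, np.ndarray]:
    if len(intervals) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    ivs = sorted(intervals)
    starts, ends = [ivs[0][0]], [ivs[0][1]]
    for s, e in ivs[1:]:
        if s <= ends[-1]:
            ends[-1] = max(ends[-1], e)
        else:
            starts.append(s)
            ends.append(e)
    return np.asarray(starts), np.asarray(ends)


def _member(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    res = np.zeros(len(pos), dtype=bool)
    res[ok] = pos[ok] < ends[idx[ok]]
    return res


def feature_profile(
    sample: MethylomeSample, annotation: GenomeAnnotation, context: str = "CpG"
) -> dict:
    """Read-weighted mean level per feature class.

    Classes: total, exon, intron (gene body outside exons), intergenic, CGI
    (CGI overlays the others). Returns NaN for classes with no covered reads.
    """
    calls = sample.subset_context(context)
    sums = {k: [0, 0] for k in ("total", "exon", "intron", "intergenic", "CGI")}
    for chrom, sub in calls.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        tot = sub["total"].to_numpy()
        genes = annotation.genes[annotation.genes["chrom"] == chrom]
        exon_iv = [iv for ex in genes["exons"] for iv in ex]
        body_iv = list(zip(genes["tx_start"], genes["tx_end"]))
        cgi_sub = annotation.cgis[annotation.cgis["chrom"] == chrom]
        cgi_iv = list(zip(cgi_sub["start"], cgi_sub["end"]))
        in_exon = _member(pos, *_merge_intervals(exon_iv))
        in_body = _member(pos, *_merge_intervals(body_iv))
        in_cgi = _member(pos, *_merge_intervals(cgi_iv))
        masks = {
            "total": np.ones(len(pos), dtype=bool),
            "exon": in_exon,
            "intron": in_body & ~in_exon,
            "intergenic": ~in_body,
            "CGI": in_cgi,
        }
        for k, m in masks.items():
            sums[k][0] += int(meth[m].sum())
            sums[k][1] += int(tot[m].sum())
    return {k: (m / t if t else float("nan")) for k, (m, t) in sums.items()}
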