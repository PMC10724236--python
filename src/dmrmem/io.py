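"""Readers and writers for per-cytosine methylation tables and annotation files,
plus the standard pretreatment filters.

Two on-disk dialects are supported for methylomes:

``cytosine_report``
    Bismark-style: chrom, 1-based position, strand, methylated count,
    unmethylated count, context.  Converted to 0-based on read.
``bedgraph_counts``
    bedGraph-with-counts: chrom, 0-based start, end, level (percent),
    methylated count, unmethylated count.  The level column is ignored in
    favour of the counts.

Internal coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeAnnotation, MethylomeSample, make_calls

DIALECTS = ("cytosine_report", "bedgraph_counts")

# Bismark cytosine reports write "CG" for the CpG context.
_CONTEXT_IN = {"CG": "CpG", "CpG": "CpG", "CHH": "CHH", "CHG": "CHG"}
_CONTEXT_OUT = {"CpG": "CG", "CHH": "CHH", "CHG": "CHG"}


def read_cytosine_report(
    path, dialect: str = "cytosine_report", sample_id: str | None = None,
    group: str = "",
) -> MethylomeSample:
    """Read a per-cytosine methylation table in the given dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    chrom, pos, strand, context, meth, total = [], [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "cytosine_report":
                    if len(fields) != 6:
                        raise ValueError("expected 6 columns")
                    c, p1, s, m, u, ctx = fields
                    p = int(p1) - 1  # 1-based on disk
                    m, u = int(m), int(u)
                    if s not in ("+", "-"):
                        raise ValueError(f"bad strand {s!r}")
                else:
                    if len(fields) != 6:
                        raise ValueError("expected 6 columns")
                    c, start, _end, _level, m, u = fields
                    p = int(start)
                    m, u = int(m), int(u)
                    s, ctx = "+", "CpG"
                if ctx not in _CONTEXT_IN:
                    raise ValueError(f"unknown context token {ctx!r}")
                if m < 0 or u < 0:
                    raise ValueError("negative count")
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}: {exc}") from None
            chrom.append(c)
            pos.append(p)
            strand.append(s)
            context.append(_CONTEXT_IN[ctx])
            meth.append(m)
            total.append(m + u)
    calls = make_calls(chrom, pos, strand, context, meth, total)
    return MethylomeSample(sample_id=sample_id, group=group, calls=calls)


def write_cytosine_report(sample: MethylomeSample, path, dialect: str = "cytosine_report") -> None:
    """Write a sample in the given dialect (bit-exact round trip)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    calls = sample.calls
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            unmeth = row.total - row.meth
            if dialect == "cytosine_report":
                fh.write(
                    f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.meth}\t"
                    f"{unmeth}\t{_CONTEXT_OUT[row.context]}\n"
                )
            else:
                level = 100.0 * row.meth / row.total if row.total else 0.0
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{level:g}\t"
                    f"{row.meth}\t{unmeth}\n"
                )


def merge_cpg_strands(sample: MethylomeSample) -> MethylomeSample:
    """Collapse symmetric CpG calls into strand-combined units.

    A '+' call at pos and a '-' call at pos+1, both CpG context, are summed
    into one call at the '+' position.  Unpaired CpG calls and all CHH/CHG
    calls pass through unchanged, so read counts are conserved.
    """
    calls = sample.calls
    is_cpg = calls["context"] == "CpG"
    cpg = calls[is_cpg]
    other = calls[~is_cpg]

    plus = cpg[cpg["strand"] == "+"]
    minus = cpg[cpg["strand"] == "-"]
    # pair minus-strand call at pos+1 with plus-strand call at pos
    minus_shift = minus.assign(pos=minus["pos"] - 1)
    merged = plus.merge(
        minus_shift[["chrom", "pos", "meth", "total"]],
        on=["chrom", "pos"],
        how="outer",
        suffixes=("", "_m"),
        indicator=True,
    )
    paired = merged["_merge"] == "both"
    merged.loc[paired, "meth"] += merged.loc[paired, "meth_m"]
    merged.loc[paired, "total"] += merged.loc[paired, "total_m"]
    # minus-only calls keep their original position and strand
    minus_only = merged["_merge"] == "right_only"
    merged.loc[minus_only, "pos"] += 1
    merged.loc[minus_only, "strand"] = "-"
    merged.loc[minus_only, ["meth", "total"]] = merged.loc[
        minus_only, ["meth_m", "total_m"]
    ].to_numpy()
    merged["strand"] = merged["strand"].fillna("+")
    merged["context"] = "CpG"
    merged = merged[["chrom", "pos", "strand", "context", "meth", "total"]]
    out = pd.concat([merged, other], ignore_index=True)
    out = make_calls(
        out["chrom"], out["pos"], out["strand"], out["context"], out["meth"], out["total"]
    )
    return sample.copy_with(out)


def pretreat(
    sample: MethylomeSample, annotation: GenomeAnnotation, min_depth: int = 10
) -> MethylomeSample:
    """Retain calls with >= min_depth reads on autosomal chromosomes.

    This is the standard pretreatment applied before DMR calling; the
    feature-average rule (>= 5 reads / >= 5 cytosines) is a separate,
    later filter with its own parameters.
    """
    calls = sample.calls
    known = set(annotation.chroms["name"])
    present = set(calls["chrom"].unique())
    missing = present - known
    if missing:
        raise ValueError(f"chromosome(s) absent from annotation: {sorted(missing)}")
    autosomes = annotation.autosomes
    keep = (calls["total"] >= min_depth) & calls["chrom"].isin(autosomes)
    return sample.copy_with(calls[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# annotation / interval formats
# ---------------------------------------------------------------------------

def write_chrom_sizes(annotation: GenomeAnnotation, path) -> None:
    """3-column TSV: name, length, autosome flag (1/0)."""
    with open(path, "w") as fh:
        for row in annotation.chroms.itertuples(index=False):
            fh.write(f"{row.name}\t{row.length}\t{int(row.is_autosome)}\n")


def read_chrom_sizes(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["name", "length", "is_autosome"]
    )
    df["is_autosome"] = df["is_autosome"].astype(bool)
    return df


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    """BED with optional name column (chrom, start, end[, name])."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            line = f"{row.chrom}\t{row.start}\t{row.end}"
            if name_col is not None:
                line += f"\t{getattr(row, name_col)}"
            fh.write(line + "\n")


def read_bed(path, names=("chrom", "start", "end", "name")) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rows.append(fields[: len(names)])
    df = pd.DataFrame(rows, columns=list(names)[: len(rows[0])] if rows else list(names))
    if len(df):
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
    return df


def write_gene_table(annotation: GenomeAnnotation, path) -> None:
    """7-column gene TSV: id, chrom, strand, tss, tx_start, tx_end, exons.

    Exons are serialized as 'start-end' pairs joined by commas.
    """
    with open(path, "w") as fh:
        for g in annotation.genes.itertuples(index=False):
            exons = ",".join(f"{s}-{e}" for s, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tx_start}\t"
                f"{g.tx_end}\t{exons}\n"
            )


def read_gene_table(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            gid, chrom, strand, tss, s, e, exons = line.rstrip("\n").split("\t")
            exon_list = [
                tuple(int(x) for x in pair.split("-")) for pair in exons.split(",") if pair
            ]
            rows.append((gid, chrom, strand, int(tss), int(s), int(e), exon_list))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exons"]
    )


def write_expression_tsv(table, path) -> None:
    """Expression TSV: probe, gene, then one column per sample."""
    df = table.signals.copy()
    df.insert(0, "gene", table.probes.set_index("probe_id").loc[df.index, "gene_id"])
    df.index.name = "probe"
    df.to_csv(path, sep="\t")


def read_expression_tsv(path, groups: dict):
    from .transomics import ExpressionTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    probes = pd.DataFrame({"probe_id": df.index, "gene_id": df["gene"].to_numpy()})
    signals = df.drop(columns=["gene"])
    return ExpressionTable(probes=probes.reset_index(drop=True), signals=signals, groups=dict(groups))
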