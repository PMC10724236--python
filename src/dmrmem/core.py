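"""Core in-memory containers for methylome analysis.

A methylome sample is a table of per-cytosine calls; a genome annotation
holds chromosomes (with autosome flags), gene models and CpG islands.
All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("CpG", "CHH", "CHG")

#: column order of the per-cytosine call table
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]


def make_calls(
    chrom, pos, strand, context, meth, total, *, validate: bool = True
) -> pd.DataFrame:
    """Assemble a per-cytosine call table, sorted by (chrom, pos, strand)."""
    calls = pd.DataFrame(
        {
            "chrom": np.asarray(chrom, dtype=object),
            "pos": np.asarray(pos, dtype=np.int64),
            "strand": np.asarray(strand, dtype=object),
            "context": np.asarray(context, dtype=object),
            "meth": np.asarray(meth, dtype=np.int64),
            "total": np.asarray(total, dtype=np.int64),
        }
    )
    calls = calls.sort_values(["chrom", "pos", "strand"], kind="stable")
    calls = calls.reset_index(drop=True)
    if validate:
        validate_calls(calls)
    return calls


def empty_calls() -> pd.DataFrame:
    return make_calls([], [], [], [], [], [])


def validate_calls(calls: pd.DataFrame) -> None:
    """Enforce the call-table invariants.

    meth <= total, counts non-negative, known contexts, and no duplicate
    (chrom, pos, strand, context) key (duplicates are a hard error, never a
    silent merge).
    """
    if len(calls) == 0:
        return
    if (calls["meth"] < 0).any() or (calls["total"] < 0).any():
        raise ValueError("negative read counts")
    if (calls["meth"] > calls["total"]).any():
        raise ValueError("meth_reads exceeds total_reads")
    bad = set(calls["context"].unique()) - set(CONTEXTS)
    if bad:
        raise ValueError(f"unknown context token(s): {sorted(bad)}")
    if calls.duplicated(["chrom", "pos", "strand", "context"]).any():
        raise ValueError("duplicate (chrom, pos, strand, context) entries")


@dataclass
class MethylomeSample:
    """One replicate's per-cytosine methylation calls plus its group label."""

    sample_id: str
    group: str
    calls: pd.DataFrame = field(default_factory=empty_calls)

    def __post_init__(self) -> None:
        validate_calls(self.calls)

    def subset_context(self, context: str) -> pd.DataFrame:
        if context not in CONTEXTS:
            raise ValueError(f"unknown context {context!r}")
        return self.calls[self.calls["context"] == context]

    def copy_with(self, calls: pd.DataFrame) -> "MethylomeSample":
        return MethylomeSample(self.sample_id, self.group, calls.reset_index(drop=True))


@dataclass
class GenomeAnnotation:
    """Chromosomes, gene models and CpG islands.

    chroms: columns (name, length, is_autosome)
    genes:  columns (gene_id, chrom, strand, tss, tx_start, tx_end, exons)
            where exons is a list of (start, end) tuples
    cgis:   columns (chrom, start, end)
    """

    chroms: pd.DataFrame
    genes: pd.DataFrame
    cgis: pd.DataFrame

    def __post_init__(self) -> None:
        lengths = dict(zip(self.chroms["name"], self.chroms["length"]))
        for _, g in self.genes.iterrows():
            if g["chrom"] not in lengths:
                raise ValueError(f"gene {g['gene_id']} on unknown chrom {g['chrom']}")
            if not (0 <= g["tx_start"] < g["tx_end"] <= lengths[g["chrom"]]):
                raise ValueError(f"gene {g['gene_id']} outside chromosome bounds")
        for _, c in self.cgis.iterrows():
            if c["chrom"] not in lengths:
                raise ValueError(f"CGI on unknown chrom {c['chrom']}")
            if not (0 <= c["start"] < c["end"] <= lengths[c["chrom"]]):
                raise ValueError("CGI outside chromosome bounds")

    @property
    def autosomes(self) -> set:
        a = self.chroms[self.chroms["is_autosome"]]
        return set(a["name"])

    def chrom_length(self, name: str) -> int:
        row = self.chroms[self.chroms["name"] == name]
        if len(row) == 0:
            raise KeyError(f"unknown chromosome {name!r}")
        return int(row["length"].iloc[0])


def empty_annotation(chroms: pd.DataFrame | None = None) -> GenomeAnnotation:
    if chroms is None:
        chroms = pd.DataFrame({"name": [], "length": [], "is_autosome": []})
    genes = pd.DataFrame(
        columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exons"]
    )
    cgis = pd.DataFrame(columns=["chrom", "start", "end"])
    return GenomeAnnotation(chroms=chroms, genes=genes, cgis=cgis)
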