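"""Expression integration: Dunnett many-to-one tests, log2 fold changes,
DEG derivation, and DMR-associated-gene x DEG intersections.

Signals are assumed already normalized and log2-scaled (microarray-style),
so fold changes are plain group-mean differences. Dunnett's test adjusts
each treatment-vs-control comparison family-wise via the multivariate-t
distribution of the Dunnett statistic (scipy's implementation, with a
seeded generator for the quasi-Monte-Carlo integration so results are
reproducible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionTable:
    """Normalized log2 signals per probe x sample with a probe->gene map."""

    probes: pd.DataFrame  # probe_id, gene_id
    signals: pd.DataFrame  # index probe_id, columns sample ids
    groups: dict  # sample id -> group

    def __post_init__(self) -> None:
        missing = set(self.signals.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")
        if set(self.signals.index) != set(self.probes["probe_id"]):
            raise ValueError("signals index must match probe ids")

    def group_columns(self, group: str) -> list:
        return [s for s in self.signals.columns if self.groups[s] == group]

    @property
    def group_names(self) -> list:
        seen = []
        for s in self.signals.columns:
            if self.groups[s] not in seen:
                seen.append(self.groups[s])
        return seen

    def gene_of(self, probe_id: str) -> str:
        return self.probes.set_index("probe_id")["gene_id"][probe_id]


@dataclass
class DegSet:
    """Genes expressed higher/lower in the reprogrammed group than the target."""

    high: set = field(default_factory=set)
    low: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.high & self.low:
            raise ValueError("high and low DEG sets must be disjoint")

    @property
    def all(self) -> set:
        return self.high | self.low


def dunnett_vs_control(
    table: ExpressionTable, control_group: str, seed: int = 0
) -> pd.DataFrame:
    """Adjusted two-sided Dunnett p-values, one column per treatment group.

    Pooled within-group variance; raises on probes where every group is
    constant (zero within-group variance).
    """
    if control_group not in table.group_names:
        raise ValueError(f"control group {control_group!r} not present")
    treatments = [g for g in table.group_names if g != control_group]
    if not treatments:
        raise ValueError("need at least one treatment group")
    ctrl_cols = table.group_columns(control_group)
    treat_cols = {g: table.group_columns(g) for g in treatments}
    for g, cols in {control_group: ctrl_cols, **treat_cols}.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates for testing")
    out = np.empty((len(table.signals), len(treatments)))
    for i, (_, row) in enumerate(table.signals.iterrows()):
        ctrl = row[ctrl_cols].to_numpy(dtype=float)
        samples = [row[treat_cols[g]].to_numpy(dtype=float) for g in treatments]
        ssq = sum(((x - x.mean()) ** 2).sum() for x in [ctrl] + samples)
        if ssq == 0:
            raise ValueError(
                f"zero within-group variance for probe {table.signals.index[i]!r}"
            )
        res = stats.dunnett(
            *samples, control=ctrl, rng=np.random.default_rng([seed, i])
        )
        out[i] = np.clip(res.pvalue, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(out, index=table.signals.index, columns=treatments)


def log2fc(table: ExpressionTable, ref_group: str) -> pd.DataFrame:
    """Per-probe group-mean minus reference-mean (signals already log2)."""
    if ref_group not in table.group_names:
        raise ValueError(f"reference group {ref_group!r} not present")
    ref = table.signals[table.group_columns(ref_group)].mean(axis=1)
    out = {}
    for g in table.group_names:
        out[g] = table.signals[table.group_columns(g)].mean(axis=1) - ref
    return pd.DataFrame(out, index=table.signals.index)


def derive_degs(
    table: ExpressionTable,
    focal: str = "iISC",
    reference: str = "ISC",
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    seed: int = 0,
) -> DegSet:
    """Derive DEG flags: Dunnett-adjusted p < p_threshold (control =
    reference) and |log2FC| >= lfc_threshold between focal and reference.

    A gene is a DEG if any of its probes passes; direction follows the
    passing probe with the largest |log2FC|.
    """
    pvals = dunnett_vs_control(table, control_group=reference, seed=seed)[focal]
    lfc = log2fc(table, ref_group=reference)[focal]
    gene_map = dict(zip(table.probes["probe_id"], table.probes["gene_id"]))
    best: dict = {}
    for probe in table.signals.index:
        if pvals[probe] < p_threshold and abs(lfc[probe]) >= lfc_threshold:
            gene = gene_map[probe]
            if gene not in best or abs(lfc[probe]) > abs(best[gene]):
                best[gene] = float(lfc[probe])
    high = {g for g, v in best.items() if v > 0}
    low = {g for g, v in best.items() if v < 0}
    return DegSet(high=high, low=low)


def intersect_dmr_deg(assoc_genes: set, degs: DegSet) -> dict:
    """Overlap of DMR-associated genes with high/low DEG sets.

    Fractions are relative to the associated-gene count (0 when empty).
    """
    assoc = set(assoc_genes)
    inter_high = sorted(assoc & degs.high)
    inter_low = sorted(assoc & degs.low)
    n = len(assoc)
    return {
        "n_assoc": n,
        "n_high": len(inter_high),
        "n_low": len(inter_low),
        "frac_high": len(inter_high) / n if n else 0.0,
        "frac_low": len(inter_low) / n if n else 0.0,
        "genes_high": inter_high,
        "genes_low": inter_low,
    }


def fc_scatter_table(
    gene_classes,
    table: ExpressionTable,
    degs: DegSet,
    focal: str = "iISC",
    target: str = "ISC",
    source: str = "MEF",
) -> pd.DataFrame:
    """Paired fold-change records for DMR-associated genes, split by
    memory class.

    ``gene_classes`` is an iterable of (gene_id, memory_class) pairs; genes
    occurring with both classes are labelled 'both'. One record per gene:
    log2FC of focal and target vs the source group (gene-level = probe
    mean), plus the DEG flag ('high', 'low' or '').
    """
    lfc = log2fc(table, ref_group=source)
    gene_lfc = lfc.join(table.probes.set_index("probe_id")["gene_id"]).groupby(
        "gene_id"
    ).mean()
    classes: dict = {}
    for gene, cls in gene_classes:
        if gene in classes and classes[gene] != cls:
            classes[gene] = "both"
        else:
            classes[gene] = cls
    rows = []
    for gene in sorted(classes):
        if gene not in gene_lfc.index:
            continue
        flag = "high" if gene in degs.high else ("low" if gene in degs.low else "")
        rows.append(
            {
                "gene_id": gene,
                "memory_class": classes[gene],
                f"fc_{focal}_vs_{source}": float(gene_lfc.loc[gene, focal]),
                f"fc_{target}_vs_{source}": float(gene_lfc.loc[gene, target]),
                "deg": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "memory_class", f"fc_{focal}_vs_{source}",
            f"fc_{target}_vs_{source}", "deg",
        ],
    )


def read_deg_list(path) -> DegSet:
    """DEG list file: gene <tab> direction ('high'/'up' or 'low'/'down')."""
    high, low = set(), set()
    with open(path) as fh:
        for line in fh:
            gene, direction = line.rstrip("\n").split("\t")
            if direction in ("high", "up"):
                high.add(gene)
            elif direction in ("low", "down"):
                low.add(gene)
            else:
                raise ValueError(f"bad DEG direction {direction!r}")
    return DegSet(high=high, low=low)


def write_deg_list(degs: DegSet, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(degs.high):
            fh.write(f"{g}\thigh\n")
        for g in sorted(degs.low):
            fh.write(f"{g}\tlow\n")
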