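"""Synthetic genomes, methylomes and expression tables with planted ground truth.

The generator emulates the structure of a source / target / reprogrammed
three-group bisulfite study (MEF, ISC, iISC; 3/2/3 replicates): group
differences are concentrated in contiguous planted regions, replicate counts
follow a beta-binomial noise model over Poisson depth, and only a small
configurable fraction of region-proximal genes are differentially expressed.

Planted region classes
----------------------
shared
    reprogramming-shared change: source differs, target == reprogrammed.
memory
    source signature retained: source == reprogrammed != target (an
    aberration of the reprogrammed cells that coincides with a
    source-vs-target difference — the "mDNA" pattern).
specific_hyper / specific_hypo
    acquired/erased only in the reprogrammed cells: source == target,
    reprogrammed higher / lower (the "sDNA" pattern).

Baseline methylation varies regionally: per-tile levels are drawn once from
a Beta distribution and shared across groups (via a common quantile), which
is what gives windowed methylomes their high within-group correlation.
Setting the tile concentrations very large recovers a flat baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeAnnotation, MethylomeSample, make_calls

CLASS_LABELS = ("shared", "memory", "specific_hyper", "specific_hypo")

# child-seed stage keys
_STAGE_ANNOT = 0
_STAGE_SITES = 1
_STAGE_TRUTH = 2
_STAGE_TILES = 3
_STAGE_EXPR = 4
_STAGE_SAMPLES = 10  # + replicate index


def _child_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic three-group methylome/expression study."""

    seed: int = 0
    n_chrom: int = 3
    chrom_length_bp: int = 2_000_000
    n_autosomes: int = 2
    cpg_spacing_mean_bp: float = 100.0
    noncpg_spacing_mean_bp: float = 100.0
    baseline_meth: dict = field(
        default_factory=lambda: {"MEF": 0.7, "ISC": 0.7, "iISC": 0.7}
    )
    noncpg_baseline: float = 0.08
    replicates: dict = field(default_factory=lambda: {"MEF": 3, "ISC": 2, "iISC": 3})
    depth_mean: float = 30.0
    bb_dispersion: float = 0.02
    #: class label -> (count, effect size on the methylation-fraction scale).
    #: The default design mirrors the study's qualitative findings: most
    #: change is reprogramming-shared (fewer reprogrammed-vs-target DMRs
    #: than source-vs-target), memory regions are a minority of the focal
    #: aberrations, and hyper aberrations outnumber hypo about 3:1.
    dmr_plan: dict = field(
        default_factory=lambda: {
            "shared": (40, 0.4),
            "memory": (8, 0.4),
            "specific_hyper": (16, 0.4),
            "specific_hypo": (8, 0.4),
        }
    )
    dmr_length_bp: tuple = (2000, 4000)
    min_cpgs_per_region: int = 20
    #: planted regions emulate CpG-dense loci: no internal inter-CpG gap may
    #: exceed this (keeps a region contiguous under downstream gap-based
    #: pre-segmentation at its default 300 bp)
    max_gap_within_region_bp: int = 300
    #: minimum bp separation between planted regions, so distinct planted
    #: loci stay distinct after segmentation
    region_margin_bp: int = 5000
    n_genes: int = 300
    frac_deg_coupled: float = 0.1
    n_background_degs: int = 5
    deg_log2_shift: float = 2.0
    expr_noise_sd: float = 0.25
    deg_coupling_flank: int = 10_000
    tile_bp: int = 2000
    tile_concentration_cpg: float = 8.0
    #: non-CpG methylation is mostly near zero with occasional methylated
    #: tiles; the low concentration gives the strong shared regional
    #: structure that makes windowed CHH/CHG levels almost perfectly
    #: correlated between any two samples
    tile_concentration_noncpg: float = 2.0
    source_group: str = "MEF"
    target_group: str = "ISC"
    reprog_group: str = "iISC"

    @property
    def groups(self) -> list:
        return list(self.replicates)

    def validate(self) -> None:
        if self.n_chrom < 1 or not (0 <= self.n_autosomes <= self.n_chrom):
            raise ValueError("need 1 <= n_autosomes <= n_chrom")
        if self.cpg_spacing_mean_bp <= 0 or self.noncpg_spacing_mean_bp <= 0:
            raise ValueError("spacings must be positive")
        for g, frac in self.baseline_meth.items():
            if not 0 <= frac <= 1:
                raise ValueError(f"baseline_meth[{g}] outside [0,1]")
        if set(self.baseline_meth) != set(self.replicates):
            raise ValueError("baseline_meth and replicates must share group keys")
        for g, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"need >=1 replicate for group {g}")
        for role in (self.source_group, self.target_group, self.reprog_group):
            if role not in self.replicates:
                raise ValueError(f"role group {role!r} missing from replicates")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        if not 0 < self.bb_dispersion < 1:
            raise ValueError("bb_dispersion must be in (0,1)")
        if not 0 <= self.noncpg_baseline <= 1:
            raise ValueError("noncpg_baseline outside [0,1]")
        if not 0 <= self.frac_deg_coupled <= 1:
            raise ValueError("frac_deg_coupled outside [0,1]")
        for label, (count, effect) in self.dmr_plan.items():
            if label not in CLASS_LABELS:
                raise ValueError(f"unknown planted class {label!r}")
            if count < 0 or not 0 < effect <= 1:
                raise ValueError(f"bad plan for class {label!r}")
        lo, hi = self.dmr_length_bp
        if not 0 < lo <= hi:
            raise ValueError("dmr_length_bp must be an increasing positive range")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth: planted regions with per-group levels, and DEG genes.

    regions:   region_id, chrom, start, end, class_label, n_cpgs,
               one ``level_<group>`` column per group
    deg_genes: gene_id, direction ('up'/'down' in the reprogrammed group),
               region_id (empty string when not methylation-coupled)
    """

    regions: pd.DataFrame
    deg_genes: pd.DataFrame


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Random gene models and CpG islands on fixed-length chromosomes.

    Genes are placed without overlap (rejection sampling); roughly half of
    the promoters receive a 1 kb CpG island centred on the TSS.
    """
    config.validate()
    rng = _child_rng(config.seed, _STAGE_ANNOT)
    L = config.chrom_length_bp
    names = [f"chr{i + 1}" for i in range(config.n_chrom)]
    chroms = pd.DataFrame(
        {
            "name": names,
            "length": [L] * config.n_chrom,
            "is_autosome": [i < config.n_autosomes for i in range(config.n_chrom)],
        }
    )

    min_gene, max_gene = 2000, 20_000
    total_bp = L * config.n_chrom
    if config.n_genes * min_gene > total_bp:
        raise ValueError(
            f"{config.n_genes} genes cannot fit in {total_bp} bp without overlap"
        )

    placed: dict = {n: [] for n in names}
    genes = []
    for i in range(config.n_genes):
        gid = f"g{i:04d}"
        for _attempt in range(1000):
            chrom = names[int(rng.integers(config.n_chrom))]
            glen = int(rng.integers(min_gene, max_gene + 1))
            if glen >= L:
                continue
            start = int(rng.integers(0, L - glen))
            end = start + glen
            if any(s < end and start < e for s, e in placed[chrom]):
                continue
            placed[chrom].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            n_exons = int(rng.integers(1, 11))
            exons = _split_exons(rng, start, end, n_exons)
            genes.append((gid, chrom, strand, tss, start, end, exons))
            break
        else:
            raise ValueError("could not place genes without overlap; reduce n_genes")

    genes_df = pd.DataFrame(
        genes, columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exons"]
    )
    cgi_rows = []
    for g in genes:
        if rng.random() < 0.5:
            tss = g[3]
            s = max(0, tss - 500)
            e = min(L, tss + 500)
            if s < e:
                cgi_rows.append((g[1], s, e))
    cgis = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    return GenomeAnnotation(chroms=chroms, genes=genes_df, cgis=cgis)


def _split_exons(rng, start, end, n_exons):
    """Partition [start, end) into alternating exon/intron chunks (exons at ends)."""
    if n_exons == 1:
        return [(start, end)]
    n_chunks = 2 * n_exons - 1
    w = rng.dirichlet(np.ones(n_chunks))
    edges = start + np.round(np.cumsum(w) * (end - start)).astype(int)
    edges[-1] = end
    bounds = np.concatenate([[start], edges])
    bounds = np.maximum.accumulate(bounds)  # guard zero-width rounding
    exons = []
    for k in range(0, n_chunks, 2):
        s, e = int(bounds[k]), int(bounds[k + 1])
        if s < e:
            exons.append((s, e))
    return exons if exons else [(start, end)]


# ---------------------------------------------------------------------------
# cytosine site layout and regional baseline (shared across stages)
# ---------------------------------------------------------------------------

def cpg_positions(config: SimulationConfig, annotation: GenomeAnnotation) -> dict:
    """Per-chromosome sorted CpG site positions (strand-combined units).

    Derived from a dedicated child seed so planting and sampling agree.
    """
    rng = _child_rng(config.seed, _STAGE_SITES)
    out = {}
    p = 1.0 / config.cpg_spacing_mean_bp
    for row in annotation.chroms.itertuples(index=False):
        n_est = int(row.length * p * 1.3) + 10
        gaps = rng.geometric(p, size=n_est)
        pos = np.cumsum(gaps) - 1
        while pos[-1] < row.length - 1:
            more = rng.geometric(p, size=n_est // 2 + 10)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        out[row.name] = pos[pos < row.length - 1]
    return out


def noncpg_sites(config: SimulationConfig, annotation: GenomeAnnotation) -> dict:
    """Per-chromosome sparse CHH/CHG sites: (positions, contexts, strands)."""
    rng = _child_rng(config.seed, _STAGE_SITES + 100)
    out = {}
    p = 1.0 / config.noncpg_spacing_mean_bp
    for row in annotation.chroms.itertuples(index=False):
        n_est = int(row.length * p * 1.3) + 10
        gaps = rng.geometric(p, size=n_est)
        pos = np.cumsum(gaps) - 1
        while pos[-1] < row.length - 1:
            more = rng.geometric(p, size=n_est // 2 + 10)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(more)])
        pos = pos[pos < row.length - 1]
        ctx = np.where(rng.random(len(pos)) < 2.0 / 3.0, "CHH", "CHG")
        strand = np.where(rng.random(len(pos)) < 0.5, "+", "-")
        out[row.name] = (pos, ctx, strand)
    return out


def _tile_quantiles(config: SimulationConfig, annotation: GenomeAnnotation) -> dict:
    """One Uniform(0,1) quantile per baseline tile, shared by all groups."""
    rng = _child_rng(config.seed, _STAGE_TILES)
    out = {}
    for row in annotation.chroms.itertuples(index=False):
        n_tiles = int(np.ceil(row.length / config.tile_bp))
        out[row.name] = (rng.random(n_tiles), rng.random(n_tiles))  # (CpG, non-CpG)
    return out


def _beta_ppf(u: np.ndarray, mean: float, conc: float) -> np.ndarray:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return stats.beta.ppf(u, mean * conc, (1 - mean) * conc)


def baseline_levels(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[dict, dict]:
    """Regional baseline methylation per tile.

    Returns (cpg, noncpg): cpg maps chrom -> {group: per-tile level array};
    noncpg maps chrom -> per-tile level array (group-invariant, mirroring
    the near-perfect cross-sample agreement of CHH/CHG methylation).
    """
    quants = _tile_quantiles(config, annotation)
    cpg, noncpg = {}, {}
    for chrom, (u_cpg, u_non) in quants.items():
        cpg[chrom] = {
            g: _beta_ppf(u_cpg, m, config.tile_concentration_cpg)
            for g, m in config.baseline_meth.items()
        }
        noncpg[chrom] = _beta_ppf(u_non, config.noncpg_baseline,
                                  config.tile_concentration_noncpg)
    return cpg, noncpg


# ---------------------------------------------------------------------------
# planted truth
# ---------------------------------------------------------------------------

def _class_levels(config: SimulationConfig, label: str, effect: float) -> dict:
    src, tgt, rep = config.source_group, config.target_group, config.reprog_group
    base = {g: config.baseline_meth[g] for g in (src, tgt, rep)}
    lo = {g: float(np.clip(base[g] - effect, 0.0, 1.0)) for g in base}
    if label == "shared":
        return {src: base[src], tgt: lo[tgt], rep: lo[rep]}
    if label == "memory":
        return {src: base[src], tgt: lo[tgt], rep: base[rep]}
    if label == "specific_hyper":
        return {src: lo[src], tgt: lo[tgt], rep: base[rep]}
    if label == "specific_hypo":
        return {src: base[src], tgt: base[tgt], rep: lo[rep]}
    raise ValueError(f"unknown class {label!r}")


def plant_truth(config: SimulationConfig, annotation: GenomeAnnotation) -> PlantedTruth:
    """Place the configured planted regions on autosomes and pick DEG genes.

    Regions are anchored on actual CpG sites (first to last site, end
    exclusive), span at least ``min_cpgs_per_region`` sites, and are
    non-overlapping with a 1 kb margin so adjacent regions cannot fuse into
    one candidate downstream.
    """
    config.validate()
    rng = _child_rng(config.seed, _STAGE_TRUTH)
    sites = cpg_positions(config, annotation)
    autosomes = [
        r.name for r in annotation.chroms.itertuples(index=False) if r.is_autosome
    ]
    if not autosomes and any(c > 0 for c, _ in config.dmr_plan.values()):
        raise ValueError("no autosomes available for planting")

    placed: dict = {c: [] for c in autosomes}
    margin = config.region_margin_bp
    rows = []
    idx = 0
    for label in CLASS_LABELS:
        count, effect = config.dmr_plan.get(label, (0, 0.0))
        levels = _class_levels(config, label, effect) if count else {}
        for _ in range(count):
            for _attempt in range(500):
                chrom = autosomes[int(rng.integers(len(autosomes)))]
                pos = sites[chrom]
                lo_bp, hi_bp = config.dmr_length_bp
                target_len = int(rng.integers(lo_bp, hi_bp + 1))
                n_sites = max(
                    config.min_cpgs_per_region,
                    int(round(target_len / config.cpg_spacing_mean_bp)),
                )
                if len(pos) < n_sites + 2:
                    continue
                i0 = int(rng.integers(0, len(pos) - n_sites))
                run = pos[i0 : i0 + n_sites]
                if np.diff(run).max() > config.max_gap_within_region_bp:
                    continue
                start = int(run[0])
                end = int(run[-1]) + 1
                if any(
                    s - margin < end and start < e + margin for s, e in placed[chrom]
                ):
                    continue
                placed[chrom].append((start, end))
                rows.append(
                    {
                        "region_id": f"dmr{idx:04d}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "class_label": label,
                        "n_cpgs": n_sites,
                        **{f"level_{g}": lv for g, lv in levels.items()},
                    }
                )
                idx += 1
                break
            else:
                raise ValueError(
                    f"could not place {count} non-overlapping '{label}' regions"
                )
    level_cols = [f"level_{g}" for g in config.groups]
    regions = pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "class_label", "n_cpgs"]
        + level_cols,
    )

    deg_rows = _pick_deg_genes(config, annotation, regions, rng)
    deg_genes = pd.DataFrame(deg_rows, columns=["gene_id", "direction", "region_id"])
    return PlantedTruth(regions=regions, deg_genes=deg_genes)


def _pick_deg_genes(config, annotation, regions, rng):
    """Couple a fraction of TSS-proximal focal-aberration regions to DEGs."""
    src, tgt, rep = config.source_group, config.target_group, config.reprog_group
    genes = annotation.genes
    deg_rows = []
    used_genes = set()
    focal = regions[regions["class_label"].isin(("memory", "specific_hyper",
                                                 "specific_hypo"))]
    proximal = []
    for r in focal.itertuples(index=False):
        mid = (r.start + r.end) // 2
        near = genes[
            (genes["chrom"] == r.chrom)
            & ((genes["tss"] - mid).abs() <= config.deg_coupling_flank)
        ]
        if len(near):
            gid = near.sort_values("gene_id")["gene_id"].iloc[0]
            proximal.append((r.region_id, gid, r.class_label))
    n_coupled = int(round(config.frac_deg_coupled * len(proximal)))
    order = rng.permutation(len(proximal))
    for j in order[:n_coupled]:
        region_id, gid, label = proximal[j]
        if gid in used_genes:
            continue
        # hypermethylation near the TSS represses; hypo activates
        is_hyper = label in ("memory", "specific_hyper")
        # memory regions are hyper in the reprogrammed group iff source > target
        if label == "memory":
            is_hyper = config.baseline_meth[rep] > _class_levels(
                config, "memory", config.dmr_plan["memory"][1]
            )[tgt]
        direction = "down" if is_hyper else "up"
        deg_rows.append((gid, direction, region_id))
        used_genes.add(gid)
    pool = [g for g in genes["gene_id"] if g not in used_genes]
    order = rng.permutation(len(pool))
    for j in order[: config.n_background_degs]:
        direction = "up" if rng.random() < 0.5 else "down"
        deg_rows.append((pool[j], direction, ""))
    return deg_rows


# ---------------------------------------------------------------------------
# methylome samples
# ---------------------------------------------------------------------------

def _true_levels_for_sites(config, annotation, truth, pos_by_chrom, cpg_tiles):
    """Per-site true CpG level per group: tile baseline overridden in regions."""
    out = {}
    for chrom, pos in pos_by_chrom.items():
        tile_idx = (pos // config.tile_bp).astype(int)
        levels = {g: cpg_tiles[chrom][g][tile_idx].copy() for g in config.groups}
        regs = truth.regions[truth.regions["chrom"] == chrom]
        for r in regs.itertuples(index=False):
            inside = (pos >= r.start) & (pos < r.end)
            for g in config.groups:
                levels[g][inside] = getattr(r, f"level_{g}")
        out[chrom] = levels
    return out


def _beta_binomial(rng, depth, mean, dispersion):
    mean = np.clip(mean, 1e-9, 1 - 1e-9)
    if dispersion <= 0:
        return rng.binomial(depth, mean)
    a = mean * (1 - dispersion) / dispersion
    b = (1 - mean) * (1 - dispersion) / dispersion
    p = rng.beta(a, b)
    return rng.binomial(depth, p)


def simulate_samples(
    config: SimulationConfig, annotation: GenomeAnnotation, truth: PlantedTruth
) -> list[MethylomeSample]:
    """Draw replicate methylomes: Poisson depth, beta-binomial methylated counts."""
    config.validate()
    pos_by_chrom = cpg_positions(config, annotation)
    noncpg = noncpg_sites(config, annotation)
    cpg_tiles, noncpg_tiles = baseline_levels(config, annotation)
    true_levels = _true_levels_for_sites(config, annotation, truth, pos_by_chrom, cpg_tiles)

    samples = []
    rep_index = 0
    for group in config.groups:
        for r in range(config.replicates[group]):
            rng = _child_rng(config.seed, _STAGE_SAMPLES + rep_index)
            rep_index += 1
            chrom_l, pos_l, strand_l, ctx_l, meth_l, total_l = [], [], [], [], [], []
            for chrom in annotation.chroms["name"]:
                pos = pos_by_chrom[chrom]
                m = true_levels[chrom][group]
                depth = rng.poisson(config.depth_mean, size=len(pos))
                meth = _beta_binomial(rng, depth, m, config.bb_dispersion)
                chrom_l.append(np.full(len(pos), chrom, dtype=object))
                pos_l.append(pos)
                strand_l.append(np.full(len(pos), "+", dtype=object))
                ctx_l.append(np.full(len(pos), "CpG", dtype=object))
                meth_l.append(meth)
                total_l.append(depth)

                npos, nctx, nstrand = noncpg[chrom]
                tile_idx = (npos // config.tile_bp).astype(int)
                nm = noncpg_tiles[chrom][tile_idx]
                ndepth = rng.poisson(config.depth_mean, size=len(npos))
                nmeth = _beta_binomial(rng, ndepth, nm, config.bb_dispersion)
                chrom_l.append(np.full(len(npos), chrom, dtype=object))
                pos_l.append(npos)
                strand_l.append(nstrand)
                ctx_l.append(nctx)
                meth_l.append(nmeth)
                total_l.append(ndepth)
            calls = make_calls(
                np.concatenate(chrom_l),
                np.concatenate(pos_l),
                np.concatenate(strand_l),
                np.concatenate(ctx_l),
                np.concatenate(meth_l),
                np.concatenate(total_l),
            )
            samples.append(
                MethylomeSample(sample_id=f"{group}_{r + 1}", group=group, calls=calls)
            )
    return samples


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimulationConfig, truth: PlantedTruth):
    """Gaussian log2 signals per probe x replicate; DEG genes shift the
    reprogrammed group's mean by ±deg_log2_shift."""
    from .transomics import ExpressionTable

    config.validate()
    rng = _child_rng(config.seed, _STAGE_EXPR)
    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    probes = pd.DataFrame(
        {"probe_id": [f"p_{g}" for g in gene_ids], "gene_id": gene_ids}
    )
    deg = {
        row.gene_id: row.direction for row in truth.deg_genes.itertuples(index=False)
    }
    sample_ids, groups = [], {}
    for g in config.groups:
        for r in range(config.replicates[g]):
            sid = f"{g}_{r + 1}"
            sample_ids.append(sid)
            groups[sid] = g
    base = rng.normal(8.0, 1.5, size=config.n_genes)
    data = np.empty((config.n_genes, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        mu = base.copy()
        if groups[sid] == config.reprog_group:
            for i, gid in enumerate(gene_ids):
                if gid in deg:
                    mu[i] += config.deg_log2_shift if deg[gid] == "up" else -config.deg_log2_shift
        data[:, j] = mu + rng.normal(0.0, config.expr_noise_sd, size=config.n_genes)
    signals = pd.DataFrame(data, index=probes["probe_id"].to_numpy(), columns=sample_ids)
    return ExpressionTable(probes=probes, signals=signals, groups=groups)
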