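import pandas as pd
import pytest

from dmrmem.core import GenomeAnnotation, MethylomeSample, make_calls


def build_sample(rows, sample_id="s1", group="A"):
    """Build a sample from (chrom, pos, strand, context, meth, total) tuples."""
    if not rows:
        return MethylomeSample(sample_id=sample_id, group=group)
    chrom, pos, strand, context, meth, total = zip(*rows)
    return MethylomeSample(
        sample_id=sample_id,
        group=group,
        calls=make_calls(chrom, pos, strand, context, meth, total),
    )


def cpg_sample(chrom_pos_meth_total, sample_id="s1", group="A"):
    """Strand-combined CpG-only sample from (chrom, pos, meth, total) tuples."""
    rows = [(c, p, "+", "CpG", m, t) for c, p, m, t in chrom_pos_meth_total]
    return build_sample(rows, sample_id=sample_id, group=group)


def make_annotation(chroms, genes=None, cgis=None):
    """chroms: (name, length, is_autosome); genes: 7-tuples; cgis: 3-tuples."""
    chroms_df = pd.DataFrame(chroms, columns=["name", "length", "is_autosome"])
    genes_df = pd.DataFrame(
        genes or [],
        columns=["gene_id", "chrom", "strand", "tss", "tx_start", "tx_end", "exons"],
    )
    cgis_df = pd.DataFrame(cgis or [], columns=["chrom", "start", "end"])
    return GenomeAnnotation(chroms=chroms_df, genes=genes_df, cgis=cgis_df)


@pytest.fixture
def one_chrom_annotation():
    return make_annotation([("chr1", 1_000_000, True)])


@pytest.fixture
def mixed_annotation():
    return make_annotation([("chr1", 1_000_000, True), ("chrX", 1_000_000, False)])


@pytest.fixture(scope="session")
def tiny_sim():
    """A small, fast simulated dataset shared across tests (session scope)."""
    from dmrmem import io, simulate

    cfg = simulate.SimulationConfig(
        seed=7,
        n_chrom=2,
        n_autosomes=2,
        chrom_length_bp=400_000,
        dmr_plan={"memory": (3, 0.4), "specific_hyper": (3, 0.4), "shared": (3, 0.4)},
        n_genes=60,
    )
    annotation = simulate.simulate_annotation(cfg)
    truth = simulate.plant_truth(cfg, annotation)
    samples = simulate.simulate_samples(cfg, annotation, truth)
    treated = [io.pretreat(io.merge_cpg_strands(s), annotation) for s in samples]
    by_group = {}
    for s in treated:
        by_group.setdefault(s.group, []).append(s)
    return {
        "config": cfg,
        "annotation": annotation,
        "truth": truth,
        "samples": samples,
        "treated": treated,
        "by_group": by_group,
    }
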