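"""Synthetic-data generator: determinism, planted-truth geometry, calibration."""

import numpy as np
import pandas as pd
import pytest

from dmrmem import simulate
from dmrmem.simulate import SimulationConfig


def small_cfg(**kw):
    defaults = dict(
        seed=11,
        n_chrom=2,
        n_autosomes=2,
        chrom_length_bp=300_000,
        n_genes=30,
        dmr_plan={"memory": (2, 0.4), "specific_hyper": (2, 0.4)},
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAnnotation:
    def test_no_genes(self):
        cfg = small_cfg(n_genes=0, dmr_plan={})
        ann = simulate.simulate_annotation(cfg)
        assert len(ann.genes) == 0
        assert len(ann.cgis) >= 0

    def test_determinism(self):
        cfg = small_cfg()
        a1 = simulate.simulate_annotation(cfg)
        a2 = simulate.simulate_annotation(cfg)
        assert a1.chroms.equals(a2.chroms)
        assert a1.genes.drop(columns="exons").equals(a2.genes.drop(columns="exons"))
        assert list(a1.genes["exons"]) == list(a2.genes["exons"])
        assert a1.cgis.equals(a2.cgis)

    def test_non_autosome_flag_count(self):
        cfg = small_cfg(n_chrom=3, n_autosomes=2)
        ann = simulate.simulate_annotation(cfg)
        assert int((~ann.chroms["is_autosome"]).sum()) == 1

    def test_gene_overflow_rejected(self):
        cfg = small_cfg(n_chrom=1, n_autosomes=1, chrom_length_bp=10_000, n_genes=100)
        with pytest.raises(ValueError, match="without overlap"):
            simulate.simulate_annotation(cfg)

    def test_genes_do_not_overlap(self):
        ann = simulate.simulate_annotation(small_cfg())
        for chrom, sub in ann.genes.groupby("chrom"):
            ivs = sorted(zip(sub["tx_start"], sub["tx_end"]))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2


class TestPlantTruth:
    def test_empty_plan(self):
        cfg = small_cfg(dmr_plan={})
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        assert len(truth.regions) == 0

    def test_memory_class_geometry(self):
        cfg = small_cfg(dmr_plan={"memory": (10, 0.4)}, chrom_length_bp=2_000_000)
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        mem = truth.regions[truth.regions["class_label"] == "memory"]
        assert len(mem) == 10
        # source == reprogrammed, target differs by the planted effect
        assert np.allclose(mem["level_MEF"], mem["level_iISC"], atol=1e-9)
        assert (np.abs(mem["level_ISC"] - mem["level_iISC"]) >= 0.4 - 1e-9).all()

    def test_class_geometry_all_classes(self):
        cfg = small_cfg(
            chrom_length_bp=2_000_000,
            dmr_plan={c: (3, 0.3) for c in simulate.CLASS_LABELS},
        )
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        r = truth.regions
        shared = r[r["class_label"] == "shared"]
        assert np.allclose(shared["level_ISC"], shared["level_iISC"])
        assert (np.abs(shared["level_MEF"] - shared["level_ISC"]) >= 0.3 - 1e-9).all()
        for label in ("specific_hyper", "specific_hypo"):
            spec = r[r["class_label"] == label]
            assert np.allclose(spec["level_MEF"], spec["level_ISC"])
            assert (np.abs(spec["level_iISC"] - spec["level_ISC"]) >= 0.3 - 1e-9).all()

    def test_regions_non_overlapping_autosomal_min_cpgs(self):
        cfg = small_cfg(chrom_length_bp=2_000_000,
                        dmr_plan={c: (5, 0.4) for c in simulate.CLASS_LABELS})
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        autosomes = ann.autosomes
        sites = simulate.cpg_positions(cfg, ann)
        for chrom, sub in truth.regions.groupby("chrom"):
            assert chrom in autosomes
            ivs = sorted(zip(sub["start"], sub["end"]))
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2
        for r in truth.regions.itertuples(index=False):
            n = ((sites[r.chrom] >= r.start) & (sites[r.chrom] < r.end)).sum()
            assert n >= 20

    def test_determinism(self):
        cfg = small_cfg()
        ann = simulate.simulate_annotation(cfg)
        t1 = simulate.plant_truth(cfg, ann)
        t2 = simulate.plant_truth(cfg, ann)
        assert t1.regions.equals(t2.regions)
        assert t1.deg_genes.equals(t2.deg_genes)


class TestSimulateSamples:
    def test_zero_depth(self):
        cfg = small_cfg(depth_mean=0.0, chrom_length_bp=50_000, dmr_plan={}, n_genes=5)
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        samples = simulate.simulate_samples(cfg, ann, truth)
        assert all((s.calls["total"] == 0).all() for s in samples)

    def test_marginal_calibration(self):
        # flat baseline (huge tile concentration), no planted regions:
        # pooled level should sit within 4 binomial SE of the configured 0.7
        cfg = SimulationConfig(
            seed=5,
            n_chrom=1,
            n_autosomes=1,
            chrom_length_bp=1_200_000,
            dmr_plan={},
            replicates={"MEF": 1, "ISC": 1, "iISC": 1},
            bb_dispersion=1e-6,
            tile_concentration_cpg=1e9,
            tile_concentration_noncpg=1e9,
            n_genes=0,
        )
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        samples = simulate.simulate_samples(cfg, ann, truth)
        for s in samples:
            cpg = s.subset_context("CpG")
            assert len(cpg) >= 10_000
            n_reads = cpg["total"].sum()
            level = cpg["meth"].sum() / n_reads
            se = np.sqrt(0.7 * 0.3 / n_reads)
            assert abs(level - 0.7) < 4 * se

    def test_planted_specific_hyper_effect(self, tiny_sim):
        cfg, truth = tiny_sim["config"], tiny_sim["truth"]
        regions = truth.regions[truth.regions["class_label"] == "specific_hyper"]
        r = regions.iloc[0]
        pooled = {}
        for group in ("ISC", "iISC"):
            meth = tot = 0
            for s in tiny_sim["samples"]:
                if s.group != group:
                    continue
                sub = s.subset_context("CpG")
                sub = sub[(sub["chrom"] == r["chrom"]) & (sub["pos"] >= r["start"])
                          & (sub["pos"] < r["end"])]
                meth += sub["meth"].sum()
                tot += sub["total"].sum()
            pooled[group] = meth / tot
        assert pooled["iISC"] - pooled["ISC"] == pytest.approx(0.4, abs=0.08)

    def test_determinism(self):
        cfg = small_cfg(chrom_length_bp=60_000, dmr_plan={}, n_genes=5)
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        s1 = simulate.simulate_samples(cfg, ann, truth)
        s2 = simulate.simulate_samples(cfg, ann, truth)
        assert all(a.calls.equals(b.calls) for a, b in zip(s1, s2))


class TestSimulateExpression:
    def test_no_deg_no_shift(self):
        cfg = small_cfg(frac_deg_coupled=0.0, n_background_degs=0)
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        assert len(truth.deg_genes) == 0
        expr = simulate.simulate_expression(cfg, truth)
        groups = pd.Series(expr.groups)
        means = {
            g: expr.signals[groups[groups == g].index].mean(axis=1)
            for g in ("MEF", "iISC")
        }
        # group means differ only by replicate noise, well under the DEG shift
        assert (means["MEF"] - means["iISC"]).abs().max() < 1.5

    def test_coupled_deg_shifted(self):
        cfg = small_cfg(frac_deg_coupled=1.0, chrom_length_bp=2_000_000,
                        n_genes=200, n_background_degs=0)
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        coupled = truth.deg_genes[truth.deg_genes["region_id"] != ""]
        assert len(coupled) > 0
        expr = simulate.simulate_expression(cfg, truth)
        groups = pd.Series(expr.groups)
        iisc_cols = groups[groups == "iISC"].index
        isc_cols = groups[groups == "ISC"].index
        for row in coupled.itertuples(index=False):
            probe = f"p_{row.gene_id}"
            delta = (
                expr.signals.loc[probe, iisc_cols].mean()
                - expr.signals.loc[probe, isc_cols].mean()
            )
            assert abs(delta) == pytest.approx(2.0, abs=1.0)
            assert (delta > 0) == (row.direction == "up")

    def test_determinism(self):
        cfg = small_cfg()
        ann = simulate.simulate_annotation(cfg)
        truth = simulate.plant_truth(cfg, ann)
        e1 = simulate.simulate_expression(cfg, truth)
        e2 = simulate.simulate_expression(cfg, truth)
        assert e1.signals.equals(e2.signals)
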