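"""DMR caller: pooling, pre-segmentation, recursive segmentation, testing,
retention filtering and end-to-end calls on synthetic data."""

import numpy as np
import pandas as pd
import pytest

from dmrmem import dmr
from dmrmem.dmr import DMR, DmrParams

from conftest import cpg_sample
from oracle import naive_segment


def params(**kw):
    return DmrParams(**kw)


class TestPerCpgGroupLevels:
    def test_pooling_arithmetic(self, one_chrom_annotation):
        a1 = cpg_sample([("chr1", 100, 3, 10)], "a1", "A")
        a2 = cpg_sample([("chr1", 100, 2, 10)], "a2", "A")
        b1 = cpg_sample([("chr1", 100, 9, 12)], "b1", "B")
        sites = dmr.per_cpg_group_levels([a1, a2], [b1], one_chrom_annotation)
        assert sites.iloc[0]["level_a"] == pytest.approx(0.25)
        assert sites.iloc[0]["level_b"] == pytest.approx(0.75)

    def test_site_covered_in_one_group_excluded(self, one_chrom_annotation):
        a = cpg_sample([("chr1", 100, 3, 10), ("chr1", 200, 3, 10)], "a", "A")
        b = cpg_sample([("chr1", 100, 3, 10)], "b", "B")
        sites = dmr.per_cpg_group_levels([a], [b], one_chrom_annotation)
        assert list(sites["pos"]) == [100]

    def test_shallow_sites_excluded(self, one_chrom_annotation):
        a = cpg_sample([("chr1", 100, 3, 9)], "a", "A")
        b = cpg_sample([("chr1", 100, 3, 20)], "b", "B")
        sites = dmr.per_cpg_group_levels([a], [b], one_chrom_annotation)
        assert len(sites) == 0

    def test_non_autosome_excluded(self, mixed_annotation):
        a = cpg_sample([("chrX", 100, 3, 20)], "a", "A")
        b = cpg_sample([("chrX", 100, 3, 20)], "b", "B")
        sites = dmr.per_cpg_group_levels([a], [b], mixed_annotation)
        assert len(sites) == 0

    def test_empty_input(self, one_chrom_annotation):
        a = cpg_sample([], "a", "A")
        b = cpg_sample([], "b", "B")
        assert len(dmr.per_cpg_group_levels([a], [b], one_chrom_annotation)) == 0


class TestPresegment:
    def _sites(self, positions):
        return pd.DataFrame(
            {"chrom": ["chr1"] * len(positions), "pos": positions}
        )

    def test_small_gaps_one_block(self):
        blocks = dmr.presegment(self._sites(range(0, 1500, 100)),
                                params(min_cpgs_candidate=10))
        assert len(blocks) == 1

    def test_gap_boundary_splits(self):
        pos = list(range(0, 1000, 100)) + [1000 + 301 + i * 100 for i in range(10)]
        blocks = dmr.presegment(self._sites(pos), params(min_cpgs_candidate=10))
        assert len(blocks) == 2
        pos2 = list(range(0, 1000, 100)) + [1000 + 200 + i * 100 for i in range(10)]
        assert len(dmr.presegment(self._sites(pos2), params(min_cpgs_candidate=10))) == 1

    def test_short_blocks_dropped(self):
        blocks = dmr.presegment(self._sites(range(0, 900, 100)),
                                params(min_cpgs_candidate=10))
        assert blocks == []


class TestSegmentBlock:
    def test_constant_difference_single_candidate(self):
        a = [0.8] * 20
        b = [0.3] * 20
        segs = dmr.segment_block(a, b, params(min_cpgs_candidate=10))
        assert [(lo, hi) for lo, hi, _ in segs] == [(0, 20)]

    def test_sign_change_two_candidates(self):
        a = [0.9] * 10 + [0.1] * 10
        b = [0.5] * 20
        segs = dmr.segment_block(a, b, params(min_cpgs_candidate=10))
        assert [(lo, hi) for lo, hi, _ in segs] == [(0, 10), (10, 20)]

    def test_zero_difference_single_candidate(self):
        a = b = [0.5] * 25
        segs = dmr.segment_block(a, b, params(min_cpgs_candidate=10))
        assert [(lo, hi) for lo, hi, _ in segs] == [(0, 25)]
        assert segs[0][2] == 1.0

    def test_matches_naive_oracle_on_random_blocks(self):
        # dyadic level grid keeps prefix-sum and direct-slice arithmetic exact
        rng = np.random.default_rng(42)
        grid = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        for n in (6, 9, 12):
            for _ in range(40):
                a = rng.choice(grid, size=n)
                b = rng.choice(grid, size=n)
                got = dmr.segment_block(a, b, params(min_cpgs_candidate=2,
                                                     min_cpgs_retain=2))
                want = naive_segment(list(a), list(b), 2)
                assert [(lo, hi) for lo, hi, _ in got] == [
                    (lo, hi) for lo, hi, _ in want
                ]


class TestTestCandidate:
    def test_identical_values(self):
        assert dmr.test_candidate([0.5] * 10, [0.5] * 10) == 1.0

    def test_complete_separation_20_sites(self):
        p = dmr.test_candidate([1.0] * 20, [0.0] * 20)
        assert p < 1e-6

    def test_single_site(self):
        assert dmr.test_candidate([1.0], [0.0]) == 1.0


class TestCallDmrs:
    def test_identical_groups_no_dmrs(self, one_chrom_annotation):
        rows = [("chr1", i * 100, 5, 15) for i in range(100)]
        a = cpg_sample(rows, "a", "A")
        b = cpg_sample(rows, "b", "B")
        assert dmr.call_dmrs([a], [b], one_chrom_annotation) == []

    def test_empty_group_rejected(self, one_chrom_annotation):
        a = cpg_sample([("chr1", 1, 1, 20)], "a", "A")
        with pytest.raises(ValueError, match="replicate"):
            dmr.call_dmrs([a], [], one_chrom_annotation)

    def test_planted_region_recovered(self, one_chrom_annotation):
        # 30 elevated CpGs inside a 100-site block
        rows_a, rows_b = [], []
        rng = np.random.default_rng(0)
        for i in range(100):
            pos = i * 100
            level = 0.9 if 40 <= i < 70 else 0.5
            rows_a.append(("chr1", pos, int(level * 30), 30))
            rows_b.append(("chr1", pos, 15, 30))
        a = cpg_sample(rows_a, "a", "A")
        b = cpg_sample(rows_b, "b", "B")
        dmrs = dmr.call_dmrs([a], [b], one_chrom_annotation)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert d.direction == "hyper"
        assert d.start == 4000 and d.end == 6901
        assert d.n_cpgs == 30
        assert d.mean_diff == pytest.approx(0.4, abs=1e-9)

    def test_short_effect_region_not_retained(self, one_chrom_annotation):
        # a strong but 15-CpG effect can never pass the 20-CpG retention rule
        rows_a, rows_b = [], []
        for i in range(15):
            rows_a.append(("chr1", i * 100, 27, 30))
            rows_b.append(("chr1", i * 100, 3, 30))
        a = cpg_sample(rows_a, "a", "A")
        b = cpg_sample(rows_b, "b", "B")
        cands = dmr.call_candidates([a], [b], one_chrom_annotation)
        assert len(cands) == 1 and cands[0].q_value < 0.05
        assert dmr.call_dmrs([a], [b], one_chrom_annotation) == []

    def test_monotone_in_retention_thresholds(self, tiny_sim):
        ann, by = tiny_sim["annotation"], tiny_sim["by_group"]
        base = dmr.call_candidates(by["iISC"], by["ISC"], ann)

        def names(p):
            return {d.name for d in dmr.apply_retention_filter(base, p)}

        loose = names(params())
        assert names(params(min_diff=0.2)) <= loose
        assert names(params(min_cpgs_retain=30)) <= loose
        assert names(params(q_threshold=0.01)) <= loose

    def test_direction_convention(self, tiny_sim):
        """hyper = focal group (A) more methylated than comparator (B)."""
        ann, by, truth = tiny_sim["annotation"], tiny_sim["by_group"], tiny_sim["truth"]
        dmrs = dmr.call_dmrs(by["iISC"], by["ISC"], ann)
        hyper_regions = truth.regions[
            truth.regions["class_label"].isin(["memory", "specific_hyper"])
        ]
        for d in dmrs:
            for r in hyper_regions.itertuples(index=False):
                ov = min(d.end, r.end) - max(d.start, r.start)
                if d.chrom == r.chrom and ov > 0.5 * (r.end - r.start):
                    assert d.direction == "hyper"


def test_dmr_bed_round_trip(tmp_path, tiny_sim):
    ann, by = tiny_sim["annotation"], tiny_sim["by_group"]
    dmrs = dmr.call_dmrs(by["iISC"], by["ISC"], ann)
    assert dmrs, "fixture should yield DMRs"
    path = tmp_path / "dmrs.bed"
    dmr.write_dmr_bed(dmrs, path)
    back = dmr.read_dmr_bed(path)
    for x, y in zip(dmrs, back):
        assert (x.chrom, x.start, x.end, x.n_cpgs, x.direction) == (
            y.chrom, y.start, y.end, y.n_cpgs, y.direction
        )
        assert x.mean_diff == pytest.approx(y.mean_diff, abs=1e-6)
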