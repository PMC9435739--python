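"""Pair construction, distance-correlation trend, block bootstrap."""

import numpy as np
import pandas as pd
import pytest

from lnctime import quantify, simdata, spatial
from lnctime.quantify import GeneModel
from lnctime.spatial import (PenalizedSpline, TooFewPairsError,
                             block_bootstrap_envelope, choose_block_size,
                             gam_trend, make_pairs,
                             pseudochromosome_positions)


def gene_at(gene_id, tss, biotype, chrom="chr1", length=5000):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand="+", gene_start=tss,
                     gene_end=tss + length, biotype=biotype,
                     exons=((tss, tss + 100), (tss + length - 100, tss + length)))


def profile_table(gene_ids, values):
    cols = {f"{t}": np.asarray(v) for t, v in
            zip(range(0, 410, 10), np.asarray(values).T)}
    return pd.DataFrame({"gene_id": gene_ids,
                         "region": ["intron5p"] * len(gene_ids), **cols})


class TestMakePairs:
    def test_three_gene_toy_enumeration(self):
        genes = [gene_at("c1", 0, "protein_coding"),
                 gene_at("c2", 100_000, "protein_coding"),
                 gene_at("l1", 50_000, "lncRNA")]
        rng = np.random.default_rng(0)
        prof = profile_table(["c1", "c2", "l1"], rng.normal(size=(3, 41)))
        pairs = make_pairs(genes, prof, max_distance_bp=500_000)
        # lncRNA equidistant from both coding genes: pairing is many-to-many
        assert len(pairs) == 2
        assert set(pairs["tss_distance"]) == {50_000}

    def test_distance_arithmetic_and_same_tss(self):
        genes = [gene_at("c1", 100, "protein_coding"),
                 gene_at("l1", 50_100, "lncRNA", length=2000),
                 gene_at("l2", 100, "lncRNA", chrom="chr2")]
        rng = np.random.default_rng(1)
        prof = profile_table(["c1", "l1", "l2"], rng.normal(size=(3, 41)))
        pairs = make_pairs(genes, prof, max_distance_bp=500_000)
        assert len(pairs) == 1  # chr2 lncRNA not paired across chromosomes
        assert pairs["tss_distance"].iloc[0] == 50_000

    def test_translation_invariance(self, sync_fixture):
        _, genes, _, prof, active = sync_fixture
        shifted = [GeneModel(gene_id=g.gene_id, chrom=g.chrom, strand=g.strand,
                             gene_start=g.gene_start + 1000,
                             gene_end=g.gene_end + 1000, biotype=g.biotype,
                             exons=tuple((a + 1000, b + 1000) for a, b in g.exons))
                   for g in genes]
        p1 = make_pairs(genes, prof, 300_000, gene_ids=active)
        p2 = make_pairs(shifted, prof, 300_000, gene_ids=active)
        assert (p1["tss_distance"].to_numpy() ==
                p2["tss_distance"].to_numpy()).all()
        assert np.allclose(p1["pearson_r"], p2["pearson_r"])


class TestGamTrend:
    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0, 500_000, 400)
        r = 0.8 - d / 1_000_000  # exactly linear in distance
        pairs = pd.DataFrame({"tss_distance": d, "pearson_r": r,
                              "distance_bin": (d // 25_000).astype(int)})
        trend = gam_trend(pairs)
        lo, hi = np.quantile(d, [0.05, 0.95])
        grid = np.linspace(lo, hi, 50)
        assert np.max(np.abs(trend(grid) - (0.8 - grid / 1_000_000))) < 0.01

    def test_constant_truth_recovered_with_unit_edf(self):
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 500_000, 300)
        pairs = pd.DataFrame({"tss_distance": d,
                              "pearson_r": np.full(d.size, 0.3),
                              "distance_bin": (d // 25_000).astype(int)})
        trend = gam_trend(pairs)
        grid = np.linspace(d.min(), d.max(), 50)
        assert np.max(np.abs(trend(grid) - 0.3)) < 0.01
        assert trend.edf <= 1.5

    def test_synchronous_fixture_trend_decreases(self, sync_fixture):
        from scipy.stats import spearmanr
        _, genes, _, prof, active = sync_fixture
        pairs = make_pairs(genes, prof, 500_000, gene_ids=active)
        trend = gam_trend(pairs)
        grid = np.linspace(pairs["tss_distance"].min(),
                           pairs["tss_distance"].max(), 50)
        rho = spearmanr(grid, trend(grid)).statistic
        assert rho < 0

    def test_too_few_pairs_signalled(self):
        pairs = pd.DataFrame({"tss_distance": [1.0, 2.0],
                              "pearson_r": [0.1, 0.2],
                              "distance_bin": [0, 0]})
        with pytest.raises(TooFewPairsError):
            gam_trend(pairs)

    def test_agrees_with_statsmodels_gam(self):
        from statsmodels.gam.api import BSplines, GLMGam
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 500_000, 800)
        y = 0.6 * np.exp(-x / 120_000) + rng.normal(0, 0.15, x.size)
        ps = PenalizedSpline().fit(x, y)
        bs = BSplines(x[:, None], df=[10], degree=[3])
        best = None
        for a in np.geomspace(1e-2, 1e8, 15):
            res = GLMGam(y, exog=np.ones((x.size, 1)), smoother=bs,
                         alpha=a).fit()
            if best is None or res.aic < best[0]:
                best = (res.aic, res)
        grid = np.linspace(x.min() + 1, x.max() - 1, 40)
        ref = best[1].predict(exog=np.ones((40, 1)), exog_smooth=grid[:, None])
        assert np.max(np.abs(ps.predict(grid) - ref)) < 0.06


class TestChooseBlockSize:
    def test_null_fixture_returns_minimum_with_flag(self, null_fixtures):
        flags = []
        for i, (_, genes, _, prof, active) in enumerate(null_fixtures):
            pairs = make_pairs(genes, prof, 500_000, gene_ids=active)
            bs, flag = choose_block_size(pairs, n_perm=200, seed=i)
            flags.append(flag)
        assert sum(flags) >= len(flags) - 1

    def test_synchronous_block_size_bounded_by_pairing_radius(self, sync_fixture):
        cfg, genes, _, prof, active = sync_fixture
        pairs = make_pairs(genes, prof, 500_000, gene_ids=active)
        bs, flag = choose_block_size(pairs, n_perm=200, seed=0)
        assert not flag
        assert bs <= 2 * cfg.max_pair_distance_bp

    def test_small_n_perm_rejected(self, sync_fixture):
        _, genes, _, prof, active = sync_fixture
        pairs = make_pairs(genes, prof, 500_000, gene_ids=active)
        with pytest.raises(ValueError):
            choose_block_size(pairs, n_perm=1)


class TestBlockBootstrap:
    def test_same_class_adjacency_preserved_within_block(self, sync_fixture):
        # all genes of a class sharing a source block travel together: every
        # destination slot containing one of them contains all, with the
        # original relative offsets
        _, genes, _, _, _ = sync_fixture
        block = 200_000
        pos = pseudochromosome_positions(genes, block,
                                         np.random.default_rng(0))
        coding = [g for g in genes if g.biotype == "protein_coding"]
        src_blocks = {}
        for g in coding:
            src_blocks.setdefault((g.chrom, g.tss // block), []).append(g)
        multi = [grp for grp in src_blocks.values() if len(grp) >= 2]
        assert multi, "fixture should have co-blocked coding genes"
        placed = {}
        for gid, chrom, new_tss in pos["protein_coding"]:
            placed.setdefault(gid, []).append((chrom, new_tss // block, new_tss))
        checked = 0
        for grp in multi:
            ref, rest = grp[0], grp[1:]
            for chrom, slot, new_tss in placed.get(ref.gene_id, []):
                for other in rest:
                    hits = [t for c, s, t in placed.get(other.gene_id, [])
                            if c == chrom and s == slot]
                    assert any(t - new_tss == other.tss - ref.tss
                               for t in hits)
                    checked += 1
        assert checked > 0

    def test_envelope_deterministic_per_seed(self, sync_fixture):
        _, genes, _, prof, active = sync_fixture
        e1 = block_bootstrap_envelope(genes, prof, 100_000, n_boot=50, seed=3,
                                      gene_ids=active)
        e2 = block_bootstrap_envelope(genes, prof, 100_000, n_boot=50, seed=3,
                                      gene_ids=active)
        assert np.allclose(e1.lo, e2.lo) and np.allclose(e1.hi, e2.hi)
        assert np.allclose(e1.trend, e2.trend)

    def test_synchronous_trend_exits_envelope_at_short_range(self, sync_fixture):
        _, genes, _, prof, active = sync_fixture
        env = block_bootstrap_envelope(genes, prof, 100_000, n_boot=200, seed=1,
                                       gene_ids=active)
        assert env.trend[0] > env.hi[0]

    def test_envelope_quantiles_stable_in_n_boot(self, sync_fixture):
        _, genes, _, prof, active = sync_fixture
        e200 = block_bootstrap_envelope(genes, prof, 100_000, n_boot=200, seed=2,
                                        gene_ids=active)
        e600 = block_bootstrap_envelope(genes, prof, 100_000, n_boot=600, seed=7,
                                        gene_ids=active)
        # interior of the distance grid; the few extreme-distance pairs make
        # the spline edges intrinsically variable
        assert np.max(np.abs(e200.lo - e600.lo)[2:-2]) < 0.05
        assert np.max(np.abs(e200.hi - e600.hi)[2:-2]) < 0.05


class TestClassifyTssElements:
    def test_proximity_rule(self):
        genes = [gene_at("l1", 10_000, "lncRNA"),
                 gene_at("l2", 50_000, "lncRNA")]
        elements = pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [9_800, 30_000],
            "end": [9_900, 30_500],
            "label": ["promoter-like", "enhancer-like"]})
        res = spatial.classify_tss_elements(genes, elements, window_bp=300)
        res = res.set_index("gene_id")
        assert res.at["l1", "labels"] == "promoter-like"
        assert res.at["l2", "labels"] == ""
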