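"""ODE integration, half-life fitting, intron tiling, elongation estimate."""

import numpy as np
import pytest

from lnctime import kinetics, quantify, simdata
from lnctime.kinetics import (NoSignalError, UnidentifiableError,
                              estimate_elongation, fit_kinetics,
                              integrate_model, tile_gene)

T = np.arange(0.0, 410.0, 10.0)


class TestIntegrateModel:
    def test_zero_input_stays_zero(self):
        M = integrate_model(T, np.zeros_like(T), alpha=0.02, beta=1.0, m0=0.0)
        assert np.allclose(M, 0.0)

    def test_steady_state_is_fixed_point(self):
        a, b, c = 0.0231, 1.3, 4.0
        M = integrate_model(T, np.full_like(T, c), a, b, m0=b * c / a)
        assert np.allclose(M, b * c / a, rtol=1e-12)

    def test_relaxation_matches_closed_form(self):
        a, b, c = 0.0231, 1.3, 4.0
        M = integrate_model(T, np.full_like(T, c), a, b, m0=0.0)
        closed = (b * c / a) * (1.0 - np.exp(-a * T))
        assert np.allclose(M, closed, rtol=1e-6)

    def test_linear_in_beta_and_input(self):
        a, b, c = 0.01, 0.7, 2.0
        M1 = integrate_model(T, np.full_like(T, c), a, b, m0=b * c / a)
        M2 = integrate_model(T, np.full_like(T, 2 * c), a, b, m0=2 * b * c / a)
        assert np.allclose(M2, 2 * M1, rtol=1e-12)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            integrate_model(T, np.full_like(T, np.nan), 0.01, 1.0)


def short_gene_fixture(seed=3, dispersion=0.0, n=5):
    """Genes short enough that elongation delay is negligible."""
    cfg = simdata.SimConfig(n_coding=n, n_lnc_per_coding=0, n_background=0,
                            coding_length_mean_kb=15, length_sigma=0.2,
                            nb_dispersion=dispersion,
                            depth_factors=tuple([1.0] * 41), seed=seed)
    genes, truth = simdata.make_genome(cfg)
    return cfg, genes, truth


def gene_profiles(table, gene_id):
    sub = table[table["gene_id"] == gene_id].set_index("region")
    P = sub.loc["intron3p"].iloc[1:].to_numpy(float)
    M = sub.loc["exon"].iloc[1:].to_numpy(float)
    return P, M


class TestFitKinetics:
    def test_noise_free_halflife_recovery_within_5pct(self):
        cfg, genes, truth = short_gene_fixture()
        surface = simdata.expected_signals(genes, truth, cfg)
        ti = truth.set_index("gene_id")
        for g in genes:
            P, M = gene_profiles(surface, g.gene_id)
            kp = fit_kinetics(cfg.times(), P, M)
            true_hl = np.log(2) / ti.at[g.gene_id, "alpha"]
            assert abs(kp.halflife / true_hl - 1) <= 0.05
            assert kp.halflife * kp.alpha == pytest.approx(np.log(2), abs=1e-12)

    def test_self_consistency_zero_residual(self):
        rng = np.random.default_rng(5)
        P = rng.uniform(0.5, 3.0, T.size)
        a_true, b_true = np.log(2) / 60.0, 1.4
        M = integrate_model(T, P, a_true, b_true, m0=1.0)
        kp = fit_kinetics(T, P, M)
        pred = integrate_model(T, P, kp.alpha, kp.beta, m0=M[0])
        assert float(np.sum((pred - M) ** 2)) <= 1e-10

    def test_brute_force_grid_oracle_agrees(self):
        cfg, genes, truth = short_gene_fixture(seed=9, n=2)
        surface = simdata.expected_signals(genes, truth, cfg)
        P, M = gene_profiles(surface, genes[0].gene_id)
        kp = fit_kinetics(cfg.times(), P, M)
        best = np.inf
        for a in np.geomspace(np.log(2) / 1000, np.log(2) / 5, 100):
            for b in np.geomspace(1e-3, 1e2, 100):
                pred = integrate_model(cfg.times(), P, a, b, m0=M[0])
                best = min(best, float(np.sum((pred - M) ** 2)))
        assert kp.sse <= best * 1.01 + 1e-12

    def test_flat_pre_mrna_unidentifiable(self):
        M = np.linspace(1, 3, T.size)
        with pytest.raises(UnidentifiableError):
            fit_kinetics(T, np.full_like(T, 2.0), M)

    def test_sse_profile_minimized_at_generating_alpha(self):
        # identifiability: along the true beta, sse over an alpha grid
        # bottoms out at the generating alpha
        rng = np.random.default_rng(6)
        P = rng.uniform(0.5, 3.0, T.size)
        a_true, b_true = np.log(2) / 45.0, 1.0
        M = integrate_model(T, P, a_true, b_true, m0=0.5)
        grid = np.geomspace(a_true / 8, a_true * 8, 33)
        sses = [float(np.sum((integrate_model(T, P, a, b_true, m0=M[0]) - M) ** 2))
                for a in grid]
        assert np.argmin(sses) == np.argmin(np.abs(grid - a_true))

    @pytest.mark.parametrize("dispersion,bound", [(0.05, 0.25), (0.5, 0.75)])
    def test_recovery_degrades_gracefully_with_noise(self, dispersion, bound):
        """Median half-life error grows smoothly with count noise.

        The bounds are regression guards at the design's information floor:
        with half-lives spanning minutes to ten hours, rates much faster
        than the 10-min sampling step or much slower than the 400-min
        window are only weakly identified, which sets the attainable
        accuracy at each noise level (see the methods note).
        """
        cfg, genes, truth = short_gene_fixture(seed=21, dispersion=dispersion,
                                               n=200)
        counts = simdata.simulate_counts(genes, truth, cfg)
        ti = truth.set_index("gene_id")
        errors = []
        for g in genes:
            P, M = gene_profiles(counts, g.gene_id)
            if np.ptp(P) == 0 or np.ptp(M) == 0:
                continue
            kp = fit_kinetics(cfg.times(), P, M)
            true_hl = np.log(2) / ti.at[g.gene_id, "alpha"]
            errors.append(abs(kp.halflife / true_hl - 1))
        assert np.median(errors) <= bound

    def test_recovery_accurate_in_identifiable_regime(self):
        """Half-lives between ~3x the sampling step and ~half the window are
        the regime the time-course design can actually measure; there the
        median error stays near the noise floor."""
        cfg = simdata.SimConfig(n_coding=100, n_lnc_per_coding=0,
                                n_background=0, coding_length_mean_kb=15,
                                length_sigma=0.2, nb_dispersion=0.05,
                                halflife_range_min=(30.0, 120.0),
                                depth_factors=tuple([1.0] * 41), seed=22)
        genes, truth = simdata.make_genome(cfg)
        counts = simdata.simulate_counts(genes, truth, cfg)
        ti = truth.set_index("gene_id")
        errors = []
        for g in genes:
            P, M = gene_profiles(counts, g.gene_id)
            kp = fit_kinetics(cfg.times(), P, M)
            errors.append(abs(kp.halflife * ti.at[g.gene_id, "alpha"]
                              / np.log(2) - 1))
        assert np.median(errors) <= 0.15


class TestTileGene:
    def test_tile_count_is_intron_kb(self, toy_gene):
        # toy gene has 17 kb of introns -> 17 tiles of 1 kb
        tiles = tile_gene(toy_gene)
        assert len(tiles) == 17
        for tile in tiles:
            assert sum(b - a for a, b in tile) == 1000

    def test_minus_strand_reverses_tile_order(self, toy_gene):
        minus = quantify.GeneModel(
            gene_id="m", chrom="chr1", strand="-",
            gene_start=toy_gene.gene_start, gene_end=toy_gene.gene_end,
            biotype="protein_coding", exons=toy_gene.exons)
        plus_tiles = tile_gene(toy_gene)
        minus_tiles = tile_gene(minus)
        # first minus-strand tile covers the genomic right end of the introns
        assert minus_tiles[0][0][1] == 20000
        assert plus_tiles[0][0][0] == 1000
        plus_bases = [iv for tile in plus_tiles for iv in tile]
        minus_bases = sorted(iv for tile in minus_tiles for iv in tile)
        assert sorted(plus_bases) == minus_bases

    def test_partial_trailing_tile_dropped(self):
        g = quantify.GeneModel(
            gene_id="p", chrom="chr1", strand="+", gene_start=0, gene_end=5500,
            biotype="protein_coding", exons=((0, 500), (5000, 5500)))
        tiles = tile_gene(g)  # 4.5 kb of intron -> 4 tiles, 0.5 kb dropped
        assert len(tiles) == 4
        assert all(sum(b - a for a, b in t) == 1000 for t in tiles)

    def test_window_distance_matches_construction(self, toy_gene):
        # 5' window: introns [1000,6000)+[8000,13000), centre of mass 7 kb
        # from the TSS; 3' window: [10000,20000), centre 15 kb -> 8 kb apart
        d = kinetics.window_distance_kb(toy_gene)
        assert d == pytest.approx(8.0, abs=1e-9)


class TestEstimateElongation:
    def test_two_gene_exact_rate(self):
        est = estimate_elongation([100.0, 50.0], [40.0, 20.0])
        assert est.rate_kb_per_min == pytest.approx(2.5, rel=1e-12)
        assert est.n_genes == 2

    def test_zero_delay_excluded_then_no_signal(self):
        with pytest.raises(NoSignalError):
            estimate_elongation([100.0, 50.0], [0.0, -3.0])

    def test_recovery_from_generated_wave(self):
        cfg = simdata.SimConfig(n_coding=100, n_lnc_per_coding=0,
                                n_background=0, coding_length_mean_kb=120,
                                length_sigma=0.4, nb_dispersion=0.05,
                                depth_factors=tuple([1.0] * 41), seed=5)
        genes, truth = simdata.make_genome(cfg)
        counts = simdata.simulate_counts(genes, truth, cfg)
        first, last = {}, {}
        for g in genes:
            sub = counts[counts["gene_id"] == g.gene_id].set_index("region")
            first[g.gene_id] = sub.loc["intron5p"].iloc[1:].to_numpy(float)
            last[g.gene_id] = sub.loc["intron3p"].iloc[1:].to_numpy(float)
        est = kinetics.elongation_from_profiles(genes, cfg.times(), first, last)
        assert abs(est.rate_kb_per_min / cfg.elongation_rate_kb_per_min - 1) <= 0.10
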