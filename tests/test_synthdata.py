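import numpy as np
import pytest
from scipy import stats

from qtlcascade import haplomap as hm
from qtlcascade import linkage as lk
from qtlcascade import synthdata as sd
from qtlcascade.regions import GenomicInterval


class TestSimulateBackcross:
    def test_null_effect_gives_null_association(self, small_map):
        spec = sd.CrossSpec(n=5000, qtl_bp=20_000_000, additive=0.0, sigma=1.0,
                            seed=9)
        geno, pheno = sd.simulate_backcross(small_map, spec)
        y = pheno.trait("glucose").to_numpy()
        g = geno.codes[:, 2]
        t = stats.ttest_ind(y[g == lk.NN], y[g == lk.NB]).statistic
        assert abs(t) < 4.0  # central t at n = 5000

    def test_genotype_frequencies_half_half(self, small_map):
        spec = sd.CrossSpec(n=10_000, qtl_bp=20_000_000, additive=0.0,
                            sigma=1.0, seed=4)
        geno, _ = sd.simulate_backcross(small_map, spec)
        for j in range(small_map.n_markers):
            frac_nn = float((geno.codes[:, j] == lk.NN).mean())
            # binomial 3.3-sigma band around 0.5 at n = 10000
            assert abs(frac_nn - 0.5) < 3.3 * 0.5 / np.sqrt(10_000)

    def test_adjacent_recombination_matches_haldane(self, small_map):
        spec = sd.CrossSpec(n=10_000, qtl_bp=20_000_000, additive=0.0,
                            sigma=1.0, seed=8)
        geno, _ = sd.simulate_backcross(small_map, spec)
        cm = small_map.position_cm
        for j in range(small_map.n_markers - 1):
            r_exp = lk.haldane((cm[j + 1] - cm[j]) / 100.0)
            r_obs = float((geno.codes[:, j] != geno.codes[:, j + 1]).mean())
            se = np.sqrt(r_exp * (1 - r_exp) / 10_000)
            assert abs(r_obs - r_exp) < 3 * se

    def test_planted_effect_recovered_monte_carlo(self, small_map):
        # marker at the QTL, a = 1, sigma = 1: group mean difference within
        # 3 standard errors of the planted effect
        spec = sd.CrossSpec(n=10_000, qtl_bp=20_000_000, additive=1.0,
                            sigma=1.0, seed=6)
        geno, pheno = sd.simulate_backcross(small_map, spec)
        y = pheno.trait("glucose").to_numpy()
        g = geno.codes[:, 2]
        diff = y[g == lk.NN].mean() - y[g == lk.NB].mean()
        se = np.sqrt(1 / (g == lk.NN).sum() + 1 / (g == lk.NB).sum())
        assert abs(diff - 1.0) < 3 * se

    def test_determinism(self, small_map):
        spec = sd.CrossSpec(n=50, qtl_bp=20_000_000, seed=123)
        g1, p1 = sd.simulate_backcross(small_map, spec)
        g2, p2 = sd.simulate_backcross(small_map, spec)
        assert np.array_equal(g1.codes, g2.codes)
        assert p1.data.equals(p2.data)

    def test_missing_rate_applied(self, small_map):
        spec = sd.CrossSpec(n=400, qtl_bp=20_000_000, missing_rate=0.2, seed=0)
        geno, _ = sd.simulate_backcross(small_map, spec)
        frac = float((geno.codes == lk.MISSING).mean())
        assert 0.1 < frac < 0.3
        assert not np.any((geno.codes == lk.MISSING).all(axis=1))

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            sd.CrossSpec(n=1, qtl_bp=1)

    def test_qtl_outside_map_rejected(self, small_map):
        spec = sd.CrossSpec(n=10, qtl_bp=99_000_000)
        with pytest.raises(ValueError, match="outside map"):
            sd.simulate_backcross(small_map, spec)


class TestMakeSnpCatalog:
    REGION = GenomicInterval("chr13", 0, 2_000_000)

    def test_dense_block_exceeds_downstream_threshold(self):
        catalog = sd.make_snp_catalog(
            self.REGION, [sd.BlockSpec(0, 1_000_000, 150)], seed=0
        )
        profiles = hm.window_counts(catalog, self.REGION)
        for p in profiles[:4]:  # the four full windows inside the block
            assert p.discordant > 100
        for p in profiles[4:]:
            assert p.discordant == 0

    def test_empty_layout_zero_discordant(self):
        catalog = sd.make_snp_catalog(self.REGION, [], seed=0,
                                      background_total_density=50)
        assert int(catalog.discordant.sum()) == 0
        assert catalog.n_snps > 0

    def test_sparse_block_never_polymorphic(self):
        catalog = sd.make_snp_catalog(
            self.REGION, [sd.BlockSpec(0, 2_000_000, 40)], seed=1
        )
        # brute-force window scan
        for ws in range(0, 2_000_000, 250_000):
            pos = catalog.positions[catalog.discordant]
            count = int(((pos >= ws) & (pos < ws + 250_000)).sum())
            assert count > 40  # strictly exceeds declared density
            assert count <= 100  # but below the polymorphism threshold
        profiles, _ = hm.call_polymorphic(hm.window_counts(catalog, self.REGION))
        assert not any(p.polymorphic for p in profiles)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            sd.make_snp_catalog(
                self.REGION,
                [sd.BlockSpec(0, 600_000, 150), sd.BlockSpec(500_000, 900_000, 150)],
                seed=0,
            )

    def test_positions_sorted_unique(self):
        catalog = sd.make_snp_catalog(
            self.REGION, [sd.BlockSpec(0, 1_000_000, 150)], seed=3,
            background_total_density=100,
        )
        assert np.all(np.diff(catalog.positions) > 0)

    def test_determinism(self):
        kw = dict(region=self.REGION, block_layout=[sd.BlockSpec(0, 500_000, 120)],
                  seed=11, background_total_density=30)
        c1 = sd.make_snp_catalog(**kw)
        c2 = sd.make_snp_catalog(**kw)
        assert np.array_equal(c1.positions, c2.positions)
        assert np.array_equal(c1.allele_b, c2.allele_b)


class TestMakeSingleCell:
    def test_unknown_cluster_rejected(self):
        with pytest.raises(ValueError, match="unknown cluster"):
            sd.make_single_cell(clusters=("Alpha", "Zeta"))

    def test_zero_means_all_zero_counts(self):
        import pandas as pd

        means = pd.DataFrame(0.0, index=["g1", "g2"],
                             columns=list(sd.CANONICAL_CLUSTERS))
        cells = sd.make_single_cell(means=means, seed=0, cells_per_cluster=5)
        assert (cells.counts.to_numpy() == 0).all()

    def test_planted_marker_argmax(self, fig3):
        means = fig3.sc.counts.groupby(fig3.sc.clusters).mean()
        for gene in ("Mki67", "S100z", "Iqgap2"):
            assert means[gene].idxmax() == "BetaP"

    def test_byte_identical_on_reseed(self):
        c1 = sd.make_single_cell(seed=5, cells_per_cluster=20)
        c2 = sd.make_single_cell(seed=5, cells_per_cluster=20)
        assert c1.counts.equals(c2.counts)

    def test_overdispersion_present(self):
        cells = sd.make_single_cell(seed=2, cells_per_cluster=500)
        ins1 = cells.counts.loc[cells.clusters == "Beta1", "Ins1"]
        # variance well above Poisson for a mean-400 gene at dispersion 0.5
        assert ins1.var() > 2 * ins1.mean()


class TestFig3Fixture:
    def test_gene_total_644(self, fig3):
        assert fig3.annotation.n_genes == 644

    def test_biotype_partition(self, fig3):
        counts = {bt: int((fig3.annotation.biotype == bt).sum())
                  for bt in sd.BIOTYPES}
        assert counts == {"coding": 208, "gene_model": 377, "miRNA": 8,
                          "riken": 51}

    def test_genes_within_interval(self, fig3):
        assert (fig3.annotation.start >= fig3.interval.start).all()
        assert (fig3.annotation.end < fig3.interval.end).all()

    def test_named_candidates_present_and_coding(self, fig3):
        for name in sd.NAMED_CANDIDATES:
            i = fig3.annotation.gene_ids.index(name)
            assert fig3.annotation.biotype[i] == "coding"

    def test_planted_sets_nested(self, fig3):
        assert set(fig3.congenic_de_genes) <= set(fig3.parental_de_genes)
        assert set(fig3.parental_de_genes) <= set(fig3.candidate_gene_ids)
        assert set(fig3.obob_de_genes) == set(fig3.congenic_de_genes) - {"Acot12"}

    def test_cascade_counts_hold_for_other_seeds(self):
        from qtlcascade import exprfilter as ef

        fx = sd.make_fig3_fixture(seed=123)
        profiles, _ = hm.call_polymorphic(
            hm.window_counts(fx.catalog, fx.interval)
        )
        kept = hm.filter_genes(fx.annotation, profiles)
        assert len(kept) == 111
        de_p = ef.de_filter(ef.compute_lfc(fx.expression["parental"]))
        de_c = ef.de_filter(ef.compute_lfc(fx.expression["congenic"]))
        assert len(de_p) == 8
        assert sorted(de_c) == sorted(sd.NAMED_CANDIDATES)

    def test_interval_length(self, fig3):
        assert fig3.interval.length_mbp == pytest.approx(42.4)

    def test_map_contains_peak_marker(self, fig3):
        idx = fig3.genmap.index_of(sd.PEAK_MARKER)
        assert fig3.genmap.position_bp[idx] == sd.PEAK_MARKER_BP
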