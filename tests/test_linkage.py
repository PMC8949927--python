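import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qtlcascade import linkage as lk
from qtlcascade import synthdata as sd


class TestHaldane:
    def test_zero_distance(self):
        assert lk.haldane(0.0) == 0.0

    def test_free_recombination_limit(self):
        assert lk.haldane(100.0) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_half_morgan(self):
        assert lk.haldane(0.5) == pytest.approx((1 - np.exp(-1)) / 2)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            lk.haldane(-0.1)

    @given(st.floats(min_value=0.0, max_value=50.0, allow_nan=False))
    def test_range(self, d):
        r = lk.haldane(d)
        assert 0.0 <= r <= 0.5
        if d <= 5.0:  # below float rounding to the 0.5 asymptote
            assert r < 0.5

    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.0, max_value=10.0))
    def test_monotone(self, d1, d2):
        lo, hi = sorted([d1, d2])
        assert lk.haldane(lo) <= lk.haldane(hi)


def _single_marker_geno(codes, small_map):
    """Genotypes at marker m2 (20 Mbp) only, everything else missing."""
    n = len(codes)
    mat = np.full((n, small_map.n_markers), lk.MISSING, dtype=np.int8)
    mat[:, 2] = codes
    return lk.GenotypeMatrix([f"i{k}" for k in range(n)], small_map, mat)


class TestGenotypeProbabilities:
    def test_typed_marker_deterministic(self, small_cross):
        geno, _ = small_cross
        probs = lk.genotype_probabilities(geno, 20_000_000)
        col = geno.codes[:, 2]
        assert np.allclose(probs[col == lk.NN, 0], 1.0)
        assert np.allclose(probs[col == lk.NB, 1], 1.0)

    def test_rows_sum_to_one(self, small_cross):
        geno, _ = small_cross
        for pos in (0, 5_000_000, 12_345_678, 50_000_000):
            probs = lk.genotype_probabilities(geno, pos)
            assert np.allclose(probs.sum(axis=1), 1.0)

    def test_midpoint_between_two_nn_markers(self, small_map):
        # enumerate two-recombination outcomes: P(NN) = (1-r)^2 / ((1-r)^2 + r^2)
        n = 4
        mat = np.full((n, small_map.n_markers), lk.MISSING, dtype=np.int8)
        mat[:, 2] = lk.NN
        mat[:, 3] = lk.NN
        geno = lk.GenotypeMatrix([f"i{k}" for k in range(n)], small_map, mat)
        mid = 25_000_000
        d = 2.5 / 100.0  # 2.5 cM to each flank, in Morgans
        r = lk.haldane(d)
        expected = (1 - r) ** 2 / ((1 - r) ** 2 + r**2)
        probs = lk.genotype_probabilities(geno, mid)
        assert np.allclose(probs[:, 0], expected)

    def test_one_sided_flank_uses_single_marker(self, small_map):
        mat = np.full((2, small_map.n_markers), lk.MISSING, dtype=np.int8)
        mat[0, :] = lk.NN  # fully typed individual keeps matrix valid
        mat[1, 0] = lk.NB
        geno = lk.GenotypeMatrix(["a", "b"], small_map, mat)
        probs = lk.genotype_probabilities(geno, 0)
        assert probs[1, 1] == pytest.approx(1.0)
        # 10 Mbp (5 cM) to the right of the only typed marker
        probs = lk.genotype_probabilities(geno, 10_000_000)
        assert probs[1, 1] == pytest.approx(1 - lk.haldane(0.05))

    def test_uniform_prior_for_untyped_region(self, small_map):
        # one individual typed only at the last marker; probability at the
        # first marker is governed by the full map distance (25 cM)
        mat = np.full((2, small_map.n_markers), lk.MISSING, dtype=np.int8)
        mat[0, :] = lk.NN
        mat[1, -1] = lk.NN
        geno = lk.GenotypeMatrix(["a", "b"], small_map, mat)
        probs = lk.genotype_probabilities(geno, 0)
        r = lk.haldane(25.0 / 100.0)
        assert probs[1, 0] == pytest.approx(1 - r)

    def test_outside_span_rejected(self, small_cross):
        geno, _ = small_cross
        with pytest.raises(ValueError):
            lk.genotype_probabilities(geno, 60_000_000)


class TestEmScan:
    def test_matches_regression_closed_form_at_typed_markers(self, small_cross):
        geno, pheno = small_cross
        y = pheno.trait("glucose").to_numpy()
        curve = lk.em_scan(geno, y, step_bp=10_000_000)
        for j, bp in enumerate(geno.genmap.position_bp):
            oracle = lk.marker_regression_lod(geno.codes[:, j], y)
            i = int(np.where(curve.position_bp == bp)[0][0])
            assert curve.lod[i] == pytest.approx(oracle, abs=1e-6)

    def test_null_lod_small(self, small_map):
        spec = sd.CrossSpec(n=2000, qtl_bp=20_000_000, additive=0.0, sigma=1.0, seed=1)
        geno, pheno = sd.simulate_backcross(small_map, spec)
        curve = lk.em_scan(geno, pheno.trait("glucose").to_numpy(), step_bp=5_000_000)
        assert curve.lod.max() < 3.0
        assert curve.lod.min() >= -1e-8

    def test_lod_nonnegative(self, small_cross):
        geno, pheno = small_cross
        curve = lk.em_scan(geno, pheno.trait("glucose").to_numpy(), step_bp=2_500_000)
        assert (curve.lod >= -1e-8).all()

    def test_affine_invariance(self, small_cross):
        geno, pheno = small_cross
        y = pheno.trait("glucose").to_numpy()
        c1 = lk.em_scan(geno, y, step_bp=10_000_000)
        c2 = lk.em_scan(geno, 3.0 * y - 7.0, step_bp=10_000_000)
        assert np.allclose(c1.lod, c2.lod, atol=1e-5)

    def test_zero_variance_rejected(self, small_cross):
        geno, _ = small_cross
        with pytest.raises(ValueError, match="zero variance"):
            lk.em_scan(geno, np.ones(geno.n_individuals))

    def test_missing_phenotypes_dropped(self, small_cross):
        geno, pheno = small_cross
        y = pheno.trait("glucose").to_numpy().copy()
        y[:10] = np.nan
        curve = lk.em_scan(geno, y, step_bp=10_000_000)
        assert np.isfinite(curve.lod).all()

    def test_effect_recovery_within_3_se(self, chr13_map):
        a, n, sigma = 1.0, 600, 1.0
        spec = sd.CrossSpec(n=n, qtl_bp=sd.PEAK_MARKER_BP, additive=a, sigma=sigma, seed=2)
        geno, pheno = sd.simulate_backcross(chr13_map, spec)
        curve = lk.em_scan(geno, pheno.trait("glucose").to_numpy())
        i = int(np.where(curve.position_bp == sd.PEAK_MARKER_BP)[0][0])
        se = 2.0 * sigma / np.sqrt(n)
        assert abs((curve.mu_nn[i] - curve.mu_nb[i]) - a) < 3 * se

    @pytest.mark.slow
    def test_peak_localization(self, chr13_map):
        # Darvasi-style bound: at a = 1 SD, n = 600 the 95% support is
        # ~0.9 cM half-width, so >= 95% of peaks land within +-3 Mbp.
        hits = 0
        reps = 20
        for s in range(reps):
            spec = sd.CrossSpec(n=600, qtl_bp=sd.PEAK_MARKER_BP, additive=1.0,
                                sigma=1.0, seed=s)
            geno, pheno = sd.simulate_backcross(chr13_map, spec)
            peak, _ = lk.em_scan(geno, pheno.trait("glucose").to_numpy()).peak()
            hits += abs(peak - sd.PEAK_MARKER_BP) <= 3_000_000
        assert hits >= 16  # binomial(20, 0.95) lower tail beyond 3 sigma


class TestPermutation:
    def test_quantile_rule_order_statistics(self):
        # 100 maxima, alpha = 0.01: type-7 interpolates between the 99th and
        # 100th order statistics at h = 99 * 0.99 + 1 = 99.01
        maxima = np.arange(1.0, 101.0)
        null = lk.PermutationNull(max_lod=maxima, alpha=0.01)
        assert null.threshold == pytest.approx(99.0 + 0.01 * 1.0)

    def test_degenerate_identical_maxima(self):
        null = lk.PermutationNull(max_lod=np.full(100, 2.5), alpha=0.01)
        assert null.threshold == pytest.approx(2.5)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            lk.PermutationNull(max_lod=np.ones(10), alpha=0.0)

    def test_permutation_threshold_runs(self, small_cross):
        geno, pheno = small_cross
        y = pheno.trait("glucose").to_numpy()
        with pytest.warns(RuntimeWarning):
            null = lk.permutation_threshold(geno, y, n_perm=50, alpha=0.05,
                                            seed=0, step_bp=10_000_000)
        assert null.n_perm == 50
        assert null.threshold > 0

    def test_invalid_alpha_rejected(self, small_cross):
        geno, pheno = small_cross
        with pytest.raises(ValueError):
            lk.permutation_threshold(geno, pheno.trait("glucose").to_numpy(),
                                     n_perm=100, alpha=1.5)

    def test_deterministic_given_seed(self, small_cross):
        geno, pheno = small_cross
        y = pheno.trait("glucose").to_numpy()
        kw = dict(n_perm=120, alpha=0.05, seed=42, step_bp=10_000_000)
        t1 = lk.permutation_threshold(geno, y, **kw).threshold
        t2 = lk.permutation_threshold(geno, y, **kw).threshold
        assert t1 == t2


class TestPeakEffects:
    def test_identical_values_p_one(self, small_map):
        geno = _single_marker_geno(
            np.array([lk.NN, lk.NN, lk.NB, lk.NB]), small_map
        )
        pheno = np.array([5.0, 5.0, 5.0, 5.0])
        out = lk.peak_effects(geno, pheno, "m2", trait="")
        assert out.p_values["NB vs NN"] == 1.0
        assert out.class_stats.loc["NN", "mean"] == out.class_stats.loc["NB", "mean"]

    def test_welch_t_hand_computed(self, small_map):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        geno = _single_marker_geno(
            np.array([lk.NN] * 3 + [lk.NB] * 3), small_map
        )
        out = lk.peak_effects(geno, np.concatenate([a, b]), "m2", trait="")
        # hand calculation: t = -2 / sqrt(1/3 + 4/3), Welch df = 50/17
        t = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        df = (1 / 3 + 4 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2)
        p_hand = 2 * stats.t.sf(abs(t), df)
        assert t == pytest.approx(-2 / np.sqrt(5 / 3))
        assert out.p_values["NB vs NN"] == pytest.approx(p_hand, abs=1e-12)
        assert out.test == "welch-t"

    def test_three_classes_bonferroni(self, small_map):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        groups = np.array(["BB"] * 4 + ["NB"] * 4 + ["NN"] * 4)
        geno = _single_marker_geno(np.array([lk.NN] * 12), small_map)
        out = lk.peak_effects(geno, y, "m2", trait="", groups=groups)
        assert out.test == "anova-bonferroni"
        for pair in ("BB vs NB", "BB vs NN", "NB vs NN"):
            raw = stats.ttest_ind(y[groups == pair[:2]],
                                  y[groups == pair[-2:]], equal_var=False).pvalue
            assert out.p_values[pair] == pytest.approx(min(1.0, 3 * raw))

    def test_small_class_excluded_with_warning(self, small_map):
        geno = _single_marker_geno(
            np.array([lk.NN, lk.NN, lk.NN, lk.NB]), small_map
        )
        with pytest.raises(ValueError):
            with pytest.warns(RuntimeWarning, match="excluded"):
                lk.peak_effects(geno, np.array([1.0, 2.0, 3.0, 4.0]), "m2", trait="")


class TestGeneticMapValidation:
    def test_decreasing_bp_rejected(self):
        with pytest.raises(ValueError):
            lk.GeneticMap("c", ("a", "b"), np.array([10, 5]), np.array([0.0, 1.0]))

    def test_tied_cm_allowed_and_columns_identical(self):
        gmap = lk.GeneticMap("c", ("a", "b"), np.array([10, 20]),
                             np.array([1.0, 1.0]))
        spec = sd.CrossSpec(n=500, qtl_bp=10, additive=0.0, sigma=1.0, seed=0)
        geno, _ = sd.simulate_backcross(gmap, spec)
        assert np.array_equal(geno.codes[:, 0], geno.codes[:, 1])
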