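import numpy as np
import pytest
from scipy import stats

from cnkit.binning import BinnedCounts
from cnkit.copy_number import (CNEstimate, ReferenceModel, build_reference,
                               estimate_cn, gc_correct, library_scale_factor,
                               qc_summary, ratio_mode, robust_cv,
                               scale_library)
from cnkit.genome import Chromosome, GenomeLayout, tile_genome


def sort_median(values):
    """Independent sort-based median oracle."""
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2


def sort_mad_sd(values):
    m = sort_median(values)
    return 1.4826 * sort_median([abs(v - m) for v in values])


@pytest.fixture
def grid1000():
    layout = GenomeLayout([Chromosome("1", 10_000_000, 0)])
    return tile_genome(layout, 10_000)  # 1000 bins


def _ref(grid, median, sd=None, n=2):
    median = np.asarray(median, dtype=float)
    sd = np.zeros_like(median) if sd is None else np.asarray(sd, dtype=float)
    return ReferenceModel(grid, median, sd, n, [f"r{i}" for i in range(n)])


class TestScaleLibrary:
    def test_identity_when_counts_equal_reference(self, grid1000):
        vals = np.full(len(grid1000), 200.0)
        ref = _ref(grid1000, vals)
        out = scale_library(BinnedCounts(grid1000, vals), ref)
        np.testing.assert_allclose(out.counts, vals)
        assert "s=1" in out.provenance

    def test_double_counts_gives_half_factor(self, grid1000):
        ref = _ref(grid1000, np.full(len(grid1000), 100.0))
        out = scale_library(BinnedCounts(grid1000, np.full(len(grid1000), 200.0)), ref)
        np.testing.assert_allclose(out.counts, 100.0)

    def test_factor_matches_sort_median_oracle(self, grid1000):
        rng = np.random.default_rng(21)
        ref_med = rng.gamma(5, 100, len(grid1000))
        counts = rng.poisson(ref_med * 1.7).astype(float)
        s = library_scale_factor(counts, ref_med)
        ok = counts > 0
        oracle = sort_median(list(ref_med[ok] / counts[ok]))
        assert s == oracle

    def test_no_usable_bins_errors(self, grid1000):
        ref = _ref(grid1000, np.zeros(len(grid1000)))
        with pytest.raises(ValueError, match="cannot scale"):
            scale_library(BinnedCounts(grid1000, np.zeros(len(grid1000))), ref)


class TestGCCorrect:
    def test_constant_counts_stay_constant(self, grid1000):
        n = len(grid1000)
        gc = np.linspace(0.3, 0.7, n)
        bc = BinnedCounts(grid1000, np.full(n, 100.0), gc=gc)
        out = gc_correct(bc)
        np.testing.assert_allclose(out.counts, 100.0, rtol=1e-9)

    def test_deterministic_linear_bias_flattened(self, grid1000):
        # construction oracle: counts are an exact linear function of GC,
        # so corrected counts must be constant away from the strata edges
        n = len(grid1000)
        rng = np.random.default_rng(13)
        gc = rng.uniform(0.3, 0.7, n)
        counts = 100.0 * (1.0 + 2.0 * (gc - 0.5))
        out = gc_correct(BinnedCounts(grid1000, counts, gc=gc))
        interior = (gc > 0.32) & (gc < 0.68)
        vals = out.counts[interior]
        assert np.max(np.abs(vals / np.median(vals) - 1.0)) < 1e-6

    def test_poisson_gc_bias_removed_seed42(self, grid1000):
        n = len(grid1000)
        assert n == 1000
        layout = GenomeLayout([Chromosome("1", 100_000_000, 0)])
        grid = tile_genome(layout, 10_000)  # 10,000 bins
        rng = np.random.default_rng(42)
        gc = rng.uniform(0.3, 0.7, len(grid))
        mu = 500.0 * np.exp(1.5 * (gc - 0.5))
        counts = rng.poisson(mu).astype(float)
        rho_before = stats.spearmanr(counts, gc).statistic
        assert rho_before > 0.6
        out = gc_correct(BinnedCounts(grid, counts, gc=gc))
        rho_after = stats.spearmanr(out.counts, gc).statistic
        assert abs(rho_after) < 0.1

    def test_all_zero_counts_errors(self, grid1000):
        n = len(grid1000)
        bc = BinnedCounts(grid1000, np.zeros(n), gc=np.full(n, 0.5))
        with pytest.raises(ValueError, match="zero"):
            gc_correct(bc)

    def test_insufficient_gc_coverage_errors(self, grid1000):
        n = len(grid1000)
        gc = np.full(n, np.nan)
        gc[: n // 2] = 0.5
        bc = BinnedCounts(grid1000, np.full(n, 10.0), gc=gc)
        with pytest.raises(ValueError, match="90%"):
            gc_correct(bc)

    def test_bins_without_gc_pass_through_flagged(self, grid1000):
        n = len(grid1000)
        gc = np.linspace(0.3, 0.7, n)
        gc[:5] = np.nan
        counts = np.full(n, 100.0)
        out = gc_correct(BinnedCounts(grid1000, counts, gc=gc))
        np.testing.assert_allclose(out.counts[:5], 100.0)
        assert out.gc_uncorrected[:5].all()
        assert not out.gc_uncorrected[5:].any()


class TestBuildReference:
    def test_identical_samples_zero_sd(self, grid1000):
        vals = np.full(len(grid1000), 321.0)
        samples = [BinnedCounts(grid1000, vals.copy(), sample_id=f"s{i}")
                   for i in range(3)]
        ref = build_reference(samples)
        np.testing.assert_allclose(ref.ref_sd, 0.0)
        np.testing.assert_allclose(ref.ref_median, 321.0)
        assert ref.n_samples == 3 and ref.member_ids == ["s0", "s1", "s2"]

    def test_hand_oracle_1_to_5(self, grid1000):
        n = len(grid1000)
        # constant samples scale to each other: after normalization every
        # sample is the cross-sample median, so feed varying bins instead
        base = np.full(n, 100.0)
        samples = []
        for v in (1, 2, 3, 4, 5):
            x = base.copy()
            x[0] = v * 100.0
            samples.append(BinnedCounts(grid1000, x))
        ref = build_reference(samples)
        assert ref.ref_median[0] == pytest.approx(300.0)
        assert ref.ref_sd[0] == pytest.approx(1.4826 * 100.0)

    def test_matches_sort_based_oracle_exactly(self, grid1000):
        rng = np.random.default_rng(31)
        n = len(grid1000)
        mat = rng.gamma(5, 100, size=(20, n))
        samples = [BinnedCounts(grid1000, mat[i]) for i in range(20)]
        ref = build_reference(samples)
        # oracle: sort-based normalization then per-bin sort median/MAD
        pseudo = np.array([sort_median(list(mat[:, j])) for j in range(n)])
        scaled = np.empty_like(mat)
        for i in range(20):
            s = sort_median(list(pseudo[mat[i] > 0] / mat[i][mat[i] > 0]))
            scaled[i] = mat[i] * s
        for j in range(0, n, 97):  # spot-check a spread of bins exactly
            col = list(scaled[:, j])
            assert ref.ref_median[j] == sort_median(col)
            assert ref.ref_sd[j] == sort_mad_sd(col)

    def test_tumour_contamination_robustness_seed7(self, grid1000):
        rng = np.random.default_rng(7)
        n = len(grid1000)
        mu = rng.gamma(8, 60, n) + 100
        normals = [BinnedCounts(grid1000, rng.poisson(mu).astype(float))
                   for _ in range(20)]
        tumours = []
        for _ in range(5):
            cn = np.full(n, 2.0)
            lo = int(rng.integers(0, n - 200))
            cn[lo:lo + 200] = rng.choice([1.0, 3.0, 4.0])
            tumours.append(BinnedCounts(grid1000,
                                        rng.poisson(mu * cn / 2).astype(float)))
        ref_all = build_reference(normals + tumours)
        ref_norm = build_reference(normals)
        rel = np.abs(ref_all.ref_median / ref_norm.ref_median - 1.0)
        assert np.mean(rel < 0.02) >= 0.99

    def test_single_sample_sd_missing(self, grid1000):
        ref = build_reference([BinnedCounts(grid1000,
                                            np.full(len(grid1000), 50.0))])
        assert np.isnan(ref.ref_sd).all()
        assert ref.n_samples == 1

    def test_grid_mismatch(self, grid1000):
        other = tile_genome(GenomeLayout([Chromosome("1", 10_000_000, 0)]), 20_000)
        with pytest.raises(ValueError, match="grid mismatch"):
            build_reference([BinnedCounts(grid1000, np.ones(len(grid1000))),
                             BinnedCounts(other, np.ones(len(other)))])

    def test_empty_cohort(self, grid1000):
        with pytest.raises(ValueError):
            build_reference([])


class TestEstimateCN:
    def test_identity_gives_diploid(self, grid1000):
        vals = np.full(len(grid1000), 400.0)
        ref = _ref(grid1000, vals, np.full(len(grid1000), 20.0))
        est = estimate_cn(BinnedCounts(grid1000, vals), ref)
        np.testing.assert_allclose(est.cn, 2.0)

    def test_half_signal_gives_cn1(self, grid1000):
        n = len(grid1000)
        ref = _ref(grid1000, np.full(n, 400.0), np.full(n, 20.0))
        x = np.full(n, 400.0)
        x[100:120] = 200.0  # heterozygous-deletion signature
        est = estimate_cn(BinnedCounts(grid1000, x), ref)
        np.testing.assert_allclose(est.cn[100:120], 1.0)
        np.testing.assert_allclose(est.cn[:100], 2.0)

    def test_sd_is_sample_side_contribution(self, grid1000):
        n = len(grid1000)
        ref = _ref(grid1000, np.full(n, 400.0), np.full(n, 40.0))
        est = estimate_cn(BinnedCounts(grid1000, np.full(n, 400.0)), ref)
        np.testing.assert_allclose(est.sd, 2.0 * 40.0 / 400.0)

    def test_low_reference_flagged_missing(self, grid1000):
        n = len(grid1000)
        med = np.full(n, 400.0)
        med[:3] = 5.0  # below the 10-read floor
        ref = _ref(grid1000, med)
        est = estimate_cn(BinnedCounts(grid1000, np.full(n, 400.0)), ref)
        assert est.flags["low_ref"][:3].all()
        assert np.isnan(est.cn[:3]).all()
        assert not est.flags["low_ref"][3:].any()

    def test_planted_cn_recovery_seed11(self, grid1000):
        rng = np.random.default_rng(11)
        n = len(grid1000)
        mu = np.full(n, 500.0)
        normals = [BinnedCounts(grid1000, rng.poisson(mu).astype(float))
                   for _ in range(20)]
        ref = build_reference(normals)
        segments = {(0, 100): 0.0, (200, 300): 1.0,
                    (400, 500): 3.0, (600, 650): 10.0}
        cn_true = np.full(n, 2.0)
        for (lo, hi), cn in segments.items():
            cn_true[lo:hi] = cn
        sample = BinnedCounts(grid1000, rng.poisson(mu * cn_true / 2).astype(float))
        scaled = scale_library(sample, ref)
        est = estimate_cn(scaled, ref)
        for (lo, hi), cn in segments.items():
            med = np.median(est.cn[lo:hi])
            tol = 1.0 if cn == 10.0 else 0.15
            assert abs(med - cn) <= tol, (cn, med)

    def test_ploidy_override_per_chromosome(self):
        layout = GenomeLayout([Chromosome("1", 100_000, 0),
                               Chromosome("X", 100_000, 1)])
        grid = tile_genome(layout, 10_000)
        n = len(grid)
        ref = _ref(grid, np.full(n, 400.0))
        est = estimate_cn(BinnedCounts(grid, np.full(n, 400.0)), ref,
                          ploidy_overrides={"X": 1.0})
        assert np.allclose(est.cn[:10], 2.0)
        assert np.allclose(est.cn[10:], 1.0)

    def test_monotonic_in_counts(self, grid1000):
        n = len(grid1000)
        ref = _ref(grid1000, np.full(n, 400.0))
        x = np.full(n, 400.0)
        base = estimate_cn(BinnedCounts(grid1000, x), ref)
        x2 = x.copy()
        x2[50:60] *= 1.75
        bumped = estimate_cn(BinnedCounts(grid1000, x2), ref)
        np.testing.assert_allclose(bumped.cn[50:60], base.cn[50:60] * 1.75)

    def test_grid_mismatch(self, grid1000):
        other = tile_genome(GenomeLayout([Chromosome("1", 10_000_000, 0)]), 20_000)
        ref = _ref(grid1000, np.full(len(grid1000), 400.0))
        with pytest.raises(ValueError, match="grid mismatch"):
            estimate_cn(BinnedCounts(other, np.full(len(other), 400.0)), ref)


class TestRatioMode:
    def test_self_ratio_is_one(self, grid1000):
        rng = np.random.default_rng(2)
        a = BinnedCounts(grid1000, rng.gamma(5, 100, len(grid1000)))
        out = ratio_mode(a, a)
        vals = out.df["N"].to_numpy()
        np.testing.assert_allclose(vals[np.isfinite(vals)], 1.0)

    def test_cn4_over_cn2(self, grid1000):
        n = len(grid1000)
        ref = _ref(grid1000, np.full(n, 400.0))
        a = estimate_cn(BinnedCounts(grid1000, np.full(n, 800.0)), ref)
        b = estimate_cn(BinnedCounts(grid1000, np.full(n, 400.0)), ref)
        out = ratio_mode(a, b)
        np.testing.assert_allclose(out.df["N"], 2.0)

    def test_denominator_floor_yields_missing(self, grid1000):
        n = len(grid1000)
        a = BinnedCounts(grid1000, np.full(n, 100.0))
        b_vals = np.full(n, 100.0)
        b_vals[:5] = 0.0
        out = ratio_mode(a, BinnedCounts(grid1000, b_vals), floor=1.0)
        assert np.isnan(out.df["N"][:5]).all()
        np.testing.assert_allclose(out.df["N"][5:], 1.0)

    def test_two_timepoints_subclonal_gain_seed23(self, grid1000):
        rng = np.random.default_rng(23)
        n = len(grid1000)
        mu = np.full(n, 600.0)
        gain = slice(300, 380)
        mu_b = mu.copy()
        mu_a = mu.copy()
        mu_a[gain] *= 1.35  # subclonal gain appears at the later timepoint
        a = BinnedCounts(grid1000, rng.poisson(mu_a).astype(float))
        b = BinnedCounts(grid1000, rng.poisson(mu_b).astype(float))
        out = ratio_mode(a, b)
        r = out.df["N"].to_numpy()
        # threshold-run oracle: smoothed ratio above 1.15
        kernel = np.ones(11) / 11
        smooth = np.convolve(r, kernel, mode="same")
        hits = np.flatnonzero(smooth > 1.15)
        assert len(hits) > 0
        assert hits.min() >= gain.start - 6 and hits.max() <= gain.stop + 5
        outside = np.ones(n, dtype=bool)
        outside[gain] = False
        assert np.median(r[outside]) == pytest.approx(1.0, abs=0.05)

    def test_grid_mismatch(self, grid1000):
        other = tile_genome(GenomeLayout([Chromosome("1", 10_000_000, 0)]), 20_000)
        with pytest.raises(ValueError, match="grid mismatch"):
            ratio_mode(BinnedCounts(grid1000, np.ones(len(grid1000))),
                       BinnedCounts(other, np.ones(len(other))))


class TestQCSummary:
    def test_constant_vector_cv_zero(self):
        assert robust_cv(np.full(100, 5.0)) == 0.0

    def test_hand_oracle_1_to_5(self):
        assert robust_cv(np.array([1, 2, 3, 4, 5.0])) == pytest.approx(1.4826 / 3)

    def test_median_zero_gives_nan(self):
        assert np.isnan(robust_cv(np.array([])))

    def test_gc_correction_reduces_cv_seed42(self, grid1000):
        rng = np.random.default_rng(42)
        n = len(grid1000)
        gc = rng.uniform(0.3, 0.7, n)
        mu = 500.0 * np.exp(1.2 * (gc - 0.5))
        raw = BinnedCounts(grid1000, rng.poisson(mu).astype(float), gc=gc)
        corrected = gc_correct(raw)
        ref = _ref(grid1000, np.full(n, 500.0), np.full(n, 20.0))
        est = estimate_cn(corrected, ref)
        qc = qc_summary(raw, corrected, est, resolution="10000bp")
        assert qc.cv_gc < qc.cv_raw
        assert qc.resolution == "10000bp"

    def test_target_offtarget_split(self, grid1000):
        n = len(grid1000)
        rng = np.random.default_rng(5)
        raw = BinnedCounts(grid1000, rng.gamma(9, 50, n))
        ref = _ref(grid1000, np.full(n, 450.0), np.full(n, 10.0))
        est = estimate_cn(raw, ref)
        mask = np.zeros(n, dtype=bool)
        mask[:300] = True
        qc = qc_summary(raw, raw, est, targeted_mask=mask)
        assert set(qc.split) == {"target", "offtarget"}
        assert qc.split["target"]["cv_raw"] >= 0
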