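"""Metrics and agreement statistics, each against an independent oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amytrans.evaluation import (bland_altman, fit_correlation, image_metrics,
                                 relative_change_map, voi_mean_suvr,
                                 wilcoxon_signed_rank)
from amytrans.phantom import (CORTICAL_LABELS, Label, PhantomConfig,
                              VolumeImage, make_tissue_map,
                              simulate_tracer_pair)


@pytest.fixture(scope="module")
def small_volumes():
    rng = np.random.default_rng(0)
    shape = (32, 32, 32)
    mask = np.zeros(shape)
    mask[4:28, 4:28, 4:28] = 1
    gt = VolumeImage(rng.random(shape) * mask + 0.2 * mask)
    return gt, VolumeImage(mask)


class TestImageMetrics:
    def test_identical_volumes(self, small_volumes):
        gt, mask = small_volumes
        rmse, psnr, sv = image_metrics(gt, gt, mask, keep_range=(4, 27))
        assert rmse == 0.0 and np.isinf(psnr) and sv == pytest.approx(1.0)

    def test_constant_offset_gives_exact_rmse(self, small_volumes):
        gt, mask = small_volumes
        pred = VolumeImage(gt.data + 0.1 * mask.data)
        rmse, _, _ = image_metrics(pred, gt, mask, keep_range=(4, 27))
        assert rmse == pytest.approx(0.1, abs=1e-12)

    def test_psnr_rmse_formula_identity(self, small_volumes):
        gt, mask = small_volumes
        rng = np.random.default_rng(1)
        pred = VolumeImage(gt.data + 0.05 * rng.standard_normal(gt.data.shape))
        rmse, psnr, _ = image_metrics(pred, gt, mask, data_range=2.0,
                                      keep_range=(4, 27))
        assert psnr == pytest.approx(20 * np.log10(2.0) - 20 * np.log10(rmse),
                                     abs=1e-9)

    def test_empty_mask_rejected(self, small_volumes):
        gt, _ = small_volumes
        with pytest.raises(ValueError):
            image_metrics(gt, gt, VolumeImage(np.zeros(gt.data.shape)))


class TestRelativeChange:
    def test_identical_volumes_give_zero_map(self, small_volumes):
        gt, mask = small_volumes
        assert not relative_change_map(gt, gt, mask).data.any()

    def test_proportional_scaling_gives_uniform_percentage(self, small_volumes):
        gt, mask = small_volumes
        pred = VolumeImage(1.1 * gt.data)
        rcm = relative_change_map(pred, gt, mask, floor=0.05)
        inside = mask.data > 0
        np.testing.assert_allclose(rcm.data[inside], 10.0, atol=1e-9)

    def test_denominator_clamped_at_floor(self):
        gt = VolumeImage(np.full((4, 4, 4), 0.02))
        pred = VolumeImage(np.full((4, 4, 4), 0.12))
        mask = VolumeImage(np.ones((4, 4, 4)))
        rcm = relative_change_map(pred, gt, mask, floor=0.1)
        np.testing.assert_allclose(rcm.data, 100.0 * 0.1 / 0.1)

    def test_negative_floor_rejected(self, small_volumes):
        gt, mask = small_volumes
        with pytest.raises(ValueError):
            relative_change_map(gt, gt, mask, floor=-1.0)


class TestBlandAltman:
    def test_identical_series(self):
        a = np.linspace(1, 2, 10)
        ba = bland_altman(a, a)
        assert ba.mean_diff == 0 and ba.lower == 0 and ba.upper == 0

    def test_constant_offset(self):
        a = np.linspace(1, 2, 10)
        ba = bland_altman(a + 0.3, a)
        assert ba.mean_diff == pytest.approx(0.3)
        assert ba.upper == pytest.approx(ba.lower) == pytest.approx(0.3)

    def test_limits_match_independent_summary(self, rng):
        a, b = rng.random(50), rng.random(50)
        ba = bland_altman(a, b)
        d = a - b
        assert ba.mean_diff == pytest.approx(d.mean())
        assert ba.upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert ba.lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))

    @given(st.integers(2, 30), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_limits_bracket_mean(self, n, seed):
        r = np.random.default_rng(seed)
        ba = bland_altman(r.random(n), r.random(n))
        assert ba.lower <= ba.mean_diff <= ba.upper

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1, 2], [1, 2, 3])


class TestCorrelationFit:
    def test_identity_line(self):
        x = np.linspace(0, 3, 20)
        fit = fit_correlation(x, x)
        assert (fit.slope, fit.intercept, fit.r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_noiseless_affine_map(self):
        x = np.linspace(0, 3, 20)
        fit = fit_correlation(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0) and fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.random(40) * 3
        y = 1.4 * x - 0.2 + 0.1 * rng.standard_normal(40)
        fit = fit_correlation(x, y)
        A = np.stack([x, np.ones_like(x)], axis=1)
        beta = np.linalg.solve(A.T @ A, A.T @ y)
        assert fit.slope == pytest.approx(beta[0], abs=1e-9)
        assert fit.intercept == pytest.approx(beta[1], abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_correlation(np.ones(5), np.arange(5.0))


def _enumerated_signed_rank(d):
    """Exhaustive sign-flip oracle: distribution of T+ over all 2^n flips."""
    from scipy.stats import rankdata
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    t_plus = ranks[d > 0].sum()
    n = d.size
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    stats = np.asarray(stats, dtype=float)
    p_ge = np.mean(stats >= t_plus - 1e-12)
    p_le = np.mean(stats <= t_plus + 1e-12)
    return t_plus - ranks[d < 0].sum(), min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 10), (3, 12)])
    def test_matches_exhaustive_enumeration(self, seed, n):
        r = np.random.default_rng(seed)
        a = r.random(n)
        b = a + r.standard_normal(n) * 0.4
        stat, p = wilcoxon_signed_rank(a, b)
        ref_stat, ref_p = _enumerated_signed_rank(a - b)
        assert stat == pytest.approx(ref_stat)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_textbook_hand_computation(self):
        """n = 6, differences with distinct magnitudes: ranks are hand
        assignable and T+ - T- follows directly."""
        a = np.array([10.0, 12.0, 9.0, 14.0, 8.0, 11.0])
        b = np.array([9.5, 10.0, 9.6, 11.0, 8.4, 11.9])
        # d = +0.5, +2.0, -0.6, +3.0, -0.4, -0.9 -> ranks 2, 5, 3, 6, 1, 4
        stat, _ = wilcoxon_signed_rank(a, b)
        assert stat == (2 + 5 + 6) - (3 + 1 + 4)

    def test_swapping_samples_flips_statistic_not_p(self, rng):
        a = rng.random(10)
        b = a + rng.standard_normal(10) * 0.3
        s1, p1 = wilcoxon_signed_rank(a, b)
        s2, p2 = wilcoxon_signed_rank(b, a)
        assert s1 == -s2 and p1 == pytest.approx(p2)

    def test_agrees_with_scipy_exact(self, rng):
        from scipy import stats
        a = rng.random(12)
        b = a + rng.standard_normal(12) * 0.5
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(stats.wilcoxon(a, b, method="exact").pvalue,
                                  abs=1e-12)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_large_sample_uses_normal_approximation(self, rng):
        from scipy import stats
        a = rng.random(40)
        b = a + rng.standard_normal(40) * 0.2
        _, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


class TestVoiMeans:
    @pytest.fixture(scope="class")
    def noiseless(self):
        cfg = PhantomConfig(grid_shape=(48, 40, 40), psf_fwhm_mm=0.0,
                            noise_sd=0.0)
        tissue = make_tissue_map(cfg, np.random.default_rng(4))
        pib, fbb = simulate_tracer_pair(tissue, 0.5, cfg, np.random.default_rng(0))
        return tissue, pib, fbb

    def test_uniform_volume_means(self, noiseless):
        tissue, _, _ = noiseless
        vol = VolumeImage(np.full(tissue.labels.shape, 1.3))
        means = voi_mean_suvr(vol, tissue)
        assert all(v == pytest.approx(1.3) for v in means)

    def test_phantom_ground_truth_values(self, noiseless):
        """Region means equal the assigned tissue-class SUVr at burden 0.5."""
        tissue, pib, fbb = noiseless
        m = voi_mean_suvr(pib, tissue)
        assert m["cortex"] == pytest.approx(2.0)
        assert m["frontal"] == pytest.approx(2.0)
        assert m["choroid_plexus"] == pytest.approx(0.9 + 0.4 * 0.5)
        m2 = voi_mean_suvr(fbb, tissue)
        assert m2["cortex"] == pytest.approx(1.6)

    def test_whole_brain_mean_is_convex_combination(self, noiseless):
        tissue, pib, _ = noiseless
        m = voi_mean_suvr(pib, tissue)
        parts = [m[k] for k in ("frontal", "parietal", "temporal",
                                "medial_temporal", "occipital", "cingulate",
                                "choroid_plexus")]
        wm = pib.data[tissue.region(Label.WHITE)].mean()
        cb = pib.data[tissue.region(Label.CEREBELLUM)].mean()
        lo, hi = min(parts + [wm, cb]), max(parts + [wm, cb])
        assert lo <= m["whole_brain"] <= hi

    def test_empty_region_reports_name(self, noiseless):
        tissue, pib, _ = noiseless
        with pytest.raises(ValueError, match="nothing_here"):
            voi_mean_suvr(pib, tissue, {"nothing_here": (99,)})
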