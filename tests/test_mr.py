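import numpy as np
import pytest
import statsmodels.api as sm

from targetmr import (
    HarmonizedPair,
    bonferroni_threshold,
    estimate_effect,
    ivw,
    mr_egger,
    mr_presso,
    scale_report,
    simulate_pair,
    wald_ratio,
    weighted_median,
)
from targetmr.mr import Z95, _weighted_median
from targetmr.simulate import SyntheticConfig

from conftest import pair_from_truth, rng_spawn


def _pair(bx, sx, by, sy):
    return HarmonizedPair.from_arrays(bx, sx, by, sy)


class TestWaldRatio:
    def test_hand_arithmetic(self):
        est = wald_ratio(_pair([0.1], [0.01], [0.05], [0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome(self):
        est = wald_ratio(_pair([0.1], [0.01], [0.0], [0.01]))
        assert est.beta == 0.0
        assert est.pval == 1.0

    def test_sign_consistency_under_allele_flip(self):
        a = wald_ratio(_pair([0.1], [0.01], [0.05], [0.01]))
        b = wald_ratio(_pair([-0.1], [0.01], [-0.05], [0.01]))
        assert (a.beta, a.se) == pytest.approx((b.beta, b.se))

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(_pair([0.0], [0.01], [0.05], [0.01]))


class TestIVW:
    def test_exact_fit_closed_form(self):
        est = ivw(_pair([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01]))
        assert est.beta == pytest.approx(0.5)
        assert est.q_stat == pytest.approx(0.0, abs=1e-20)
        assert est.phi == 1.0
        assert est.se == pytest.approx(1 / np.sqrt(500.0))

    def test_equal_ratios_recovered_exactly(self):
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.05, 0.3, 6)
        c = -0.7
        est = ivw(_pair(bx, bx * 0 + 0.01, c * bx, rng.uniform(0.01, 0.05, 6)))
        assert est.beta == pytest.approx(c)

    def test_matches_statsmodels_wls_through_origin(self):
        """Dual-route check: closed form vs an independent WLS fit."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            k = int(rng.integers(2, 30))
            bx = rng.normal(0, 0.2, k)
            by = rng.normal(0, 0.2, k)
            sy = rng.uniform(0.005, 0.1, k)
            est = ivw(_pair(bx, sy, by, sy), underdispersion_floor=False)
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
            # statsmodels' sigma2 is the phi = Q/(k-1) scale with no floor
            assert est.se == pytest.approx(fit.bse[0], rel=1e-8)

    def test_floor_never_shrinks_se_below_fixed_effect(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = int(rng.integers(2, 15))
            bx = rng.normal(0, 0.2, k)
            by = 0.3 * bx + rng.normal(0, 1e-6, k)  # near-exact fit: Q ~ 0
            sy = rng.uniform(0.01, 0.1, k)
            est = ivw(_pair(bx, sy, by, sy))
            fixed_se = 1 / np.sqrt(np.sum(bx**2 / sy**2))
            assert est.se >= fixed_se * (1 - 1e-12)
            assert est.phi >= 1.0

    def test_k1_rejected_and_dispatch_matches_wald(self):
        single = _pair([0.1], [0.01], [0.05], [0.01])
        with pytest.raises(ValueError, match="wald"):
            ivw(single)
        assert estimate_effect(single) == wald_ratio(single)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0, 0.2, 8)
        by = rng.normal(0, 0.1, 8)
        sy = rng.uniform(0.01, 0.1, 8)
        flip = np.where(np.arange(8) % 2 == 0, -1.0, 1.0)
        a = ivw(_pair(bx, sy, by, sy))
        b = ivw(_pair(flip * bx, sy, flip * by, sy))
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)


class TestEgger:
    def test_k2_rejected(self):
        with pytest.raises(ValueError, match="3"):
            mr_egger(_pair([0.1, 0.2], [0.01, 0.01], [0.0, 0.1], [0.01, 0.01]))

    def test_matches_statsmodels_wls_with_intercept(self):
        rng = np.random.default_rng(21)
        k = 12
        bx = np.abs(rng.normal(0.2, 0.05, k))
        by = 0.01 + 0.4 * bx + rng.normal(0, 0.02, k)
        sy = rng.uniform(0.01, 0.05, k)
        slope, intercept = mr_egger(_pair(bx, sy, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_slope_and_intercept_recovery(self):
        """Simulated data with known slope and constant directional
        pleiotropy: both coefficients land within 3 SE almost always."""
        theta, delta = 0.05, 0.02
        hits_slope = hits_int = 0
        reps = 200
        for seed in rng_spawn(101, reps):
            cfg = SyntheticConfig(
                seed=seed, m_snps=20, ld_decay=0.0,
                causal_index=tuple(range(20)),
                causal_beta=tuple(np.linspace(0.3, 0.8, 20)),
                theta=theta, directional_pleiotropy=delta, pleiotropy_sd=0.0,
            )
            e, o, _ = simulate_pair(cfg)
            slope, intercept = mr_egger(pair_from_truth(e, o))
            hits_slope += abs(slope.beta - theta) <= 3 * slope.se
            hits_int += abs(intercept.beta - delta) <= 3 * intercept.se
        assert hits_slope / reps >= 0.97
        assert hits_int / reps >= 0.97

    def test_orientation_invariance(self):
        rng = np.random.default_rng(9)
        bx = rng.normal(0, 0.3, 10)
        by = rng.normal(0, 0.1, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        flip = np.where(rng.random(10) < 0.5, -1.0, 1.0)
        a = mr_egger(_pair(bx, sy, by, sy))
        b = mr_egger(_pair(flip * bx, sy, flip * by, sy))
        assert a[0].beta == pytest.approx(b[0].beta)
        assert a[1].beta == pytest.approx(b[1].beta)


class TestWeightedMedian:
    def test_equal_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        est = weighted_median(_pair(bx, 0.01 * np.ones(3), 0.4 * bx, [0.01, 0.02, 0.03]))
        assert est.beta == pytest.approx(0.4)

    def test_uniform_weights_reduce_to_plain_median(self):
        ratios = np.array([0.1, 0.5, 0.9, 0.2, 0.7])
        assert _weighted_median(ratios, np.ones(5)) == pytest.approx(np.median(ratios))

    def test_outlier_robustness(self):
        """One gross outlier among ten concordant instruments barely moves
        the estimate (50% breakdown)."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 100
        for seed in rng_spawn(77, reps):
            rng = np.random.default_rng(seed)
            bx = rng.uniform(0.2, 0.5, 10)
            sy = np.full(10, 0.005)
            by = 0.3 * bx + rng.normal(0, sy)
            by[0] += 1.0  # gross pleiotropic outlier
            est = weighted_median(_pair(bx, np.full(10, 1e-4), by, sy), n_boot=200, seed=seed)
            hits += abs(est.beta - 0.3) <= 3 * est.se
        assert hits / reps >= 0.95

    def test_zero_exposure_beta_excluded_with_warning(self):
        bx = [0.0, 0.2, 0.3, 0.4]
        with pytest.warns(UserWarning):
            est = weighted_median(_pair(bx, [0.01] * 4, [0.0, 0.08, 0.12, 0.16], [0.01] * 4))
        assert est.k == 3
        assert est.beta == pytest.approx(0.4, abs=1e-9)

    def test_deterministic_under_seed(self):
        bx = np.linspace(0.1, 0.4, 5)
        by = 0.2 * bx
        a = weighted_median(_pair(bx, [0.01] * 5, by, [0.02] * 5), seed=42)
        b = weighted_median(_pair(bx, [0.01] * 5, by, [0.02] * 5), seed=42)
        assert a == b


class TestPresso:
    def test_k3_rejected(self):
        with pytest.raises(ValueError):
            mr_presso(_pair([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.01] * 3))

    def test_injected_outlier_detected(self):
        rng = np.random.default_rng(13)
        k = 20
        bx = rng.uniform(0.2, 0.6, k)
        sy = np.full(k, 0.01)
        by = 0.1 * bx + rng.normal(0, sy)
        by[7] += 10 * sy[7]  # pleiotropic effect 10x its SE
        res = mr_presso(_pair(bx, np.full(k, 1e-4), by, sy), seed=1)
        assert "snp8" in res.outliers
        assert res.global_p < 0.05

    def test_clean_data_corrected_equals_ivw(self):
        e, o, _ = simulate_pair(SyntheticConfig(
            seed=4, m_snps=20, ld_decay=0.0, causal_index=tuple(range(20)),
            causal_beta=0.5, theta=0.05))
        pair = pair_from_truth(e, o)
        res = mr_presso(pair, seed=0)
        if not res.outliers:
            assert res.corrected.beta == pytest.approx(ivw(pair).beta)
            assert res.global_p > 0.05

    def test_deterministic_under_seed(self):
        bx = np.linspace(0.1, 0.5, 6)
        by = 0.2 * bx + np.array([0.001, -0.002, 0.0, 0.002, -0.001, 0.0])
        a = mr_presso(_pair(bx, [0.01] * 6, by, [0.01] * 6), seed=9)
        b = mr_presso(_pair(bx, [0.01] * 6, by, [0.01] * 6), seed=9)
        assert a.global_p == b.global_p


class TestScaling:
    def test_null_beta_gives_unit_or(self):
        est = wald_ratio(_pair([0.1], [0.01], [0.0], [0.01]))
        rep = scale_report(est, -10, "case_control", 0.017)
        assert rep.value == 1.0
        assert rep.ci[0] < 1.0 < rep.ci[1]

    def test_reduction_scaling_binary(self):
        """Per-mmHg log-odds 0.0478 becomes OR exp(-0.478) ~ 0.62 per
        10-mmHg reduction."""
        pair = _pair([1.0], [0.01], [0.0478], [0.01])
        rep = scale_report(wald_ratio(pair), -10, "case_control")
        assert rep.value == pytest.approx(np.exp(-0.478))
        assert rep.ci[0] < rep.ci[1]

    def test_reduction_scaling_flips_continuous_sign(self):
        pair = _pair([1.0], [0.01], [-0.027], [0.01])
        rep = scale_report(wald_ratio(pair), -10, "continuous")
        assert rep.value == pytest.approx(0.27)

    def test_ci_transform_monotone_and_coverage_preserving(self):
        est = wald_ratio(_pair([1.0], [0.01], [0.05], [0.02]))
        rep = scale_report(est, -10, "case_control")
        lo, hi = rep.ci
        assert lo == pytest.approx(np.exp(-10 * est.beta - Z95 * 10 * est.se))
        assert hi == pytest.approx(np.exp(-10 * est.beta + Z95 * 10 * est.se))

    def test_scale_equivariance_on_log_odds(self):
        est = wald_ratio(_pair([1.0], [0.01], [0.03], [0.02]))
        a = scale_report(est, -20, "case_control")
        b = scale_report(est, -10, "case_control")
        assert np.log(a.value) == pytest.approx(2 * np.log(b.value))

    def test_bonferroni(self):
        assert f"{bonferroni_threshold(0.05, 3):.3f}" == "0.017"
        assert bonferroni_threshold(0.05, 1) == 0.05
        assert bonferroni_threshold(0.10, 4) == 0.025
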