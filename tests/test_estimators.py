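"""MR estimator suite: oracles, reductions, invariances and robustness."""

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_hd
from cytomr.errors import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
)
from cytomr.estimators import (
    ConMixConfig,
    PressoConfig,
    contamination_mixture,
    conmix_validity_mask,
    egger,
    ivw,
    ivw_correlated,
    mr_presso,
    mvmr_ivw,
    wald_ratio,
    weighted_median,
)
from cytomr.experiments import make_dataset
from cytomr.sumstats import HarmonizedDataset, HarmonizedRecord, LDMatrix


class TestWaldRatio:
    def test_forced_arithmetic(self):
        res = wald_ratio(0.5, 0.05, -0.1, 0.02)
        assert res.theta == pytest.approx(-0.2)
        assert res.se == pytest.approx(0.04)
        assert res.ci_low == pytest.approx(-0.2 - 1.959963984540054 * 0.04)

    def test_null_outcome_gives_p_one(self):
        res = wald_ratio(1.0, 0.1, 0.0, 0.1)
        assert res.theta == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.1, 0.1, 0.1)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        hd = make_hd([0.5], [-0.1], se_y=0.02)
        res = ivw(hd)
        assert res.method == "wald_ratio"
        assert res.theta == pytest.approx(-0.2)

    def test_equal_weight_ratios_average_and_brute_force_q(self):
        # beta_x identical and se_y identical -> equal weights
        hd = make_hd([0.5, 0.5, 0.5], [0.05, 0.10, 0.15], se_y=0.02)
        res = ivw(hd, effects="fixed")
        assert res.theta == pytest.approx(0.2)
        w = 0.5**2 / 0.02**2
        q_expected = sum(w * (r - 0.2) ** 2 for r in (0.1, 0.2, 0.3))
        assert res.q_stat == pytest.approx(q_expected, rel=1e-10)
        assert res.q_df == 2

    def test_matches_weighted_regression_through_origin(self, rng):
        hd = make_dataset(rng, j=12, theta=0.3)
        bx, _, by, sy = hd.arrays()
        fit = sm.WLS(by, bx, weights=1.0 / sy**2).fit()
        res = ivw(hd, effects="fixed")
        assert res.theta == pytest.approx(fit.params[0], rel=1e-10)
        # statsmodels rescales by the residual variance; undo to compare
        se_fixed = fit.bse[0] / np.sqrt(fit.scale)
        assert res.se == pytest.approx(se_fixed, rel=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            hd = make_dataset(rng, j=8, theta=0.1,
                              pleiotropy=rng.normal(0, 0.05, size=8))
            assert ivw(hd).se >= ivw(hd, effects="fixed").se - 1e-15

    def test_zero_exposure_beta_snps_dropped(self):
        hd = make_hd([0.5, 0.0, 0.5], [0.1, 0.7, 0.1])
        res = ivw(hd)
        assert res.n_snps == 2

    def test_allele_coding_invariance(self, rng):
        hd = make_dataset(rng, j=10, theta=0.2)
        flipped_recs = [
            HarmonizedRecord(r.variant_id, -r.beta_x, r.se_x, -r.beta_y, r.se_y, r.eaf)
            if i % 2 else r
            for i, r in enumerate(hd.records)
        ]
        hd2 = HarmonizedDataset("e", "o", flipped_recs)
        assert ivw(hd2).theta == pytest.approx(ivw(hd).theta, rel=1e-12)
        assert weighted_median(hd2, n_boot=50, seed=3).theta == pytest.approx(
            weighted_median(hd, n_boot=50, seed=3).theta, rel=1e-12)
        assert contamination_mixture(hd2).theta == pytest.approx(
            contamination_mixture(hd).theta, rel=1e-12)
        assert egger(hd2).theta == pytest.approx(egger(hd).theta, rel=1e-12)


class TestIVWCorrelated:
    def test_identity_ld_reduces_to_fixed_effect_ivw(self, rng):
        hd = make_dataset(rng, j=6, theta=0.25)
        ld = LDMatrix([r.variant_id for r in hd.records], np.eye(6))
        hd.ld = ld
        res_ld = ivw_correlated(hd, effects="fixed")
        res = ivw(hd, effects="fixed")
        assert res_ld.theta == pytest.approx(res.theta, abs=1e-10)
        assert res_ld.se == pytest.approx(res.se, abs=1e-10)

    def test_two_snp_worked_example_against_matrix_inverse_oracle(self):
        bx = np.array([0.4, 0.3])
        by = np.array([0.10, 0.06])
        sy = np.array([0.02, 0.03])
        r = np.array([[1.0, 0.3], [0.3, 1.0]])
        ld = LDMatrix(["rs1", "rs2"], r)
        hd = make_hd(bx, by, se_y=0.0)  # se overridden below
        hd.records = [
            HarmonizedRecord("rs1", 0.4, 0.02, 0.10, 0.02, 0.3),
            HarmonizedRecord("rs2", 0.3, 0.02, 0.06, 0.03, 0.3),
        ]
        hd.ld = ld
        omega = np.outer(sy, sy) * r
        oinv = np.linalg.inv(omega)
        theta_exp = float(bx @ oinv @ by) / float(bx @ oinv @ bx)
        se_exp = float(np.sqrt(1.0 / (bx @ oinv @ bx)))
        res = ivw_correlated(hd, effects="fixed")
        assert res.theta == pytest.approx(theta_exp, rel=1e-10)
        assert res.se == pytest.approx(se_exp, rel=1e-10)

    def test_near_duplicate_snp_does_not_double_count_information(self):
        hd1 = make_hd([0.4], [0.1], se_y=0.02)
        single = ivw(hd1)
        r = np.array([[1.0, 0.999], [0.999, 1.0]])
        hd2 = make_hd([0.4, 0.4], [0.1, 0.1], se_y=0.02,
                      ld=LDMatrix(["rs1", "rs2"], r))
        dup = ivw_correlated(hd2, effects="fixed")
        assert dup.theta == pytest.approx(single.theta, abs=1e-3)
        # the SE shrinks by at most the tiny extra information in r=0.999
        assert dup.se > single.se * 0.7

    def test_perfectly_collinear_ld_raises(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        hd = make_hd([0.4, 0.4], [0.1, 0.1], ld=LDMatrix(["rs1", "rs2"], r))
        with pytest.raises(CollinearityError):
            ivw_correlated(hd)


class TestEgger:
    def test_noise_free_proportional_data_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hd = make_hd(bx, 0.5 * bx)
        res = egger(hd)
        assert res.theta == pytest.approx(0.5, abs=1e-12)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_pleiotropy_recovered_as_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        hd = make_hd(bx, 0.1 + 0.5 * bx)
        res = egger(hd)
        assert res.theta == pytest.approx(0.5, abs=1e-10)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)

    def test_noisy_fixture_matches_weighted_least_squares_oracle(self, rng):
        hd = make_dataset(rng, j=5, theta=0.4, bx_sign="positive")
        bx, _, by, sy = hd.arrays()
        X = sm.add_constant(bx)
        fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
        res = egger(hd)
        assert res.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert res.theta == pytest.approx(fit.params[1], rel=1e-10)
        # SEs match under the multiplicative-inflation convention
        infl = max(1.0, np.sqrt(fit.scale))
        assert res.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * infl, rel=1e-8)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_hd([0.1, 0.2], [0.05, 0.1]))


def _brute_force_weighted_median(values, weights):
    """Independent oracle: scan the cumulative midpoint-weight function."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w)
    p = s - w / 2.0
    if 0.5 <= p[0]:
        return v[0]
    if 0.5 >= p[-1]:
        return v[-1]
    k = np.searchsorted(p, 0.5)
    return v[k - 1] + (v[k] - v[k - 1]) * (0.5 - p[k - 1]) / (p[k] - p[k - 1])


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_middle_ratio(self):
        # bx = 1, se_y equal -> equal weights; ratios 1, 2, 9
        hd = make_hd([1.0, 1.0, 1.0], [1.0, 2.0, 9.0])
        assert weighted_median(hd, n_boot=50, seed=0).theta == pytest.approx(2.0)

    def test_interpolated_value_matches_brute_force_oracle(self):
        # weights proportional to (0.5, 0.25, 0.25) on ratios (1, 2, 3):
        # cumulative midpoints (0.25, 0.625, 0.875) -> interpolate to 5/3
        bx = np.array([np.sqrt(2.0), 1.0, 1.0])
        by = bx * np.array([1.0, 2.0, 3.0])
        hd = make_hd(bx, by, se_y=0.05)
        res = weighted_median(hd, n_boot=50, seed=0)
        assert res.theta == pytest.approx(5.0 / 3.0, rel=1e-12)
        assert res.theta == pytest.approx(
            _brute_force_weighted_median([1, 2, 3], [0.5, 0.25, 0.25]), rel=1e-12)

    def test_random_weights_match_oracle(self, rng):
        for _ in range(20):
            hd = make_dataset(rng, j=7, theta=0.2)
            bx, _, by, sy = hd.arrays()
            got = weighted_median(hd, n_boot=50, seed=1).theta
            assert got == pytest.approx(
                _brute_force_weighted_median(by / bx, bx**2 / sy**2), rel=1e-10)

    def test_bootstrap_se_reproducible_with_seed(self, rng):
        hd = make_dataset(rng, j=6, theta=0.1)
        a = weighted_median(hd, n_boot=200, seed=42)
        b = weighted_median(hd, n_boot=200, seed=42)
        assert a.se == b.se


class TestConMix:
    def test_identical_ratios_return_consensus(self):
        hd = make_hd([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        assert contamination_mixture(hd).theta == pytest.approx(0.4)

    def test_outliers_assigned_invalid_and_theta_near_truth(self, rng):
        # 8 SNPs consistent with theta 0.2 plus 2 planted outliers at ratio 2
        bx = np.full(10, 0.5)
        by = 0.2 * bx + rng.normal(0, 0.01, size=10)
        by[:2] = 2.0 * bx[:2]
        hd = make_hd(bx, by, se_y=0.01)
        res = contamination_mixture(hd)
        assert res.theta == pytest.approx(0.2, abs=0.05)
        mask = conmix_validity_mask(hd)
        assert not mask[0] and not mask[1]
        assert mask[2:].all()

    def test_huge_psi_uninformative_limit_is_flagged(self, rng):
        hd = make_dataset(rng, j=6, theta=0.3)
        res = contamination_mixture(hd, ConMixConfig(psi=1e6))
        assert "uninformative" in res.notes

    def test_ci_brackets_estimate(self, rng):
        hd = make_dataset(rng, j=8, theta=0.15)
        res = contamination_mixture(hd)
        assert res.ci_low <= res.theta <= res.ci_high


class TestPresso:
    def test_seed_determinism(self, rng):
        hd = make_dataset(rng, j=8, theta=0.2)
        cfg = PressoConfig(n_sim=300, seed=7)
        assert mr_presso(hd, cfg)[0] == mr_presso(hd, cfg)[0]

    def test_planted_outlier_flagged_and_correction_helps(self, rng):
        hd = make_dataset(rng, j=10, theta=0.1)
        r = hd.records[4]
        hd.records[4] = HarmonizedRecord(r.variant_id, r.beta_x, r.se_x,
                                         10 * max(abs(r.beta_y), 0.05), r.se_y, r.eaf)
        gp, flags, corrected = mr_presso(hd, PressoConfig(n_sim=500, seed=1))
        assert gp < 0.05
        assert flags[4]
        raw = ivw(hd)
        assert abs(corrected.theta - 0.1) < abs(raw.theta - 0.1)

    def test_too_few_snps_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(make_hd([0.1, 0.2, 0.3], [0.0, 0.1, 0.2]))


class TestMVMR:
    def test_exact_recovery_of_known_coefficients(self, rng):
        X = rng.normal(0.2, 0.1, size=(10, 2))
        y = X @ np.array([0.3, -0.2])
        res = mvmr_ivw(X, y, np.full(10, 0.02))
        assert res[0].theta == pytest.approx(0.3, abs=1e-10)
        assert res[1].theta == pytest.approx(-0.2, abs=1e-10)

    def test_single_column_reduces_to_ivw(self, rng):
        hd = make_dataset(rng, j=10, theta=0.2)
        bx, _, by, sy = hd.arrays()
        (res,) = mvmr_ivw(bx[:, None], by, sy)
        fe = ivw(hd, effects="fixed")
        re = ivw(hd)
        assert res.theta == pytest.approx(fe.theta, abs=1e-10)
        # the J-K df inflation of the one-column fit equals the RE inflation
        assert res.se == pytest.approx(re.se, abs=1e-10)

    def test_collinear_columns_raise(self, rng):
        x = rng.normal(size=10)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(CollinearityError):
            mvmr_ivw(X, rng.normal(size=10), np.full(10, 0.02))

    def test_matches_weighted_least_squares_oracle(self, rng):
        X = rng.normal(0.2, 0.1, size=(12, 2))
        y = X @ np.array([0.3, -0.2]) + rng.normal(0, 0.02, size=12)
        sy = np.full(12, 0.02)
        res = mvmr_ivw(X, y, sy)
        fit = sm.WLS(y, X, weights=1.0 / sy**2).fit()
        for k in range(2):
            assert res[k].theta == pytest.approx(fit.params[k], rel=1e-10)


class TestDirectionalPleiotropy:
    def test_egger_recovers_under_inside_while_ivw_is_biased(self, rng):
        # balanced pleiotropy (InSIDE): Egger slope consistent; one-signed
        # pleiotropy on one-signed instruments: IVW biased upward
        theta = 0.2
        egger_err, ivw_err = [], []
        for _ in range(100):
            alpha = rng.normal(0, 0.05, size=15)
            hd = make_dataset(rng, j=15, theta=theta, pleiotropy=alpha,
                              bx_sign="positive")
            egger_err.append(egger(hd).theta - theta)
            alpha_dir = np.abs(rng.normal(0, 0.05, size=15))
            hd_dir = make_dataset(rng, j=15, theta=theta, pleiotropy=alpha_dir,
                                  bx_sign="positive")
            ivw_err.append(ivw(hd_dir).theta - theta)
        assert abs(np.mean(egger_err)) < 3 * np.std(egger_err) / 10  # ~Monte-Carlo error
        assert np.mean(ivw_err) > 5 * abs(np.mean(egger_err))
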