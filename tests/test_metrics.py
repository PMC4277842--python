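"""Statistics battery vs independent oracles: all-pairs c index, bootstrap
DeLong variance, hand-summed Hosmer-Lemeshow, quadratic-root Wilson bounds,
closed-form Cox distortion recovery, hand-arithmetic accuracy measures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score, roc_curve

from icuvalid import (
    PredictionSet,
    brier_score,
    c_index,
    calibration_groups,
    cox_calibration,
    delong_test,
    entropy_r2,
    hosmer_lemeshow,
    oe_ratio,
    roc_points,
    shapiro_r,
    ss_r2,
    validate,
    wilson_ci,
)
from icuvalid.metrics import ValidationReport

from conftest import make_prediction_set


def cindex_all_pairs(y, p):
    """Brute-force pair enumeration with ties counted half."""
    deaths, survivors = p[y == 1], p[y == 0]
    total = 0.0
    for d in deaths:
        for s in survivors:
            total += 1.0 if d > s else (0.5 if d == s else 0.0)
    return total / (len(deaths) * len(survivors))


class TestCIndex:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert c_index((y, p))[0] == 1.0

    def test_all_ties_give_half(self):
        y = np.array([0, 1, 0, 1])
        p = np.full(4, 0.3)
        assert c_index((y, p))[0] == 0.5

    def test_matches_all_pairs_enumeration_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 61))
            # coarse grid of risks forces ties
            p = rng.choice(np.linspace(0.05, 0.95, 7), size=n)
            y = (rng.random(n) < p).astype(int)
            if y.min() == y.max():
                y[0], y[1] = 0, 1
            assert c_index((y, p))[0] == pytest.approx(cindex_all_pairs(y, p), abs=1e-12)

    def test_agrees_with_reference_auc(self, preds):
        assert c_index(preds)[0] == pytest.approx(
            roc_auc_score(preds.outcome, preds.predicted_risk), abs=1e-12
        )

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            c_index((np.ones(5, int), np.full(5, 0.5)))

    @given(st.floats(min_value=0.1, max_value=5.0), st.floats(min_value=-2, max_value=2))
    def test_invariant_under_monotone_transform(self, a, b):
        rng = np.random.default_rng(42)
        n = 80
        p = rng.random(n)
        y = (rng.random(n) < p).astype(int)
        y[0], y[1] = 0, 1
        transformed = np.exp(a * p + b)  # strictly increasing
        assert c_index((y, p))[0] == pytest.approx(c_index((y, transformed))[0], abs=1e-12)


class TestDeLong:
    def test_self_comparison_is_null(self, preds):
        ca, cb, diff, var, z, p = delong_test(preds, preds)
        assert diff == 0 and var == 0 and p == 1.0

    def test_monotone_transform_gives_zero_difference(self, preds):
        risk2 = expit(2.0 * preds.log_odds + 0.3)  # monotone in log-odds
        other = PredictionSet.from_risks("transformed", preds.admission_ids, risk2, preds.outcome)
        *_, diff, var, z, p = delong_test(preds, other)
        assert diff == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_z_antisymmetric_under_model_swap(self, rng):
        a = make_prediction_set(rng, n=300, name="a")
        noisy = expit(a.log_odds + rng.normal(0, 1, 300))
        b = PredictionSet.from_risks("b", a.admission_ids, noisy, a.outcome)
        z_ab = delong_test(a, b)[4]
        z_ba = delong_test(b, a)[4]
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_mismatched_admissions_error(self, rng):
        a = make_prediction_set(rng, n=50, name="a")
        b = make_prediction_set(rng, n=40, name="b")
        with pytest.raises(ValueError):
            delong_test(a, b)

    def test_variance_close_to_paired_bootstrap(self, rng):
        n = 200
        x = rng.normal(size=n)
        risk_a = expit(1.2 * x - 0.5)
        y = (rng.random(n) < risk_a).astype(int)
        risk_b = expit(0.9 * x + 0.3 * rng.normal(size=n) - 0.4)
        ids = np.array([f"A{i}" for i in range(n)])
        a = PredictionSet.from_risks("a", ids, risk_a, y)
        b = PredictionSet.from_risks("b", ids, risk_b, y)
        var = delong_test(a, b)[3]

        diffs = []
        for _ in range(10_000):
            idx = rng.integers(0, n, n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            diffs.append(roc_auc_score(yy, risk_a[idx]) - roc_auc_score(yy, risk_b[idx]))
        boot = np.var(diffs, ddof=1)
        assert abs(var - boot) / boot < 0.15


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero(self):
        # observed deaths per group arranged to equal expected exactly
        p = np.repeat([0.1, 0.2, 0.5], 20)
        y = np.concatenate([np.r_[np.ones(2), np.zeros(18)],
                            np.r_[np.ones(4), np.zeros(16)],
                            np.r_[np.ones(10), np.zeros(10)]])
        chi2, df, pval, _ = hosmer_lemeshow((y.astype(int), p), n_groups=3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_three_group_hand_example(self):
        # n_g = 100 each, mean risks 0.1/0.2/0.3, observed 12/18/33
        p = np.repeat([0.1, 0.2, 0.3], 100)
        y = np.concatenate([np.r_[np.ones(12), np.zeros(88)],
                            np.r_[np.ones(18), np.zeros(82)],
                            np.r_[np.ones(33), np.zeros(67)]]).astype(int)
        chi2, df, pval, table = hosmer_lemeshow((y, p), n_groups=3)
        hand = (12 - 10) ** 2 / (100 * 0.1 * 0.9) \
             + (18 - 20) ** 2 / (100 * 0.2 * 0.8) \
             + (33 - 30) ** 2 / (100 * 0.3 * 0.7)
        assert chi2 == pytest.approx(hand, abs=1e-12)
        assert df == 3
        assert pval == pytest.approx(stats.chi2.sf(hand, 3), abs=1e-12)

    def test_degenerate_group_errors(self):
        y = np.array([0] * 10 + [1] * 10)
        p = np.r_[np.zeros(10), np.full(10, 0.9)]
        with pytest.raises(ValueError, match="fewer groups"):
            hosmer_lemeshow((y, p), n_groups=2)

    def test_group_sizes_balanced_without_ties(self, rng):
        p = rng.random(2005)
        y = (rng.random(2005) < p).astype(int)
        table = calibration_groups((y, p), n_groups=10)
        assert table["n"].sum() == 2005
        assert table["n"].max() - table["n"].min() <= 1
        assert table["expected"].sum() == pytest.approx(p.sum())
        assert (table["mean_risk"].diff().dropna() > 0).all()


class TestCoxCalibration:
    def test_recovers_identity_on_calibrated_predictions(self):
        rng = np.random.default_rng(5)
        p = expit(rng.normal(-0.8, 1.3, 50_000))
        y = (rng.random(50_000) < p).astype(int)
        res = cox_calibration((y, p))
        assert res.intercept_ci[0] < 0.0 < res.intercept_ci[1]
        assert res.slope_ci[0] < 1.0 < res.slope_ci[1]

    def test_recovers_closed_form_distortion_inverse(self):
        # survival-log-odds' = c + d * log-odds => intercept -> -c/d, slope -> 1/d
        rng = np.random.default_rng(6)
        c, d = 0.4, 1.25
        s_lo = rng.normal(0.8, 1.3, 80_000)
        y = (rng.random(80_000) < expit(-s_lo)).astype(int)  # death prob
        p_dist = expit(-(c + d * s_lo))  # distorted death risk
        res = cox_calibration((y, p_dist))
        assert res.intercept == pytest.approx(-c / d, abs=0.03)
        assert res.slope == pytest.approx(1 / d, abs=0.03)

    def test_chi2_p_identity_for_two_df(self, preds):
        res = cox_calibration(preds)
        assert res.df == 2
        assert res.p == pytest.approx(np.exp(-res.chi2 / 2), abs=1e-12)
        assert res.chi2 >= 0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cox_calibration((np.zeros(20, int), np.full(20, 0.5)))


class TestAccuracyMeasures:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        p = np.array([1.0 - 1e-12, 1e-12, 1.0 - 1e-12, 1e-12])
        assert brier_score((y, p)) == pytest.approx(0.0, abs=1e-20)
        assert ss_r2((y, p)) == pytest.approx(1.0)
        assert shapiro_r((y, p)) == pytest.approx(1.0)

    def test_null_predictor_scores_zero(self, rng):
        y = (rng.random(500) < 0.3).astype(int)
        p = np.full(500, y.mean())
        assert ss_r2((y, p)) == pytest.approx(0.0, abs=1e-12)
        assert entropy_r2((y, p)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_vectors(self):
        y = np.array([1, 0, 1, 1, 0])
        p = np.array([0.9, 0.2, 0.6, 0.3, 0.1])
        assert brier_score((y, p)) == pytest.approx(0.142, abs=1e-12)
        pbar = 0.6
        null = (3 * (1 - pbar) ** 2 + 2 * pbar**2) / 5
        assert ss_r2((y, p)) == pytest.approx(1 - 0.142 / null, abs=1e-12)

        y4 = np.array([1, 0, 1, 0])
        p4 = np.array([0.8, 0.3, 0.5, 0.4])
        gm = (0.8 * 0.7 * 0.5 * 0.6) ** 0.25
        assert shapiro_r((y4, p4)) == pytest.approx(gm, abs=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_scaled_measures_bounded_above_by_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        y = (rng.random(n) < 0.4).astype(int)
        y[0], y[1] = 0, 1
        p = np.clip(rng.random(n), 1e-6, 1 - 1e-6)
        assert ss_r2((y, p)) <= 1.0
        assert entropy_r2((y, p)) <= 1.0


class TestWilson:
    def test_printed_interval_reproduced(self):
        lo, hi = wilson_ci(6907, 23269)
        assert round(100 * lo, 1) == 29.1
        assert round(100 * hi, 1) == 30.3

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = wilson_ci(0, 50)
        assert lo == 0.0
        assert hi > 0

    def test_matches_quadratic_root_oracle(self):
        z = stats.norm.ppf(0.975)
        for k, n in [(1, 10), (5, 17), (50, 100), (333, 1000), (6907, 23269), (0, 7), (7, 7)]:
            # roots of (1 + z^2/n) p^2 - (2 phat + z^2/n) p + phat^2 = 0
            phat = k / n
            roots = np.sort(np.roots([1 + z**2 / n, -(2 * phat + z**2 / n), phat**2]))
            lo, hi = wilson_ci(k, n)
            assert lo == pytest.approx(roots[0].real, abs=1e-10)
            assert hi == pytest.approx(roots[1].real, abs=1e-10)
            assert lo <= phat <= hi

    @given(st.integers(min_value=1, max_value=30))
    def test_width_decreases_with_n_at_fixed_rate(self, mult):
        k, n = 3, 10
        lo1, hi1 = wilson_ci(k * mult, n * mult)
        lo2, hi2 = wilson_ci(k * (mult + 1), n * (mult + 1))
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wilson_ci(1, 0)
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


class TestRoc:
    def test_passes_through_corner_for_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        pts = roc_points((y, p))
        assert ((pts["fpr"] == 0) & (pts["tpr"] == 1)).any()

    def test_trapezoid_area_equals_c_index(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 120))
            p = rng.choice(np.linspace(0.1, 0.9, 9), size=n)  # with ties
            y = (rng.random(n) < p).astype(int)
            if y.min() == y.max():
                y[0], y[1] = 0, 1
            pts = roc_points((y, p))
            area = np.trapezoid(pts["tpr"], pts["fpr"])
            assert area == pytest.approx(c_index((y, p))[0], abs=1e-12)

    def test_monotone_and_matches_reference_curve(self, preds):
        pts = roc_points(preds)
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()
        fpr, tpr, _ = roc_curve(preds.outcome, preds.predicted_risk)
        ours = set(zip(np.round(pts["fpr"], 12), np.round(pts["tpr"], 12)))
        assert all((round(f, 12), round(t, 12)) in ours for f, t in zip(fpr, tpr))


class TestValidateReport:
    def test_perfect_prediction_report(self):
        y = np.tile([1, 0], 100)
        preds = PredictionSet.from_risks("perfect", np.arange(200).astype(str),
                                         y.astype(float), y)
        rep = validate(preds)
        assert rep.c_index == 1.0
        assert rep.brier == pytest.approx(0.0, abs=1e-20)
        assert rep.hl_chi2 == pytest.approx(0.0, abs=1e-6)

    def test_calibrated_set_observed_close_to_expected(self, rng):
        preds = make_prediction_set(rng, n=20_000)
        rep = validate(preds)
        assert rep.expected_mortality_pct == pytest.approx(rep.observed_mortality_pct, abs=1.5)
        assert rep.wilson_ci_95[0] < rep.observed_mortality_pct < rep.wilson_ci_95[1]

    def test_report_round_trips_through_json(self, preds):
        rep = validate(preds)
        again = ValidationReport.from_json(rep.to_json())
        assert again == rep

    def test_oe_ratio_near_one_for_calibrated(self, rng):
        preds = make_prediction_set(rng, n=20_000)
        assert oe_ratio(preds) == pytest.approx(1.0, abs=0.05)
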