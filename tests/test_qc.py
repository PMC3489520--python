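"""QC battery: Grubbs banding, NTC, LDR, precision/accuracy/robustness/
resolution, efficiency regression, inter-method R^2, scorecard."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import telqpcr as tq
from telqpcr.curves import InvalidParameterError
from telqpcr.qc import (
    QCThresholds,
    accuracy_test,
    build_scorecard,
    check_ntc,
    determine_ldr,
    efficiency_amount_regression,
    filter_unknown_outliers,
    grubbs_classify,
    grubbs_critical_value,
    grubbs_max_g,
    intermethod_r2,
    precision_metrics,
    resolution_ttests,
    robustness_cv,
    unknown_resolution,
)


class TestGrubbs:
    def test_degenerate_inputs_keep_everything(self):
        res = grubbs_classify([10.0, 10.0, 10.0])
        assert res.degenerate and res.classes == ["keep"] * 3
        res = grubbs_classify([10.0, 11.0])
        assert res.degenerate

    def test_max_g_value_is_outlier_at_one_percent(self):
        # {10,10,10,10,14}: G for 14 hits the bound (n-1)/sqrt(n) = 1.78885,
        # above the n=5 two-sided 1% critical value 1.7637
        res = grubbs_classify([10.0, 10.0, 10.0, 10.0, 14.0])
        assert res.g[-1] == pytest.approx(4 / math.sqrt(5), abs=1e-4)
        assert res.classes[-1] == "outlier"
        assert res.classes[:4] == ["keep"] * 4

    def test_small_deviation_kept(self):
        # {1,2,3}: G_max = 1.0 < 1.1543 (n=3 at 5%)
        res = grubbs_classify([1.0, 2.0, 3.0])
        assert max(res.g) == pytest.approx(1.0)
        assert res.classes == ["keep"] * 3

    def test_max_g_bound(self):
        for n in (3, 5, 12, 30):
            assert grubbs_max_g(n) == pytest.approx((n - 1) / math.sqrt(n))
        # for n = 3 the bound (1.1547) sits a hair above the 1% critical
        # value, so triplicate outlier calls need near-coincident duplicates
        assert grubbs_critical_value(3, 0.01) < grubbs_max_g(3)

    def test_classification_matches_critical_value_oracle(self):
        # independent oracle: the t-based critical value table for n = 3..30
        rng = np.random.default_rng(12345)
        thr = QCThresholds()
        for n in range(3, 31):
            for _ in range(20):
                x = rng.normal(size=n)
                if x.std(ddof=1) == 0:
                    continue
                res = grubbs_classify(x, thr)
                g = np.abs(x - x.mean()) / x.std(ddof=1)
                imax = int(np.argmax(g))
                for i in range(n):
                    if i == imax and g[i] > grubbs_critical_value(n, 0.01):
                        expect = "outlier"
                    elif g[i] > grubbs_critical_value(n, 0.05):
                        expect = "straggler"
                    else:
                        expect = "keep"
                    assert res.classes[i] == expect, (n, i, g[i])

    def test_null_outlier_rate_at_most_1p5_percent(self):
        rng = np.random.default_rng(777)
        thr = QCThresholds()
        calls = 0
        trials = 10_000
        for _ in range(trials):
            n = int(rng.integers(3, 31))
            res = grubbs_classify(rng.normal(size=n), thr)
            calls += "outlier" in res.classes
        assert calls / trials <= 0.015

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=12),
           st.floats(-100, 100))
    def test_shift_invariance(self, values, shift):
        a = grubbs_classify(values)
        b = grubbs_classify([v + shift for v in values])
        assert a.classes == b.classes


class TestFilterUnknownOutliers:
    def test_concordant_replicates_unflagged(self):
        flags = filter_unknown_outliers(
            cq_values=[15.0, 15.1, 14.9, 15.05, 15.0, 14.95],
            ts_values=[1.0, 1.02, 0.98, 1.01, 0.99, 1.0],
            observed_ng=[20.0] * 6,
            ldr=(4.5, 72.0),
        )
        assert not flags["excluded"].any()

    def test_out_of_ldr_excluded(self):
        flags = filter_unknown_outliers(
            cq_values=[15.0, 15.1, 14.9],
            ts_values=[1.0, 1.02, 0.98],
            observed_ng=[20.0, 2.0, 20.0],
            ldr=(4.5, 72.0),
        )
        assert list(flags["excluded"]) == [False, True, False]

    def test_injected_shift_among_ten_replicates_flagged_alone(self):
        # one +6-cycle well in a 10-replicate pooled set
        rng = np.random.default_rng(5)
        cq = list(15.0 + rng.normal(0, 0.12, 9)) + [21.0]
        ts = list(np.exp(rng.normal(0, 0.1, 9))) + [1.0 / 64.0]
        ng = [20.0] * 9 + [20.0 / 64.0]
        flags = filter_unknown_outliers(cq, ts, ng, (4.5, 72.0))
        assert flags["excluded"].iloc[-1]
        assert not flags["excluded"].iloc[:-1].any()

    def test_missing_ldr_is_error(self):
        with pytest.raises(InvalidParameterError):
            filter_unknown_outliers([15.0] * 3, [1.0] * 3, [20.0] * 3, None)


class TestCheckNtc:
    # Cq values as printed for the four assays (telomere / reference):
    # most-diluted-standard Cq vs NTC Cq
    @pytest.mark.parametrize("ntc,std,dimer,dcq,verdict", [
        (34.9, 17.6, False, 17.3, "ok"),           # singleplex telomere
        (27.2, 13.9, False, 13.3, "ok"),           # multiplex telomere
        (19.4, 15.7, False, 3.7, "borderline"),
        (15.5, 14.1, False, 1.4, "borderline"),
        (27.9, 39.9, False, -12.0, "overlap"),
        (27.9, 39.9, True, -12.0, "dimer-explained"),
        (31.1, 34.3, True, -3.2, "dimer-explained"),
        (36.2, 37.4, False, -1.2, "overlap"),
    ])
    def test_printed_classifications(self, ntc, std, dimer, dcq, verdict):
        got_dcq, got = check_ntc([ntc], [std], dimer)
        assert got_dcq == pytest.approx(dcq, abs=1e-9)
        assert got == verdict

    def test_silent_ntc_is_ok(self):
        dcq, verdict = check_ntc([math.nan, math.nan], [17.6])
        assert math.isinf(dcq) and verdict == "ok"


class TestLdr:
    def _steps(self, amounts, cqs):
        return pd.DataFrame({"amount_ng": amounts, "y": cqs})

    def test_perfectly_linear_full_range(self):
        amounts = [4.5, 9.0, 18.0, 36.0, 72.0]
        cqs = [20.0 - math.log2(a / 4.5) for a in amounts]
        ldr, resid = determine_ldr(self._steps(amounts, cqs))
        assert ldr == (4.5, 72.0)
        assert resid.abs().max() <= 1e-9

    def test_decaying_top_step_excluded(self):
        # efficiency loss at high template bends the top step by > 0.5 Cq
        amounts = [4.5, 9.0, 18.0, 36.0, 72.0]
        cqs = [20.0 - math.log2(a / 4.5) for a in amounts]
        cqs[-1] += 1.2
        ldr, _ = determine_ldr(self._steps(amounts, cqs))
        assert ldr == (4.5, 36.0)

    def test_two_steps_rejected(self):
        with pytest.raises(InvalidParameterError):
            determine_ldr(self._steps([4.5, 9.0], [20.0, 19.0]))

    def test_no_qualifying_run_returns_none(self):
        rng = np.random.default_rng(1)
        amounts = [4.5, 9.0, 18.0, 36.0, 72.0]
        cqs = list(rng.normal(20, 3, 5))
        ldr, _ = determine_ldr(self._steps(amounts, cqs))
        assert ldr is None


class TestPrecisionAccuracy:
    def test_identical_triplicates_zero_sd(self):
        sd, r2 = precision_metrics([[15.0] * 3, [16.0] * 3],
                                   [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert sd == 0.0 and r2 == pytest.approx(1.0)

    def test_noisy_cq_sd_recovered(self):
        rng = np.random.default_rng(3)
        trips = [15.0 + rng.normal(0, 0.12, 3) for _ in range(50)]
        sd, _ = precision_metrics(trips, [1, 2, 3], [1, 2, 3])
        assert sd == pytest.approx(0.12, abs=0.03)

    def test_accuracy_exact_slope_one(self):
        exp = np.array([0.5, 1.0, 1.5, 2.0])
        slope, se, t, p = accuracy_test(exp, exp)
        assert slope == 1.0 and t == 0.0 and p == 1.0

    def test_accuracy_multiplicative_bias_detected(self):
        exp = np.linspace(0.5, 2.0, 20)
        slope, _, t, p = accuracy_test(1.06 * exp, exp)
        assert slope == pytest.approx(1.06, abs=1e-9)
        assert p < 1e-6

    def test_accuracy_power_under_noise(self):
        # slope 1.05 with sigma 0.02 log units: detected in most replicates
        rng = np.random.default_rng(8)
        exp = np.tile(np.linspace(0.65, 1.86, 5), 4)  # 5 steps x 4 batches
        hits = 0
        trials = 200
        for _ in range(trials):
            obs = 1.05 * exp + rng.normal(0, 0.02, exp.size)
            slope, _, _, p = accuracy_test(obs, exp)
            hits += p < 0.05
        assert hits / trials >= 0.8


class TestRobustnessResolution:
    def test_robustness_hand_value(self):
        per_step, avg = robustness_cv({18.0: [1.0, 1.1]})
        assert per_step[18.0] == pytest.approx(6.7344, abs=1e-3)
        assert avg == pytest.approx(per_step[18.0])

    def test_robustness_identical_batches_zero(self):
        per_step, avg = robustness_cv({18.0: [1.0, 1.0], 36.0: [1.3, 1.3]})
        assert avg == 0.0

    def test_robustness_single_batch_rejected(self):
        with pytest.raises(InvalidParameterError):
            robustness_cv({18.0: [1.0]})

    def test_resolution_conventions_and_oracle(self):
        assert resolution_ttests([[1.0, 1.0], [1.0, 1.0]]) == [1.0]
        assert resolution_ttests([[1.0, 1.0], [2.0, 2.0]]) == [0.0]
        ps = resolution_ttests([[1.00, 1.01, 0.99], [0.70, 0.71, 0.69]])
        assert ps[0] < 1e-3
        # pooled-variance default matches the scipy oracle
        a, b = [1.0, 1.2, 0.9, 1.1], [0.8, 0.75, 0.95, 0.7]
        assert resolution_ttests([a, b])[0] == pytest.approx(
            stats.ttest_ind(a, b).pvalue
        )

    def test_resolution_power_tracks_precision(self):
        # a 2-fold step is resolved more often at Cq SD 0.12 than at 0.33
        rng = np.random.default_rng(17)
        rates = {}
        for sd in (0.12, 0.33):
            hits = 0
            for _ in range(200):
                lo = rng.normal(1.0, sd / 3.32, 4)  # per-batch mean log amounts
                hi = rng.normal(1.0 + math.log10(2), sd / 3.32, 4)
                hits += resolution_ttests([list(hi), list(lo)])[0] < 0.05
            rates[sd] = hits / 200
        assert rates[0.12] > rates[0.33]

    def test_unknown_resolution_arithmetic(self):
        dmm, avg_sd, ratio = unknown_resolution([1.0, 2.0], [0.1, 0.1])
        assert (dmm, avg_sd, ratio) == (1.0, pytest.approx(0.1), 10.0)
        dmm, _, ratio = unknown_resolution([1.0, 1.0], [0.1, 0.1])
        assert dmm == 0.0 and math.isnan(ratio)


class TestEfficiencyRegressionAndIntermethod:
    def test_constant_e_no_slope(self):
        slope, _, r2, p = efficiency_amount_regression(
            [1.9] * 3 + [1.9001] * 3,
            [0.65, 1.0, 1.5, 0.65, 1.0, 1.5],
        )
        assert abs(slope) < 1e-3

    def test_linear_e_perfect_fit(self):
        x = np.array([0.65, 1.0, 1.26, 1.56, 1.86])
        slope, _, r2, p = efficiency_amount_regression(2.0 - 0.1 * x, x)
        assert slope == pytest.approx(-0.1, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_intermethod_affine_invariance(self):
        s = pd.Series([1.0, 1.5, 2.0, 0.7], index=list("abcd"))
        mat = intermethod_r2({"m1": s, "m2": 3.0 * s + 1.0})
        assert mat.loc["m1", "m2"] == pytest.approx(100.0)

    def test_intermethod_needs_three_common(self):
        a = pd.Series([1.0, 2.0], index=list("ab"))
        mat = intermethod_r2({"m1": a, "m2": a})
        assert math.isnan(mat.loc["m1", "m2"])


class TestScorecard:
    def _metrics(self):
        target = dict(
            ldr_step_fraction=1.0, ntc_dcq=15.0, ntc_verdict="ok",
            e_mean=1.95, e_interbatch_sd=0.01, dilution_e_p=0.7,
            cq_sd=0.12, accuracy_slope=1.0, accuracy_p=0.8,
            precision_r2=0.995, resolution_sig_fraction=1.0,
        )
        return {
            "telomere": dict(target),
            "reference": dict(target),
            "ts": dict(cv_mean=9.0, standards_max_dev=0.05,
                       outlier_fraction=0.02, sd_dminmax_pct=6.0,
                       intermethod_min_r2=95.0),
        }

    def test_all_best_bands(self):
        card = build_scorecard(self._metrics())
        assert card.overall == "best"

    def test_unexplained_ntc_overlap_is_worst(self):
        m = self._metrics()
        m["reference"]["ntc_verdict"] = "overlap"
        assert build_scorecard(m).overall == "worst"

    def test_dimer_explained_overlap_not_counted(self):
        m = self._metrics()
        m["reference"]["ntc_verdict"] = "dimer-explained"
        assert build_scorecard(m).overall == "best"

    def test_purity_identical_inputs_identical_verdicts(self):
        a = build_scorecard(self._metrics())
        b = build_scorecard(self._metrics())
        assert a.rows.equals(b.rows) and a.overall == b.overall

    def test_empty_metrics_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_scorecard({})

    def test_scale_consistency_constant_cq_shift(self):
        # adding a constant to all Cq values leaves SD-based metrics, Grubbs
        # classes and resolution p-values unchanged
        rng = np.random.default_rng(9)
        cqs = rng.normal(15.0, 0.2, 12)
        assert (grubbs_classify(cqs).classes
                == grubbs_classify(cqs + 7.0).classes)
        trips = [cqs[i:i + 3] for i in range(0, 12, 3)]
        sd1, _ = precision_metrics(trips, [1, 2, 3], [1, 2, 3])
        sd2, _ = precision_metrics([t + 7.0 for t in trips],
                                   [1, 2, 3], [1, 2, 3])
        assert sd1 == pytest.approx(sd2)
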