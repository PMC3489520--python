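"""Amplification-curve processing: baseline, window, efficiency, Cq, N0."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import telqpcr as tq
from telqpcr.curves import (
    InvalidParameterError,
    ProcessedTrace,
    WindowFit,
    correct_baseline,
    detect_melt_peaks,
    determine_cq,
    estimate_n0,
    find_window_of_linearity,
    fit_reaction_efficiency,
    mean_batch_efficiency,
)
from telqpcr.simulate import simulate_melt_curve

from conftest import pure_exponential_trace


def exactly_corrected(tr: tq.FluorescenceTrace, baseline: float) -> ProcessedTrace:
    """A ProcessedTrace with the true constant subtracted exactly."""
    return ProcessedTrace(trace=tr, baseline=baseline,
                          corrected=tr.readings - baseline, noise=0.0,
                          usable=True, mode="strict")


class TestCorrectBaseline:
    def test_strict_recovers_constructed_constant(self):
        # F(c) = 5 + 0.001 * 2^c: the exact constant restores log-linearity
        tr = pure_exponential_trace(n0=0.001, baseline=5.0)
        pt = correct_baseline(tr, "strict")
        assert pt.usable
        assert pt.baseline == pytest.approx(5.0, abs=0.01)
        fit = fit_reaction_efficiency(pt, (5, 12))
        assert fit.r2 >= 0.99999

    def test_flat_trace_unusable_with_min_baseline(self):
        readings = np.full(40, 7.5)
        tr = tq.FluorescenceTrace("B1", "W1", "ntc", "telomere", "ntc", 1,
                                  None, readings)
        pt = correct_baseline(tr, "strict")
        assert not pt.usable
        assert pt.baseline == pytest.approx(7.5)

    def test_min_mode_subtracts_minimum(self):
        tr = pure_exponential_trace(n0=0.001, baseline=5.0)
        pt = correct_baseline(tr, "min")
        assert pt.baseline == pytest.approx(float(tr.readings.min()))

    def test_noisy_recovery_within_three_sd(self):
        # 100 seeded wells at noise 0.5% of plateau with a fixed true
        # baseline (baseline_sd = 0): mean recovery error within 3 noise SD
        cfg = tq.SimulationConfig(seed=21, batches=1, n_unknowns=34,
                                  noise_sd=0.5, baseline_sd=0.0)
        sim = tq.simulate_plate(cfg)
        unk = [t for t in sim.traces if t.role == "unknown"][:100]
        assert len(unk) == 100
        recovered = [correct_baseline(tr, "strict").baseline for tr in unk]
        assert abs(np.mean(recovered) - cfg.baseline_level) <= 3 * cfg.noise_sd

    def test_unknown_mode_rejected(self):
        tr = pure_exponential_trace()
        with pytest.raises(InvalidParameterError):
            correct_baseline(tr, "weird")


class TestWindowOfLinearity:
    def test_pure_exponential_window_is_exact(self):
        pts = [correct_baseline(pure_exponential_trace(n0=n0), "strict")
               for n0 in (1e-4, 5e-5, 2.5e-5)]
        fits = find_window_of_linearity(pts)
        for f in fits:
            assert f is not None
            assert f.r2 == pytest.approx(1.0, abs=1e-9)
            assert f.end - f.start + 1 == 5

    def test_window_excludes_plateau(self):
        cfg = tq.SimulationConfig(seed=2, noise_sd=0.0, baseline_sd=0.0,
                                  cq_sd=0.0, cq_shared_sd=0.0)
        tr = tq.simulate_trace(1e-3, cfg)
        pt = correct_baseline(tr, "strict")
        (fit,) = find_window_of_linearity([pt])
        g = pt.corrected
        ninety = np.flatnonzero(
            np.nan_to_num(g, nan=-np.inf) >= 0.9 * np.nanmax(g)
        )[0] + 1
        assert fit.end < ninety

    def test_aberrant_trace_gets_individual_window(self):
        # twelve concordant logistic traces plus one amplifying 8 cycles
        # early: the group window lands in the early trace's plateau, so it
        # alone needs an individual window
        cfg = tq.SimulationConfig(noise_sd=0.0, baseline_sd=0.0, cq_sd=0.0,
                                  cq_shared_sd=0.0)
        normal = [tq.simulate_trace(1e-5 * cfg.plateau, cfg, well=f"W{i}")
                  for i in range(12)]
        early = tq.simulate_trace(1e-5 * cfg.plateau * 2**8, cfg, well="W12")
        pts = [correct_baseline(t, "strict") for t in normal + [early]]
        fits = find_window_of_linearity(pts)
        assert not any(f.individual for f in fits[:12])
        assert fits[12] is None or fits[12].individual
        if fits[12] is not None:
            assert fits[12].end < fits[0].start

    def test_unusable_traces_skipped(self):
        flat = tq.FluorescenceTrace("B1", "W1", "ntc", "telomere", "ntc", 1,
                                    None, np.full(40, 3.0))
        pts = [correct_baseline(flat, "strict")]
        assert find_window_of_linearity(pts) == [None]


class TestEfficiencyAndCq:
    @pytest.mark.parametrize("e_true", [2.0, 1.787])
    def test_noiseless_efficiency_exact(self, e_true):
        tr = pure_exponential_trace(n0=1e-4, efficiency=e_true)
        fit = fit_reaction_efficiency(exactly_corrected(tr, 5.0), (5, 12))
        assert fit.efficiency == pytest.approx(e_true, abs=1e-6)

    def test_noisy_mean_efficiency_within_three_percent(self):
        # 100 seeded unknown wells, noise 1% of plateau, true E 1.9
        cfg = tq.SimulationConfig(seed=31, batches=1, n_unknowns=34,
                                  true_E_telomere=1.9, cq_sd=0.0,
                                  cq_shared_sd=0.0)
        sim = tq.simulate_plate(cfg)
        res = tq.TelomereAssay.from_simulation(sim).fit()
        f = res.fits
        unk = f[(f.baseline_mode == "strict") & (f.role == "unknown")
                & (f.target == "telomere") & f.usable]
        assert len(unk) >= 100
        assert abs(unk["e"].head(100).mean() - 1.9) / 1.9 <= 0.03

    def test_cq_closed_form(self):
        # F_corr = 1e-4 * 2^c, Nt = 0.1 -> Cq = log2(1000) = 9.9658
        tr = pure_exponential_trace(n0=1e-4, baseline=5.0)
        pt = exactly_corrected(tr, 5.0)
        fit = fit_reaction_efficiency(pt, (5, 12))
        cq = determine_cq(pt, fit, 0.1)
        assert cq == pytest.approx(math.log2(1000), abs=1e-6)

    def test_doubling_n0_shifts_cq_by_one(self):
        cqs = []
        for n0 in (1e-4, 2e-4):
            pt = exactly_corrected(pure_exponential_trace(n0=n0), 5.0)
            fit = fit_reaction_efficiency(pt, (5, 12))
            cqs.append(determine_cq(pt, fit, 0.1))
        assert cqs[0] - cqs[1] == pytest.approx(1.0, abs=1e-6)

    def test_threshold_above_trace_maximum_undefined(self):
        pt = correct_baseline(pure_exponential_trace(n0=1e-4, cycles=20),
                              "strict")
        fit = fit_reaction_efficiency(pt, (5, 12))
        assert math.isnan(determine_cq(pt, fit, 1e9))

    def test_window_without_enough_points_rejected(self):
        pt = correct_baseline(pure_exponential_trace(), "strict")
        with pytest.raises(InvalidParameterError):
            fit_reaction_efficiency(pt, (38, 40))


class TestEstimateN0:
    def test_direct_arithmetic(self):
        assert estimate_n0(10.0, 2.0, 0.2) == pytest.approx(1.953125e-4)

    def test_zero_cq_identity(self):
        assert estimate_n0(0.0, 2.0, 0.2) == pytest.approx(0.2)

    def test_invalid_efficiency(self):
        with pytest.raises(InvalidParameterError):
            estimate_n0(10.0, 1.0, 0.2)

    def test_round_trip_through_pipeline(self, exact_sim, exact_results):
        fits = exact_results.fits
        sub = fits[(fits.baseline_mode == "strict") & fits.usable]
        merged = sub.merge(
            exact_sim.truth.wells[["batch", "well", "true_n0"]],
            on=["batch", "well"],
        ).dropna(subset=["n0"])
        rel = (merged["n0"] / merged["true_n0"] - 1.0).abs()
        assert rel.max() <= 1e-3

    @given(st.floats(0.5, 35.0), st.floats(1.2, 2.05), st.floats(0.01, 10.0))
    def test_inverts_exponential(self, cq, e, nt):
        n0 = estimate_n0(cq, e, nt)
        assert n0 * e**cq == pytest.approx(nt, rel=1e-9)


class TestMeanBatchEfficiency:
    def test_iterative_trim_drops_deviator(self):
        mean, included, ok = mean_batch_efficiency([2.00, 2.02, 1.98, 2.50])
        assert ok
        assert mean == pytest.approx(2.0, abs=1e-12)
        assert list(included) == [True, True, True, False]

    def test_no_trim_when_tight(self):
        mean, included, ok = mean_batch_efficiency([2.0, 2.0, 2.0])
        assert ok and mean == 2.0 and included.all()

    def test_too_few_survivors_flagged(self):
        mean, _, ok = mean_batch_efficiency([1.0, 3.0])
        assert not ok and math.isnan(mean)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            mean_batch_efficiency([2.0])


class TestMeltPeaks:
    def test_no_dimer_for_matching_peak(self):
        mc = simulate_melt_curve([(80.0, 1.0)])
        peaks, dimer = detect_melt_peaks(mc, 80.0)
        assert peaks and not dimer

    def test_dimer_flag_for_distant_peak(self):
        mc = simulate_melt_curve([(87.0, 0.4)])
        _, dimer = detect_melt_peaks(mc, 80.0)
        assert dimer

    def test_flat_curve_no_peaks(self):
        rng = np.random.default_rng(0)
        t = np.arange(72.0, 95.5, 0.5)
        mc = tq.MeltCurve("B1", "W1", t, rng.normal(0, 0.002, t.size))
        peaks, dimer = detect_melt_peaks(mc, 80.0)
        assert peaks == [] and not dimer

    def test_non_monotone_temperatures_rejected(self):
        t = np.array([72.0, 73.0, 72.5] + list(np.arange(74, 90.0, 0.5)))
        with pytest.raises(InvalidParameterError):
            tq.MeltCurve("B1", "W1", t, np.zeros(t.size))


class TestFitTrace:
    def test_single_trace_pipeline(self):
        tr = pure_exponential_trace(n0=1e-4, efficiency=2.0, baseline=5.0)
        fit = tq.fit_trace(tr, nt=0.1)
        assert fit.usable
        assert fit.efficiency == pytest.approx(2.0, abs=1e-6)
        assert fit.cq == pytest.approx(math.log2(1000), abs=1e-6)
        assert fit.n0 == pytest.approx(1e-4, rel=1e-6)
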