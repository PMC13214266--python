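"""Off-rate correction, cumulative-release curves, RRP/refill estimation."""

import numpy as np
import pytest

from optoquant.pool import (CumulativeReleaseCurve, PulseResponseSeries,
                            analyze_pool_trace, correct_off_rate,
                            cumulative_curve, fit_rrp_refill,
                            make_template_bank, noise_floor, to_vesicles)
from optoquant.simulate import (HotspotSpec, impulse_response, render_trace,
                                simulate_release_train)


def forward_trace(r, stim_times, frame_times, tau_off, tau_rise=0.0):
    trace = np.zeros_like(frame_times)
    for ri, ts in zip(r, stim_times):
        trace += ri * impulse_response(frame_times - ts, tau_off, tau_rise)
    return trace


class TestCorrectOffRate:
    def test_single_pulse_recovers_peak(self):
        t = np.arange(200) / 10.0
        stim = np.array([3.0])
        trace = 0.7 * impulse_response(t - 3.0, 8.96)
        series = correct_off_rate(trace, t, stim, 8.96)
        assert series.amplitudes[0] == pytest.approx(0.7, abs=1e-9)

    def test_noiseless_roundtrip_machine_precision(self, rng):
        """Forward-render 50 pulses at 16 Hz through the sensor kernel, then
        invert: amplitudes come back to machine precision (sampling fast
        enough to resolve the pulses)."""
        stim = 1.0 + np.arange(50) / 16.0
        t = np.arange(int(64 * 40)) / 64.0
        r_true = rng.uniform(0.0, 1.0, 50)
        trace = forward_trace(r_true, stim, t, tau_off=8.96)
        series = correct_off_rate(trace, t, stim, 8.96)
        assert np.abs(series.amplitudes - r_true).max() < 1e-6

    def test_fast_sensor_limit_equals_raw_peaks(self):
        """As tau_off shrinks well below the inter-stimulus interval the
        corrected amplitudes equal the per-stimulus peaks of the raw trace."""
        stim = np.arange(10.0) + 2.0
        t = np.arange(240) / 20.0
        tau = 0.05
        r_true = np.linspace(0.2, 1.1, 10)
        trace = forward_trace(r_true, stim, t, tau_off=tau)
        series = correct_off_rate(trace, t, stim, tau)
        peaks = [trace[(t >= s) & (t < s + 1.0)].max() for s in stim]
        assert np.allclose(series.amplitudes, peaks, atol=1e-9)

    def test_warns_when_tau_off_below_frame_interval(self):
        t = np.arange(100) / 10.0
        with pytest.warns(RuntimeWarning, match="ill-conditioned"):
            make_template_bank(t, np.array([1.0]), tau_off=0.05)

    def test_singular_bank_rejected(self):
        t = np.arange(50) / 10.0
        with pytest.raises(ValueError, match="beyond the trace"):
            make_template_bank(t, np.array([60.0]), tau_off=1.0)
        with pytest.raises(ValueError, match="tau_off"):
            make_template_bank(t, np.array([1.0]), tau_off=-1.0)

    def test_conservation_of_total_release(self, rng):
        """Total corrected release matches the ground-truth total within 2%
        at high SNR."""
        stim = 1.0 + np.arange(160) / 16.0
        t = np.arange(600) / 10.0
        spec = HotspotSpec((0, 0), 0.7, 0.5, 0.9, (0.7, 0.3), rrp=30,
                           refill_rate=0.05)
        ev = simulate_release_train(spec, stim, seed=5)
        trace = render_trace(ev, t, 8.96, 0.0)
        peak = trace.max()
        trace_n = trace + rng.normal(0, peak / 20.0, t.size)  # SNR 20
        series = correct_off_rate(trace_n, t, stim, 8.96)
        total_true = ev["amplitude"].sum()
        assert series.amplitudes.sum() == pytest.approx(total_true, rel=0.02)


class TestCumulativeCurve:
    def test_running_sum(self):
        s = PulseResponseSeries(np.array([1.0, 1.0, 1.0]), np.arange(3.0),
                                8.96, 0)
        curve = cumulative_curve(s)
        assert np.allclose(curve.cumulative, [1, 2, 3])
        assert curve.late_window == (2, 3)

    def test_monotone_nondecreasing(self, rng):
        s = PulseResponseSeries(rng.uniform(0, 1, 100), np.arange(100.0),
                                8.96, 0)
        assert (np.diff(cumulative_curve(s).cumulative) >= 0).all()

    def test_depletion_curve_concave_then_linear(self):
        spec = HotspotSpec((0, 0), 0.7, 1.0, 0.9, (1.0,), rrp=30,
                           refill_rate=0.05)
        ev = simulate_release_train(spec, np.arange(600.0), seed=2)
        s = PulseResponseSeries(ev["amplitude"].to_numpy(),
                                np.arange(600.0), 8.96, 0)
        curve = cumulative_curve(s)
        early_slope = curve.cumulative[59] / 60.0
        lo, hi = curve.late_window
        late_slope = (curve.cumulative[hi - 1] - curve.cumulative[lo]) / (hi - lo)
        assert early_slope > 3 * late_slope


class TestFitRrpRefill:
    def test_exact_line(self):
        n = np.arange(1, 301)
        curve = CumulativeReleaseCurve(5.0 + 0.02 * n, n, (200, 300))
        est = fit_rrp_refill(curve)
        assert est.rrp_dff == pytest.approx(5.0, abs=1e-9)
        assert est.refill_per_stim_dff == pytest.approx(0.02, abs=1e-12)
        assert est.r2 > 0.999999

    def test_zero_refill_simulation(self):
        spec = HotspotSpec((0, 0), 0.7, 1.0, 1.0, (1.0,), rrp=8,
                           refill_rate=0.0)
        ev = simulate_release_train(spec, np.arange(400.0), seed=0)
        s = PulseResponseSeries(ev["amplitude"].to_numpy(), np.arange(400.0),
                                8.96, 0)
        est = fit_rrp_refill(cumulative_curve(s))
        assert est.refill_per_stim_dff == pytest.approx(0.0, abs=1e-9)
        assert est.rrp_dff == pytest.approx(ev["amplitude"].sum(), rel=1e-6)

    def test_negative_intercept_flagged_not_hidden(self):
        n = np.arange(1, 301)
        curve = CumulativeReleaseCurve(-2.0 + 0.01 * n, n, (150, 300))
        est = fit_rrp_refill(curve)
        assert "rrp_not_resolvable" in est.flags
        assert est.rrp_dff < 0

    def test_short_late_window_flagged(self):
        n = np.arange(1, 31)
        curve = CumulativeReleaseCurve(1.0 + 0.1 * n, n, (20, 30))
        assert "short_late_window" in fit_rrp_refill(curve).flags


class TestToVesicles:
    def test_division_examples(self):
        est = fit_rrp_refill(CumulativeReleaseCurve(
            8.0 + 0.0088 * np.arange(1, 301), np.arange(1, 301), (200, 300)))
        out = to_vesicles(est, 0.4)
        assert out.rrp_vesicles == pytest.approx(20.0)
        assert out.refill_per_1000 == pytest.approx(22.0)
        halved = to_vesicles(est, 0.8)
        assert halved.rrp_vesicles == pytest.approx(10.0)
        assert halved.refill_per_1000 == pytest.approx(11.0)

    def test_invalid_q(self):
        est = fit_rrp_refill(CumulativeReleaseCurve(
            1.0 + 0.01 * np.arange(1, 301), np.arange(1, 301), (200, 300)))
        with pytest.raises(ValueError):
            to_vesicles(est, 0.0)


class TestEndToEnd:
    def test_forward_recovery_single_site(self):
        """Full chain on noiseless single-site depletion trains: intercept
        within 15% of the pool, slope within 20% of the refill rate."""
        q = 0.4
        stim = 2.0 + np.arange(1920) / 16.0
        t = np.arange(int(150 * 10)) / 10.0
        bank = make_template_bank(t, stim, 8.96)
        rrps, refills = [], []
        for seed in range(20):
            spec = HotspotSpec((0, 0), 0.7, q, 0.8, (0.75, 0.2, 0.05),
                               rrp=20, refill_rate=0.022)
            ev = simulate_release_train(spec, stim, seed=seed)
            trace = render_trace(ev, t, 8.96, 0.0)
            est = analyze_pool_trace(trace, t, stim, 8.96, q=q, bank=bank)
            rrps.append(est.rrp_vesicles)
            refills.append(est.refill_per_1000)
        assert np.mean(rrps) == pytest.approx(20.0, rel=0.15)
        assert np.mean(refills) == pytest.approx(22.0, rel=0.20)

    def test_refill_regime_discrimination(self):
        """Trains with 10x different refill rates yield non-overlapping
        late-phase slope confidence intervals."""
        q = 1.0
        stim = 2.0 + np.arange(1920) / 16.0
        t = np.arange(1500) / 10.0
        bank = make_template_bank(t, stim, 3.15)
        cis = []
        for rate in (18.6e-3, 1.12e-3):
            spec = HotspotSpec((0, 0), 0.7, q, 1.0, (1.0,), rrp=30,
                               refill_rate=rate)
            ev = simulate_release_train(spec, stim, seed=3)
            trace = render_trace(ev, t, 3.15, 0.0)
            series = correct_off_rate(trace, t, stim, 3.15, bank=bank)
            est = fit_rrp_refill(cumulative_curve(series))
            cis.append(est.refill_ci)
        assert cis[0][0] > cis[1][1]   # PVN-like lower bound above VTA-like upper

    def test_lower_refill_means_stronger_rundown(self):
        """Across a refill ladder, late-train release rises with refill rate
        (rank correlation), i.e. low-refill synapses run down."""
        from scipy.stats import spearmanr
        rates = [0.001, 0.005, 0.02, 0.08]
        late = []
        for rate in rates:
            spec = HotspotSpec((0, 0), 0.7, 1.0, 0.9, (1.0,), rrp=20,
                               refill_rate=rate)
            ev = simulate_release_train(spec, np.arange(1500.0), seed=7)
            late.append(ev["quanta"].to_numpy()[1000:].mean())
        rho = spearmanr(rates, late).statistic
        assert rho == pytest.approx(1.0)

    def test_noise_floor_positive_and_scales(self, rng):
        t = np.arange(800) / 10.0
        stim = 2.0 + np.arange(400) / 16.0
        bank = make_template_bank(t, stim, 3.15)
        f1 = noise_floor(bank, 0.1, seed=1)
        f2 = noise_floor(bank, 0.2, seed=1)
        assert f2[1] > f1[1] > 0.0
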