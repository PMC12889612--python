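"""Leaky-integrator fitting, pulse endpoints, leakiness and pulse areas."""

import math

import numpy as np
import pytest

from swimstate.errors import FormatError, InvalidArgumentError
from swimstate.integration import (estimate_pulse_template,
                                   fit_leaky_integrator, inverse_leakiness,
                                   pulse_endpoints, pulse_integration_auc,
                                   pulse_response_auc)
from swimstate.synthetic import leaky_integrate

#: closed-form geometric-recursion value of the inverse leakiness for a
#: tau = 5 s integrator under 1 s ON / 1 s OFF unit square pulses, endpoints
#: at the interval boundaries (frozen from a 6-iteration hand recursion)
INV_LEAK_TAU5 = 0.49731820308681285


def pulse_train(n, fs, period=2.0, on=1.0, amp=1.0, t0=0.0):
    t = np.arange(n) / fs
    return np.where((t >= t0) & (((t - t0) % period) < on), amp, 0.0)


def boundary_frames(n_periods, period=2.0, per_half=2):
    """Frame grid whose last frame in each half-period sits at the boundary."""
    step = period / (2 * per_half)
    t = np.arange(1, int(n_periods * 2 * per_half) + 1) * step - 1e-9
    return t


def exact_integrator_trace(frame_t, tau, period=2.0, on=1.0, amp=1.0):
    """Continuous-time leaky integral of the square-pulse train at frame_t."""
    out = np.empty(frame_t.size)
    for i, t in enumerate(frame_t):
        k = int(t // period)
        # level at the start of period k via the boundary recursion
        a = 0.0
        r_on = math.exp(-on / tau)
        r_off = math.exp(-(period - on) / tau)
        for _ in range(k):
            a = (a * r_on + amp * tau * (1 - r_on)) * r_off
        rel = t - k * period
        if rel < on:
            out[i] = a * math.exp(-rel / tau) + amp * tau * (
                1 - math.exp(-rel / tau))
        else:
            a_on = a * r_on + amp * tau * (1 - r_on)
            out[i] = a_on * math.exp(-(rel - on) / tau)
    return out


class TestFitLeakyIntegrator:
    @pytest.mark.parametrize("tau", [2.0, 5.0, 10.0, 20.0])
    def test_noiseless_recovery_within_5pct(self, tau):
        fs = 3.0
        v = pulse_train(int(40 * fs), fs)
        trace = leaky_integrate(v, tau, 1 / fs)
        fit = fit_leaky_integrator(trace, v, fs)
        assert fit.converged
        assert fit.tau == pytest.approx(tau, rel=0.05)
        assert fit.beta == pytest.approx(1.0, rel=0.05)

    def test_scale_equivariance(self):
        fs = 3.0
        v = pulse_train(int(30 * fs), fs)
        trace = leaky_integrate(v, 7.0, 1 / fs)
        f1 = fit_leaky_integrator(trace, v, fs)
        f2 = fit_leaky_integrator(3.5 * trace, v, fs)
        assert f2.tau == pytest.approx(f1.tau, rel=1e-6)
        assert f2.beta == pytest.approx(3.5 * f1.beta, rel=1e-6)

    def test_perfect_integrator_hits_grid_upper_bound(self):
        fs = 3.0
        v = pulse_train(int(30 * fs), fs)
        trace = np.cumsum(v) / fs  # tau -> infinity limit: running integral
        fit = fit_leaky_integrator(trace, v, fs)
        assert fit.tau > 80.0
        # prediction is a near-monotone staircase: inter-pulse leak at the
        # grid's upper bound is a small fraction of the per-pulse rise
        pred = fit.beta * leaky_integrate(v, fit.tau, 1 / fs)
        rises = np.diff(pred)
        assert rises.min() > -0.02 * pred.max()
        assert pred[-1] == pytest.approx(pred.max(), rel=0.02)

    def test_all_zero_trace_sentinel(self):
        fit = fit_leaky_integrator(np.zeros(60), pulse_train(60, 3.0), 3.0)
        assert fit.beta == 0.0 and math.isnan(fit.tau) and not fit.converged

    def test_noisy_recovery_median_error(self):
        # median relative error <= 15% at ΔF/F noise 0.05 across 50 seeds
        fs, tau = 3.0, 8.0
        v = pulse_train(int(40 * fs), fs)
        clean = leaky_integrate(v, tau, 1 / fs)
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            trace = clean / tau + rng.normal(0, 0.05, clean.size)
            fit = fit_leaky_integrator(trace, v, fs)
            errs.append(abs(fit.tau - tau) / tau)
        assert np.median(errs) <= 0.15


class TestPulseEndpoints:
    def test_staircase_endpoints(self):
        frame_t = boundary_frames(7)
        onsets = [2 * k for k in range(6)]
        # one unit step per pulse, held through the OFF period
        trace = np.array([math.floor(t / 2) + (1 if (t % 2) >= 1 - 1e-8
                                               else 0) for t in frame_t],
                         dtype=float)
        on, off = pulse_endpoints(trace, frame_t, onsets)
        np.testing.assert_allclose(on, np.arange(1, 7))
        np.testing.assert_allclose(off[1:], np.arange(1, 7))
        assert off[0] == 0.0

    def test_transient_endpoints(self):
        frame_t = boundary_frames(7)
        trace = np.where((frame_t % 2) < 1, 1.0, 0.0)
        on, off = pulse_endpoints(trace, frame_t, [2 * k for k in range(6)])
        np.testing.assert_allclose(on, 1.0)
        np.testing.assert_allclose(off, 0.0)

    def test_matches_geometric_recursion_oracle(self):
        tau = 5.0
        frame_t = boundary_frames(7)
        trace = exact_integrator_trace(frame_t, tau)
        on, off = pulse_endpoints(trace, frame_t, [2 * k for k in range(6)])
        r = math.exp(-1.0 / tau)
        a, exp_on, exp_off = 0.0, [], [0.0]
        for _ in range(6):
            a = a * r + tau * (1 - r)
            exp_on.append(a)
            a = a * r
            exp_off.append(a)
        np.testing.assert_allclose(on, exp_on, atol=1e-6)
        np.testing.assert_allclose(off, exp_off, atol=1e-6)

    def test_pulse_shorter_than_frame_rejected(self):
        with pytest.raises(FormatError):
            pulse_endpoints(np.zeros(10), np.arange(10.0), [0, 2, 4, 6, 8, 10],
                            pulse_on=0.5, pulse_off=0.5)


class TestInverseLeakiness:
    def test_perfect_integrator_staircase_is_one(self):
        on = np.arange(1.0, 7.0)
        off = np.arange(0.0, 7.0)
        assert inverse_leakiness(on, off) == pytest.approx(1.0)

    def test_memoryless_responder_is_zero(self):
        assert inverse_leakiness(np.ones(6),
                                 np.zeros(7)) == pytest.approx(0.0)

    def test_tau5_square_pulse_closed_form(self):
        frame_t = boundary_frames(7)
        trace = exact_integrator_trace(frame_t, 5.0)
        on, off = pulse_endpoints(trace, frame_t, [2 * k for k in range(6)])
        assert inverse_leakiness(on, off) == pytest.approx(INV_LEAK_TAU5,
                                                           abs=1e-6)

    def test_monotone_in_tau(self):
        vals = []
        for tau in (0.5, 1.0, 2.0, 5.0, 10.0, 50.0):
            frame_t = boundary_frames(7)
            trace = exact_integrator_trace(frame_t, tau)
            on, off = pulse_endpoints(trace, frame_t,
                                      [2 * k for k in range(6)])
            vals.append(inverse_leakiness(on, off))
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_denominator_gives_nan(self):
        assert math.isnan(inverse_leakiness(np.zeros(6), np.zeros(7)))


class TestPulseAUC:
    def test_rectangular_response(self):
        fs = 10.0
        frame_t = np.arange(100) / fs
        trace = np.where((frame_t >= 2.0) & (frame_t < 3.0), 2.0, 0.0)
        auc = pulse_response_auc(trace, frame_t, 2.0, window=2.0)
        assert auc == pytest.approx(2.0, abs=2 * 2.0 / fs)

    def test_zero_trace(self):
        frame_t = np.arange(100) / 10.0
        assert pulse_response_auc(np.zeros(100), frame_t, 2.0) == 0.0

    def test_matches_fine_grid_quadrature(self):
        # indicator-like transient, trapezoid at 30 Hz vs quadrature at
        # 100x oversampling
        decay, rise = 0.5, 0.05
        def wave(t):
            t = np.maximum(t - 2.0, 0)
            return np.exp(-t / decay) - np.exp(-t / rise)
        coarse_t = np.arange(0, 10, 1 / 30) + 1e-6
        fine_t = np.arange(0, 10, 1 / 3000)
        coarse = pulse_response_auc(wave(coarse_t), coarse_t, 2.0, window=2.0)
        fine = np.trapezoid(wave(fine_t)[(fine_t >= 2.0) & (fine_t <= 4.0)],
                            fine_t[(fine_t >= 2.0) & (fine_t <= 4.0)])
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_additive_over_disjoint_windows_and_linear(self):
        rng = np.random.default_rng(0)
        frame_t = np.arange(0, 12, 1 / 3)
        trace = rng.normal(0, 1, frame_t.size)
        a = pulse_response_auc(trace, frame_t, 0.0, window=4.0)
        b = pulse_response_auc(trace, frame_t, 4.0, window=4.0)
        whole = pulse_response_auc(trace, frame_t, 0.0, window=8.0)
        assert a + b == pytest.approx(whole, abs=1e-9)
        assert pulse_response_auc(2 * trace, frame_t, 0.0, window=4.0) == \
            pytest.approx(2 * a, abs=1e-9)

    def test_truncation_warns(self):
        frame_t = np.arange(0, 3, 1 / 3)
        with pytest.warns(UserWarning):
            pulse_response_auc(np.ones(frame_t.size), frame_t, 2.0, window=5.0)


class TestPulseIntegrationAUC:
    def test_memoryless_cell_residual_is_zero(self):
        fs = 10.0
        frame_t = np.arange(0, 16, 1 / fs)
        onsets = [2 * k for k in range(6)]
        template = np.where(np.arange(0, 2, 1 / fs) < 1.0, 1.0, 0.0)
        trace = np.zeros(frame_t.size)
        for t0 in onsets:
            idx = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + 2.0))
            trace[idx[:template.size]] += template[:idx.size]
        auc = pulse_integration_auc(trace, frame_t, onsets, template)
        assert auc == pytest.approx(0.0, abs=1e-9)

    def test_staircase_minus_templates_arithmetic_oracle(self):
        fs = 10.0
        frame_t = np.arange(0, 16, 1 / fs)
        onsets = [2.0 * k for k in range(6)]
        stair = np.floor(frame_t / 2.0) + np.where((frame_t % 2.0) < 1.0,
                                                   (frame_t % 2.0), 1.0)
        tt = np.arange(0, 2, 1 / fs)
        template = np.where(tt < 1.0, tt, 1.0)
        auc = pulse_integration_auc(stair, frame_t, onsets, template)
        # direct arithmetic: integral of stair over [0,12] minus 6 template
        # copies (each has area 0.5 + 1.0 minus trapezoid end corrections)
        resid = stair.copy()
        for t0 in onsets:
            idx = np.flatnonzero((frame_t >= t0) & (frame_t < t0 + 2.0))
            resid[idx[:template.size]] -= template[:idx.size]
        sel = (frame_t >= 0) & (frame_t <= 12.0)
        expect = np.trapezoid(resid[sel], frame_t[sel])
        assert auc == pytest.approx(expect, abs=1e-9)

    def test_template_longer_than_period_rejected(self):
        frame_t = np.arange(0, 16, 1 / 3)
        with pytest.raises(FormatError):
            pulse_integration_auc(np.zeros(frame_t.size), frame_t,
                                  [2 * k for k in range(6)],
                                  np.zeros(30), period=2.0)


class TestTemplate:
    def test_template_from_first_pulses_is_baseline_subtracted(self):
        frame_t = np.arange(0, 30, 1 / 3)
        trace = np.full(frame_t.size, 5.0)
        trace[(frame_t >= 10) & (frame_t < 11)] += 1.0
        templ = estimate_pulse_template(trace, frame_t, [10.0], period=2.0)
        assert templ.max() == pytest.approx(1.0)
        assert templ.min() == pytest.approx(0.0)
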