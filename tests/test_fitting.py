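"""Phase segmentation, exponential fits, rate-curve and isotherm recovery,
step detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssbkin import (
    NoiseModel,
    Protocol,
    Segment,
    Trace,
    apparent_bind_rate,
    detect_steps,
    equilibrate,
    fit_exponential,
    fit_isotherm,
    fit_rate_curve,
    generate_concentration_series,
    segment_phases,
    simulate_protocol,
    step_histogram_mode,
)
from ssbkin.fitting import FitError


def make_exp_trace(A, k, B, T=100.0, fs=10.0, sigma=0.0, seed=0):
    t = np.arange(0.0, T, 1.0 / fs)
    y = A * np.exp(-k * t) + B
    if sigma:
        y = y + np.random.default_rng(seed).normal(0, sigma, len(t))
    return Trace(t, y)


class TestFitExponential:
    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.02, 2.0), st.floats(-0.08, 0.08).filter(lambda a: abs(a) > 0.005),
           st.floats(0.0, 0.1))
    def test_exact_on_noiseless_exponential(self, k, A, B):
        tr = make_exp_trace(A, k, B, T=min(10.0 / k, 500.0))
        fit = fit_exponential(tr, (0.0, tr.time[-1]))
        assert fit.rate == pytest.approx(k, rel=1e-6)

    def test_short_window_rejected(self):
        tr = make_exp_trace(0.05, 0.1, 0.0, T=100.0)
        with pytest.raises(FitError):
            fit_exponential(tr, (0.0, 0.5))

    def test_recovers_rate_under_noise_and_drift(self):
        t = np.arange(0.0, 300.0, 0.1)
        rng = np.random.default_rng(42)
        y = 0.016 * np.exp(-0.017 * t) + 2e-5 * t + rng.normal(0, 0.005, len(t))
        fit = fit_exponential(Trace(t, y), (0.0, t[-1]))
        assert fit.rate == pytest.approx(0.017, rel=0.25)


class TestSegmentPhases:
    def test_four_phase_cycle_sign_pattern(self, ideal_50nM_cycle):
        phases = segment_phases(ideal_50nM_cycle)
        labels = [p.label for p in phases]
        assert labels == ["bind-wrap", "bind-unwrap", "unbind-wrap", "rebind-unwrap"]
        signs = [np.sign(p.amplitude) for p in phases]
        assert signs == [1.0, -1.0, 1.0, -1.0]

    def test_low_concentration_single_phase(self, table1):
        proto = Protocol((Segment(600.0, 0.1), Segment(100.0, 0.0)))
        tr = simulate_protocol(proto, table1)
        phases = segment_phases(tr)
        assert [p.label for p in phases] == ["bind-wrap"]

    def test_flat_trace_yields_no_phases(self):
        proto = Protocol((Segment(60.0, 1.0),))
        t = np.arange(0.0, 60.0, 0.1)
        tr = Trace(t, np.zeros_like(t), protocol=proto)
        assert segment_phases(tr) == []

    def test_mismatched_protocol_rejected(self, ideal_50nM_cycle):
        proto = Protocol((Segment(10.0, 1.0),))
        with pytest.raises(FitError):
            segment_phases(ideal_50nM_cycle, proto)


class TestApparentBindRate:
    def test_limits(self):
        kb, kw = 0.18, 1.8
        c_small = 1e-4
        assert apparent_bind_rate(c_small, kb, kw) / c_small == pytest.approx(kb, rel=1e-4)
        assert apparent_bind_rate(1e6, kb, kw) == pytest.approx(kw, rel=1e-4)
        assert apparent_bind_rate(kw / kb, kb, kw) == pytest.approx(kw / 2)

    def test_domain(self):
        with pytest.raises(ValueError):
            apparent_bind_rate(1.0, -0.1, 1.0)


class TestRateCurve:
    def test_round_trip_recovery_single_seed(self, prose):
        series = generate_concentration_series(prose, noise=NoiseModel(seed=0))
        rc = fit_rate_curve(series)
        assert rc.k_b == pytest.approx(prose.k_b, rel=0.2)
        assert rc.k_w == pytest.approx(prose.k_w, rel=0.3)
        assert rc.unbind_wrap_rate == pytest.approx(0.11, rel=0.3)

    def test_nonparametric_slope(self, prose):
        series = generate_concentration_series(prose, noise=NoiseModel(seed=1))
        rc = fit_rate_curve(series, method="nonparametric")
        assert rc.k_b == pytest.approx(prose.k_b, rel=0.25)


class TestIsotherm:
    def test_exact_isotherm(self):
        cs = np.array([0.5, 1, 2, 5, 10, 20, 50])
        pts = [(c, c / (c + 5.0)) for c in cs]
        cc, err = fit_isotherm(pts)
        assert cc == pytest.approx(5.0, rel=1e-6)

    def test_equilibrium_states_give_calibrated_crossover(self, table1):
        pts = []
        for c in (1.5, 2.5, 3.5, 5.0, 10.0, 30.0):
            s = equilibrate(c, table1)
            pts.append((c, s.theta_b / (s.theta_b + s.theta_w)))
        cc, _ = fit_isotherm(pts)
        assert cc == pytest.approx(3.4, abs=1.0)

    def test_noise_robustness(self):
        rng = np.random.default_rng(3)
        cs = np.array([0.5, 1, 2, 5, 10, 20, 50])
        est = []
        for _ in range(40):
            pts = [(c, c / (c + 5.0) + rng.normal(0, 0.05)) for c in cs]
            est.append(fit_isotherm(pts)[0])
        assert np.median(est) == pytest.approx(5.0, rel=0.1)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            fit_isotherm([(1, 0.2), (2, 0.3), (3, 0.4)])


def staircase_trace(step_nm, n_steps, dwell_s=8.0, fs=10.0, sigma=0.5, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, n_steps * dwell_s, 1.0 / fs)
    y = step_nm * (t // dwell_s) + rng.normal(0, sigma, len(t))
    return Trace(t, y)


class TestDetectSteps:
    @pytest.mark.parametrize("step", [2.0, 5.0])
    def test_staircase_mode_recovery(self, step):
        tr = staircase_trace(step, n_steps=12, seed=5)
        steps = detect_steps(tr, min_step=1.0)
        assert len(steps) >= 6
        assert step_histogram_mode(steps, bin_width=0.5) == pytest.approx(step, abs=0.5)

    def test_flat_trace_no_steps(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 60.0, 0.1)
        tr = Trace(t, rng.normal(0, 0.5, len(t)))
        assert detect_steps(tr, min_step=1.0) == []
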