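import numpy as np
import pytest

from hemowave.fixtures import analytic_pq, random_pq_draw
from hemowave.wsa import (input_impedance, separate, separation_metrics,
                          windkessel_impedance)


def harmonic_flow(period=0.8, n=1024, n_harm=10, seed=3):
    rng = np.random.default_rng(seed)
    t = np.linspace(0, period, n, endpoint=False)
    q = np.full(n, 80.0)
    for k in range(1, n_harm + 1):
        q += rng.uniform(5, 25) * np.cos(2 * np.pi * k * t / period
                                         + rng.uniform(0, 2 * np.pi))
    return t, q


class TestInputImpedance:
    def test_proportional_signals_give_flat_spectrum(self):
        t, q = harmonic_flow()
        z0 = 0.07
        spec = input_impedance(z0 * q, q, 0.8)
        assert np.allclose(spec.modulus[:10], z0, rtol=1e-9)
        assert spec.Zc == pytest.approx(z0, rel=1e-9)

    def test_windkessel_closed_form_at_every_harmonic(self):
        """Pressure synthesized through an analytic 3-element Windkessel
        must return the closed-form modulus at each harmonic (0.5%)."""
        period = 0.8
        t, q = harmonic_flow(period)
        R1, R2, C = 0.06, 1.1, 1.3
        qh = np.fft.rfft(q)
        freqs = np.arange(qh.size) / period
        ph = qh * windkessel_impedance(R1, R2, C, freqs)
        p = np.fft.irfft(ph, n=q.size)
        spec = input_impedance(p, q, period)
        expected = np.abs(windkessel_impedance(R1, R2, C, freqs[1:11]))
        assert np.allclose(spec.modulus[:10], expected, rtol=0.005)

    def test_flowless_harmonics_excluded_with_warning(self):
        period = 0.8
        t = np.linspace(0, period, 1024, endpoint=False)
        # flow content only at harmonics 1..6 -> 7, 8, 9 excluded
        q = 50.0 + sum(10 * np.cos(2 * np.pi * k * t / period)
                       for k in range(1, 7))
        p = 0.05 * q + 70.0
        with pytest.warns(UserWarning, match="excluded"):
            spec = input_impedance(p, q, period)
        assert spec.excluded == [7, 8, 9]
        assert spec.Zc == pytest.approx(0.05, rel=1e-6)

    def test_too_few_usable_harmonics_rejected(self):
        period = 0.8
        t = np.linspace(0, period, 1024, endpoint=False)
        q = 50.0 + 10 * np.cos(2 * np.pi * t / period)
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            input_impedance(0.05 * q, q, period)


class TestSeparation:
    def test_reflection_free_line(self):
        t, P, Q, F, B = analytic_pq(reflection_scale=0.0)
        sep = separate(t, P, Q, 0.06)
        assert np.allclose(sep.Pb, 0.0, atol=1e-12)
        assert np.allclose(sep.Pf, P)

    def test_closed_end_limit(self):
        t = np.linspace(0, 0.8, 512, endpoint=False)
        P = 90 + 10 * np.sin(2 * np.pi * t / 0.8)
        sep = separate(t, P, np.zeros_like(P), 0.1)
        assert np.allclose(sep.Pf, P / 2)
        assert np.allclose(sep.Pb, P / 2)

    def test_reconstruction_identity(self, baseline_beat):
        sep = separate(baseline_beat.t, baseline_beat.P_root,
                       baseline_beat.Q_root, 0.05)
        assert np.allclose(sep.Pf + sep.Pb, baseline_beat.P_root,
                           atol=1e-10)

    def test_known_composition_recovered(self):
        t, P, Q, F, B = analytic_pq(reflection_scale=0.5, delay=0.15,
                                    Zc_true=0.08)
        sep = separate(t, P, Q, 0.08)
        rms = np.sqrt(np.mean((sep.Pf - F) ** 2)) / np.ptp(F)
        assert rms < 1e-10

    def test_recovery_over_randomized_draws(self):
        """100 seeded draws: median RMS recovery error of the forward
        and backward components < 1%, and the impedance-based Zc within
        3% of truth."""
        rng = np.random.default_rng(2024)
        errs, zerrs = [], []
        for _ in range(100):
            d = random_pq_draw(rng)
            spec = input_impedance(d["P"], d["Q"], d["period"])
            sep = separate(d["t"], d["P"], d["Q"], spec.Zc)
            errs.append(np.sqrt(np.mean((sep.Pf - d["F"]) ** 2))
                        / np.ptp(d["F"]))
            errs.append(np.sqrt(np.mean((sep.Pb - d["B"]) ** 2))
                        / max(np.ptp(d["B"]), 1.0))
            zerrs.append(abs(spec.Zc / d["Zc_true"] - 1))
        assert np.median(errs) < 0.01
        assert np.median(zerrs) < 0.03


class TestSummaryMetrics:
    def test_reflection_coefficient_and_forward_fraction(self):
        t = np.linspace(0, 0.8, 800, endpoint=False)
        sep = separate(t, np.full(800, 52.0), np.zeros(800), 0.1)
        sep.amp_f, sep.amp_b = 30.0, 22.0
        out = separation_metrics(sep, aPP=48.0)
        # the study's worked-example ratios
        assert sep.amp_b / sep.amp_f == pytest.approx(0.733, abs=0.001)
        assert out["forward_fraction"] == pytest.approx(0.625, abs=0.001)

    def test_zero_pulse_pressure_gives_absent_fraction(self):
        t = np.linspace(0, 0.8, 800, endpoint=False)
        sep = separate(t, np.full(800, 52.0), np.zeros(800), 0.1)
        assert separation_metrics(sep, aPP=0.0)["forward_fraction"] is None

    def test_triangle_slope(self):
        """Pf rising as a clean ramp reports that slope (within the
        smoothing of the 25-Hz pre-filter)."""
        t = np.linspace(0, 0.8, 800, endpoint=False)
        s = 400.0
        P = 50 + s * np.minimum(t, 0.8 - t)
        Q = P / 0.1
        sep = separate(t, P, Q, 0.1)
        assert sep.max_slope_f == pytest.approx(s, rel=0.15)


class TestPipelineStates:
    def test_zc_estimates_match_study_conditions(self, study_default):
        rows = {r.state: r.wsa_summary for r in study_default.reports}
        assert rows["baseline"]["Zc"] == pytest.approx(0.05, rel=0.30)
        assert rows["banding"]["Zc"] == pytest.approx(0.16, rel=0.30)

    def test_forward_fraction_strictly_increases(self, study_default):
        ff = [r.wsa_summary["forward_fraction"]
              for r in study_default.reports]
        assert ff[0] < ff[1] < ff[2]
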