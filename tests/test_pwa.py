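import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemowave.pwa import (aix, analyze_pressure, augmentation,
                          basic_pressures, classify_phenotype, find_foot,
                          find_inflection)


def shoulder_wave(n=800, period=0.8, bump_amp=14.0, bump_t=0.23,
                  bump_w=0.045):
    """Logistic upstroke to a plateau + late Gaussian bump: a textbook
    augmented (Type A) central pressure wave with a known shoulder at
    the junction of the two components."""
    t = np.linspace(0, period, n, endpoint=False)
    upstroke = 60.0 + 40.0 / (1 + np.exp(-(t - 0.07) / 0.012))
    decay = np.where(t > 0.35, -40.0 * (t - 0.35), 0.0)
    bump = bump_amp * np.exp(-0.5 * ((t - bump_t) / bump_w) ** 2)
    return t, upstroke + bump + decay


class TestBasicPressures:
    def test_sinusoid(self):
        t = np.linspace(0, 1, 1000, endpoint=False)
        sbp, dbp, mean, pp = basic_pressures(100 + 20 * np.sin(2 * np.pi * t))
        assert (sbp, dbp) == pytest.approx((120, 80), abs=1e-3)
        assert mean == pytest.approx(100, abs=1e-6)
        assert pp == pytest.approx(40, abs=1e-2)

    def test_constant_wave_degenerates(self):
        sbp, dbp, mean, pp = basic_pressures(np.full(100, 90.0))
        assert sbp == dbp == mean == 90.0 and pp == 0.0

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            basic_pressures(np.array([1.0, 2.0]))


class TestAixArithmetic:
    @pytest.mark.parametrize("ap, pp, expected", [
        (-1.0, 48.0, -2.083),
        (11.0, 84.0, 13.095),
        (-2.0, 75.0, -2.667),
        (0.0, 50.0, 0.0),
    ])
    def test_ratio(self, ap, pp, expected):
        assert aix(ap, pp) == pytest.approx(expected, abs=0.001)

    def test_zero_pulse_pressure_rejected(self):
        with pytest.raises(ValueError):
            aix(1.0, 0.0)


class TestInflectionDetection:
    def test_shoulder_found_before_bump_center(self):
        t, P = shoulder_wave()
        t_inf, p_inf = find_inflection(t, P)
        foot = find_foot(t, P)
        assert t_inf is not None
        assert t_inf + foot < 0.23
        # shoulder sits at the junction: on the plateau, below bump top
        assert 95.0 < p_inf < np.max(P)

    def test_featureless_pulse_handled(self):
        t = np.linspace(0, 0.8, 800, endpoint=False)
        P = 80 + 30 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2)
        t_inf, p_inf = find_inflection(t, P)  # must not raise
        if t_inf is not None:
            assert np.min(P) <= p_inf <= np.max(P)

    def test_amplitude_scale_invariance(self):
        t, P = shoulder_wave()
        t1, _ = find_inflection(t, P)
        t2, _ = find_inflection(t, 0.37 * P)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_affine_invariance_of_aix(self):
        t, P = shoulder_wave()
        _, ai1 = augmentation(t, P)
        _, ai2 = augmentation(t, 2.5 * P + 17.0)
        assert ai1 == pytest.approx(ai2, rel=1e-6)

    def test_sampling_rate_stability(self):
        """Metrics at 500 Hz vs 1 kHz differ by < 0.5%."""
        t, P = shoulder_wave(n=800)
        ap1, ai1 = augmentation(t, P, 0.8)
        ap2, ai2 = augmentation(t[::2], P[::2], 0.8)
        assert ai2 == pytest.approx(ai1, rel=0.005)
        s1 = basic_pressures(P)
        s2 = basic_pressures(P[::2])
        for a, b in zip(s1, s2):
            assert b == pytest.approx(a, rel=0.005)


class TestPhenotype:
    @pytest.mark.parametrize("ai, t_inf, t_peak, expected", [
        (13.1, 0.17, 0.26, "TypeA"),
        (-2.1, 0.21, 0.18, "TypeC"),
        (5.0, 0.17, 0.26, "Indeterminate"),
        (5.0, 0.26, 0.17, "Indeterminate"),
        (None, None, 0.2, "Indeterminate"),
    ])
    def test_classification_rules(self, ai, t_inf, t_peak, expected):
        assert classify_phenotype(ai, t_inf, t_peak) == expected


class TestOnSimulatedBeats:
    def test_baseline_pressures_near_study_conditions(self, baseline_beat):
        """Baseline beat: aSBP ~106, aDBP ~59, MAP ~83 (fixture
        tolerance +/-6 mmHg)."""
        m = analyze_pressure(baseline_beat.t, baseline_beat.P_root,
                             baseline_beat.period)
        assert m.aSBP == pytest.approx(106.0, abs=6.0)
        assert m.aDBP == pytest.approx(59.0, abs=6.0)
        assert m.MAP == pytest.approx(83.0, abs=6.0)

    def test_baseline_inflection_in_design_window(self, baseline_beat):
        m = analyze_pressure(baseline_beat.t, baseline_beat.P_root,
                             baseline_beat.period)
        assert 0.17 <= m.t_inflection <= 0.23

    def test_three_state_aix_pattern(self, study_default):
        rows = {r.state: r.pwa for r in study_default.reports}
        assert rows["banding"].AIx > rows["baseline"].AIx
        assert rows["remodeling"].AIx < 10.0
        assert rows["remodeling"].phenotype == "TypeC"

    def test_aix_invariant_to_affine_rescaling(self, baseline_beat):
        t, P = baseline_beat.t, baseline_beat.P_root
        _, ai1 = augmentation(t, P, baseline_beat.period)
        _, ai2 = augmentation(t, 1.4 * P + 11.0, baseline_beat.period)
        assert ai2 == pytest.approx(ai1, rel=1e-6)
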