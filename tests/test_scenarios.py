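import numpy as np
import pytest

from hemowave import (apply_banding, default_tree, heart_config, remodel,
                      run_to_periodic, scale_tpr, stress_index,
                      total_compliance, total_peripheral_resistance,
                      tune_pfill)
from hemowave.scenarios import ScenarioSpec


class TestBanding:
    def test_zero_fraction_is_identity(self, tree):
        assert total_compliance(apply_banding(tree, 0.0)) == pytest.approx(
            total_compliance(tree))

    def test_default_banding_compliance(self, tree):
        """80% proximal reduction: CT 0.96 -> 0.58 mL/mmHg (~40% total)."""
        banded = apply_banding(tree, 0.80)
        ct = total_compliance(banded)
        assert round(ct, 2) == 0.58
        drop = 1 - ct / total_compliance(tree)
        assert drop == pytest.approx(0.40, abs=0.01)

    def test_distal_elements_untouched(self, tree):
        banded = apply_banding(tree, 0.80)
        for s, sb in zip(tree.segments, banded.segments):
            if not s.proximal:
                assert sb.compliance_per_length == s.compliance_per_length
        assert banded.terminals == tree.terminals

    def test_unbandable_tree_rejected(self, tree):
        no_prox = type(tree)(
            [s.replace(proximal=False) for s in tree.segments],
            dict(tree.children), dict(tree.terminals), tree.pref)
        with pytest.raises(ValueError, match="proximal"):
            apply_banding(no_prox, 0.8)


class TestTprScaling:
    def test_identity(self, tree):
        assert total_peripheral_resistance(scale_tpr(tree, 1.0)) == \
            pytest.approx(total_peripheral_resistance(tree))

    def test_thirty_percent_increase(self, tree):
        scaled = scale_tpr(tree, 1.3)
        assert total_peripheral_resistance(scaled) == pytest.approx(
            1.3 * 0.92, rel=1e-9)
        # Table-level rounding: 0.92 -> 1.20
        assert round(total_peripheral_resistance(scaled), 2) == 1.20

    def test_composition(self, tree):
        ab = scale_tpr(scale_tpr(tree, 1.2), 1.1)
        once = scale_tpr(tree, 1.32)
        assert total_peripheral_resistance(ab) == pytest.approx(
            total_peripheral_resistance(once), rel=1e-9)

    def test_terminal_compliance_unchanged(self, tree):
        scaled = scale_tpr(tree, 1.3)
        for k in tree.terminals:
            assert scaled.terminals[k].C == tree.terminals[k].C


class TestStressIndex:
    def test_normalization(self):
        assert stress_index(2.0, 1.0, 2.0) == pytest.approx(1.0)

    def test_baseline_magnitude(self):
        # 106 * 123^(1/3) / 3.2
        assert stress_index(106.0, 123.0, 3.2) == pytest.approx(164.7,
                                                                abs=0.1)

    def test_homogeneity_in_pressure_and_elastance(self):
        assert stress_index(212.0, 123.0, 6.4) == pytest.approx(
            stress_index(106.0, 123.0, 3.2))

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            stress_index(-1.0, 100.0, 3.0)


class TestPfillTuning:
    def test_fixed_point(self, tree, baseline_heart, baseline_beat):
        heart, beat = tune_pfill(baseline_heart, tree, baseline_beat.SV)
        assert heart.Pfill == pytest.approx(baseline_heart.Pfill, rel=0.05)
        assert beat.SV == pytest.approx(baseline_beat.SV, rel=0.005)

    def test_sv_monotone_in_pfill(self, tree, baseline_heart):
        svs = [run_to_periodic(baseline_heart.replace(Pfill=pf), tree).SV
               for pf in (9.0, 11.5, 14.0)]
        assert svs[0] < svs[1] < svs[2]

    def test_banding_raises_pfill(self, study_default):
        """Conserving SV on the banded tree needs a higher preload."""
        rows = {r.state: r for r in study_default.reports}
        assert rows["banding"].heart["Pfill"] > rows["baseline"].heart["Pfill"]

    def test_unreachable_target_raises(self, tree, baseline_heart):
        with pytest.raises(ValueError, match="trace|attainable"):
            tune_pfill(baseline_heart, tree, 160.0)


class TestRemodeling:
    def test_sigma_converges_to_target(self, study_default):
        rem = study_default.remodeling
        assert abs(rem.sigma_final / rem.sigma_target - 1) <= 0.01

    def test_elastance_increase_in_physiologic_range(self, study_default):
        rem = study_default.remodeling
        assert rem.Ees_remodel / 3.2 == pytest.approx(1.34, abs=0.15)

    def test_beta_scales_with_elastance(self, study_default):
        rem = study_default.remodeling
        base = heart_config("banding")
        assert rem.beta_remodel / base.beta == pytest.approx(
            rem.Ees_remodel / base.Ees, rel=1e-6)

    def test_dead_volume_and_tree_unchanged(self, study_default):
        rows = {r.state: r for r in study_default.reports}
        assert rows["remodeling"].heart["Vd"] == rows["banding"].heart["Vd"]
        assert rows["remodeling"].tree_summary == rows["banding"].tree_summary

    def test_sv_conserved_across_all_states(self, study_default):
        svs = [r.beat_metrics["SV"] for r in study_default.reports]
        for sv in svs[1:]:
            assert sv == pytest.approx(svs[0], rel=0.01)

    def test_already_converged_input_returns_quickly(self, tree):
        """A sigma target equal to the banded state's own stress index
        terminates in at most one iteration."""
        banded = scale_tpr(apply_banding(tree, 0.8), 1.3)
        heart = heart_config("banding")
        heart, beat = tune_pfill(heart, banded, 74.0)
        sigma = stress_index(beat.peak_lv_pressure, beat.EDV, heart.Ees)
        rem = remodel(heart, banded, sigma, 74.0)
        assert rem.iterations <= 1
        assert rem.Ees_remodel == pytest.approx(heart.Ees, rel=0.05)


class TestScenarioSpec:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(banding_fraction=1.0)
        with pytest.raises(ValueError):
            ScenarioSpec(name="nonsense")
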