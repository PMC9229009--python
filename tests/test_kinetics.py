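"""Kinetic descriptors: slope, minimum detection, overtone spread, phase
trajectory, and the four-way signature classification."""

import numpy as np
import pytest

from slbqcmd.kinetics import (
    ClassifierConfig,
    SignatureReport,
    classify_signature,
    detect_frequency_minimum,
    initial_slope,
    overtone_spread,
    phase_trajectory,
)
from slbqcmd.simulate import SCENARIOS, generate_trace, scenario_defaults
from slbqcmd.traces import FlowMarkers, QCMDTrace


def ramp_trace(slope=-10.0, t_ramp=3.0, t_start=2.0, t_total=20.0, recover_to=-5.0):
    """Piecewise-linear trace: flat, ramp at `slope` to a minimum, recovery."""
    t = np.arange(0, t_total, 1 / 60)
    f = np.zeros_like(t)
    in_ramp = (t >= t_start) & (t <= t_start + t_ramp)
    f[in_ramp] = slope * (t[in_ramp] - t_start)
    f_min = slope * t_ramp
    after = t > t_start + t_ramp
    f[after] = recover_to + (f_min - recover_to) * np.exp(-(t[after] - t_start - t_ramp))
    D = np.zeros_like(t)
    return QCMDTrace(time=t, delta_f={3: f, 5: f.copy()}, delta_D={3: D, 5: D.copy()})


class TestInitialSlope:
    def test_exact_on_linear_ramp(self):
        tr = ramp_trace(slope=-10.0)
        m = FlowMarkers(2.0, 15.0, 19.0)
        assert initial_slope(tr, m, 3, smooth_window=1) == pytest.approx(-10.0, abs=0.05)

    def test_flat_trace_warns_zero(self, flat_trace):
        m = FlowMarkers(2.0, 15.0, 19.0)
        with pytest.warns(UserWarning, match="no adsorption"):
            assert initial_slope(flat_trace, m, 3) == 0.0

    def test_two_step_default_near_secant(self):
        """Slope on the two-step default within 10% of f_min/t_min = −28.8."""
        p = scenario_defaults("two_step_slb")
        tr = generate_trace(p)
        s = initial_slope(tr, p.markers, 3)
        assert s == pytest.approx(-72.0 / 2.5, rel=0.10)

    def test_invariant_under_vertical_offset_and_time_shift(self):
        p = scenario_defaults("two_step_slb")
        tr = generate_trace(p)
        ref = initial_slope(tr, p.markers, 3)
        shifted = QCMDTrace(time=tr.time + 7.0,
                            delta_f={n: v + 4.0 for n, v in tr.delta_f.items()},
                            delta_D=tr.delta_D)
        m2 = FlowMarkers(p.markers.t_start + 7.0, p.markers.t_rinse + 7.0,
                         p.markers.t_end + 7.0)
        assert initial_slope(shifted, m2, 3) == pytest.approx(ref, abs=1e-6)

    def test_short_window_rejected(self):
        t = np.arange(0, 1, 1 / 60)
        f = -30 * t
        tr = QCMDTrace(time=t, delta_f={3: f}, delta_D={3: np.zeros_like(t)})
        with pytest.raises(ValueError, match="3 samples"):
            initial_slope(tr, FlowMarkers(0.98, 0.99, 1.0), 3, smooth_window=1)


class TestMinimumDetection:
    def test_two_step_default_location(self):
        p = scenario_defaults("two_step_slb")
        tr = generate_trace(p)
        found = detect_frequency_minimum(tr, 3, prominence=10.0)
        assert found is not None
        t_min, f_min = found
        assert t_min == pytest.approx(p.markers.t_start + 2.5, abs=0.1)
        assert f_min == pytest.approx(-72.0, abs=0.5)

    def test_monotone_one_step_absent(self, noisefree_runs):
        _, tr = noisefree_runs["one_step_slb"]
        assert detect_frequency_minimum(tr, 3, prominence=10.0) is None

    def test_noise_only_absent(self):
        rng = np.random.default_rng(4)
        t = np.arange(0, 20, 1 / 60)
        tr = QCMDTrace(time=t,
                       delta_f={3: rng.normal(0, 0.5, t.size)},
                       delta_D={3: np.zeros_like(t)})
        assert detect_frequency_minimum(tr, 3, prominence=10.0) is None

    def test_absent_minimum_blocks_two_step_label(self):
        """If no minimum clears the prominence, classify cannot say two-step."""
        for scen in ("one_step_slb", "vesicle_layer", "incomplete_bilayer"):
            p = scenario_defaults(scen, seed=2, noise_sd_f=0.5, noise_sd_D=0.05)
            tr = generate_trace(p)
            cfg = ClassifierConfig(min_prominence=10.0)
            if detect_frequency_minimum(tr, 3, cfg.min_prominence) is None:
                assert classify_signature(tr, p.markers, cfg).label != "two_step_slb"


class TestOvertoneSpread:
    def test_identical_harmonics_zero(self, flat_trace):
        assert overtone_spread(flat_trace, (0.0, 10.0)) == 0.0

    def test_generator_spread_recovered(self):
        p = scenario_defaults("vesicle_layer")
        tr = generate_trace(p)
        window = (p.markers.t_end - 1.0, p.markers.t_end)
        conv = 1 - np.exp(-p.rate * (p.markers.t_end - p.markers.t_start))
        assert overtone_spread(tr, window) == pytest.approx(6.0 * conv, rel=0.02)

    def test_single_harmonic_rejected(self):
        t = np.arange(0, 5, 1 / 60)
        tr = QCMDTrace(time=t, delta_f={3: np.zeros_like(t)},
                       delta_D={3: np.zeros_like(t)})
        with pytest.raises(ValueError, match="2 harmonics"):
            overtone_spread(tr, (0, 5))


class TestPhaseTrajectory:
    def test_two_step_runs_northeast_then_southwest(self, noisefree_runs):
        p, tr = noisefree_runs["two_step_slb"]
        steps = [s.direction for s in phase_trajectory(tr, 3)]
        moving = [d for d in steps if d != "stationary"]
        i_ne = moving.index("NE")
        i_sw = moving.index("SW")
        assert i_ne < i_sw
        assert moving.count("NE") + moving.count("SW") > 0.6 * len(moving)

    def test_one_step_mainly_east(self, noisefree_runs):
        p, tr = noisefree_runs["one_step_slb"]
        moving = [s.direction for s in phase_trajectory(tr, 3) if s.direction != "stationary"]
        assert moving.count("E") > 0.5 * len(moving)
        assert "SW" not in moving

    def test_constant_trace_all_stationary(self, flat_trace):
        assert all(s.direction == "stationary" for s in phase_trajectory(flat_trace, 3))


class TestClassification:
    @pytest.mark.parametrize("preset,expected", [
        ("PG", "vesicle_layer"),
        ("PC", "two_step_slb"),
        ("PG-LPG-10", "one_step_slb"),
        ("PG-LPG-20", "one_step_slb"),
        ("PG-LPG-30", "one_step_slb"),
        ("PG-LPG-40", "incomplete_bilayer"),
    ])
    def test_lipid_system_presets(self, preset, expected):
        from slbqcmd.simulate import get_preset

        p = get_preset(preset)
        rep = classify_signature(generate_trace(p), p.markers)
        assert rep.label == expected

    def test_descriptors_populated_for_vesicle_layer(self, noisefree_runs):
        p, tr = noisefree_runs["vesicle_layer"]
        rep = classify_signature(tr, p.markers)
        assert rep.D_final > 1.0 and not rep.rigid
        assert rep.f_final < -45
        assert rep.overtone_spread_final > 3.0
        assert rep.f_min is None

    def test_rigid_flag_matches_dissipation(self, noisefree_runs):
        for scen in SCENARIOS:
            p, tr = noisefree_runs[scen]
            rep = classify_signature(tr, p.markers)
            assert rep.rigid == (rep.D_final < 1.0)

    def test_two_step_report_invariant(self, noisefree_runs):
        p, tr = noisefree_runs["two_step_slb"]
        rep = classify_signature(tr, p.markers)
        assert rep.f_min is not None and rep.f_min < rep.f_final

    def test_markers_outside_trace_rejected(self, noisefree_runs):
        _, tr = noisefree_runs["one_step_slb"]
        with pytest.raises(ValueError, match="outside the trace"):
            classify_signature(tr, FlowMarkers(5.0, 100.0, 120.0))

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError, match="rigid flag"):
            SignatureReport(label="one_step_slb", f_final=-26.0, D_final=0.5,
                            initial_slope=-10.0, overtone_spread_final=0.2,
                            rinse_delta_f=0.0, rinse_delta_D=0.0, rigid=False)
        with pytest.raises(ValueError, match="f_min < f_final"):
            SignatureReport(label="two_step_slb", f_final=-26.0, D_final=0.5,
                            initial_slope=-10.0, overtone_spread_final=0.2,
                            rinse_delta_f=0.0, rinse_delta_D=0.0, rigid=True,
                            f_min=-20.0)
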