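import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohlock.experiments import (
    CalibrationCurve,
    ClocWindow,
    PathwaySpec,
    SequenceProgram,
    fit_pgse,
    fit_spillover,
    hmqc_program,
    hsqc_program,
    pathway_phase,
    pgse_attenuation,
    pgse_program,
    robustness_sweep,
    scenario_signals,
    simulate_sequence,
    spillover_signal,
)
from cohlock.hamiltonians import GradientEvent
from cohlock.io_cli.fixtures import generate_calibration_fixture
from cohlock.propagation import EnsembleSpec
from cohlock.spin_algebra import SpinSystem

SYS_H = SpinSystem.single("1H")
SYS_HC = SpinSystem.heteronuclear(j_hz=145.0)
GAMMA_H = SYS_H.gamma[0]

# peak stray drift (T) at the zone edge for a full-amplitude coupled
# gradient: RG * Gmax * l / 2
SPILL_DRIFT = 1.9e-3 * 1.0306 * 6.5e-3 / 2


class TestPathwayPhase:
    def test_4_1_selects_s_plus_to_i_minus(self):
        pw = PathwaySpec(orders=((0, 1), (-1, 0)), ratios=(4.0, 1.0))
        assert pathway_phase(pw, SYS_HC, "nominal4") == 0.0

    def test_4_minus1_selects_s_minus_to_i_minus(self):
        pw = PathwaySpec(orders=((0, -1), (-1, 0)), ratios=(4.0, -1.0))
        assert pathway_phase(pw, SYS_HC, "nominal4") == 0.0

    def test_coupled_2_2_1_train_dephases(self):
        orders = ((0, 1), (0, 1), (1, 0))
        own = PathwaySpec(orders=orders, ratios=(2.0, 2.0, -1.0))
        coupled = PathwaySpec(orders=orders, ratios=(2.0, 2.0, 1.0))
        assert pathway_phase(own, SYS_HC) == 0.0
        assert pathway_phase(coupled, SYS_HC) != 0.0

    def test_exact_gammas_leave_residual(self):
        pw = PathwaySpec(orders=((0, 1), (-1, 0)), ratios=(4.0, 1.0))
        residual = pathway_phase(pw, SYS_HC, "exact")
        assert residual != 0.0
        assert abs(residual) < 0.1 * 4  # small compared to the moments

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            PathwaySpec(orders=((0, 1),), ratios=(4.0, 1.0))

    def test_unknown_convention_raises(self):
        pw = PathwaySpec(orders=((1,),), ratios=(1.0,))
        with pytest.raises(ValueError):
            pathway_phase(pw, SYS_H, "approximate")


class TestPgseAttenuation:
    def test_zero_gradient_gives_one(self):
        assert pgse_attenuation(0.0) == pytest.approx(1.0)

    def test_paper_constants_scalar_oracle(self):
        # direct arithmetic: gamma^2 delta^2 G^2 (Delta - delta) D = 0.8665
        val = pgse_attenuation(1.0306, 1e-3, 7e-3, 1.9e-9)
        expected = np.exp(-(2.675e8**2) * 1e-6 * 1.0306**2 * 6e-3 * 1.9e-9)
        assert val == pytest.approx(expected)
        assert val == pytest.approx(0.42, abs=0.005)

    @settings(max_examples=30)
    @given(
        st.floats(0.01, 2.0),
        st.floats(0.01, 2.0),
    )
    def test_monotone_decreasing_in_gradient(self, g1, g2):
        lo, hi = sorted((g1, g2))
        assert pgse_attenuation(hi) <= pgse_attenuation(lo)

    def test_monotone_in_each_parameter(self):
        base = dict(delta=1e-3, big_delta=7e-3, diffusion=1.9e-9)
        v0 = pgse_attenuation(0.5, **base)
        assert pgse_attenuation(0.5, 1.2e-3, 7e-3, 1.9e-9) < v0
        assert pgse_attenuation(0.5, 1e-3, 8e-3, 1.9e-9) < v0
        assert pgse_attenuation(0.5, 1e-3, 7e-3, 2.5e-9) < v0

    def test_invalid_timing_raises(self):
        with pytest.raises(ValueError):
            pgse_attenuation(0.5, delta=7e-3, big_delta=1e-3)


class TestSpilloverSignal:
    def test_zero_gradient_is_one(self):
        assert spillover_signal(0.0) == pytest.approx(1.0)

    def test_paper_constants_k_value(self):
        # k = l/2 * gamma * RG * Gmax * integral = 1.53 rad
        k = 0.5 * 6.5e-3 * GAMMA_H * 1.9e-3 * 1.0306 * 0.9e-3
        assert k == pytest.approx(1.53, abs=0.01)
        assert spillover_signal(1.0) == pytest.approx(np.sin(k) / k, rel=1e-12)
        assert spillover_signal(1.0) == pytest.approx(0.65, abs=0.01)

    def test_matches_voxel_simulation(self):
        """Closed form vs 64-voxel free-dephasing simulation within 1 %."""
        from cohlock.propagation import LockingWindow, ensemble_signal

        for g in (0.3, 0.6, 0.95):
            grad = GradientEvent(
                shape="trapezoid", drift_scale=SPILL_DRIFT, relative_amplitude=g
            )
            window = LockingWindow.free_evolution(grad)
            # member drift encodes the voxel position; the event's relative
            # amplitude supplies the swept fraction g
            spec = EnsembleSpec.voxel_grid(64, max_drift=SPILL_DRIFT)
            sim = ensemble_signal("-", window, spec, SYS_H)
            assert sim == pytest.approx(float(spillover_signal(g)), abs=0.01)


class TestFits:
    def test_pgse_noiseless_exact_recovery(self):
        curve, _ = generate_calibration_fixture("pgse", noise_sigma=0.0, seed=0)
        res = fit_pgse(curve, gmax_tm=None, diffusion=1.9e-9, n_boot=20)
        assert res.estimate == pytest.approx(1.0306, rel=1e-6)

    def test_pgse_noisy_recovery_within_2_percent(self):
        curve, _ = generate_calibration_fixture("pgse", noise_sigma=0.01, seed=11)
        res = fit_pgse(curve, gmax_tm=None, diffusion=1.9e-9, n_boot=50)
        assert res.estimate == pytest.approx(1.0306, rel=0.02)
        assert res.ci_low < res.estimate < res.ci_high

    def test_pgse_fit_diffusion_instead(self):
        curve, _ = generate_calibration_fixture("pgse", noise_sigma=0.0, seed=0)
        res = fit_pgse(curve, gmax_tm=1.0306, diffusion=None, n_boot=20)
        assert res.estimate == pytest.approx(1.9e-9, rel=1e-6)

    def test_pgse_requires_exactly_one_unknown(self):
        curve, _ = generate_calibration_fixture("pgse", noise_sigma=0.0, seed=0)
        with pytest.raises(ValueError):
            fit_pgse(curve, gmax_tm=None, diffusion=None)
        with pytest.raises(ValueError):
            fit_pgse(curve, gmax_tm=1.0, diffusion=1e-9)

    def test_spillover_noiseless_exact(self):
        curve, _ = generate_calibration_fixture("spillover", noise_sigma=0.0, seed=0)
        res = fit_spillover(curve, n_boot=20)
        assert res.estimate == pytest.approx(1.9e-3, rel=1e-6)

    def test_spillover_noisy_recovery_within_5_percent(self):
        curve, _ = generate_calibration_fixture("spillover", noise_sigma=0.01, seed=5)
        res = fit_spillover(curve, n_boot=50)
        assert res.estimate == pytest.approx(1.9e-3, rel=0.05)

    def test_degenerate_curve_raises(self):
        curve = CalibrationCurve(
            g=np.full(6, 0.5), intensity=np.linspace(1, 0.5, 6)
        )
        with pytest.raises(ValueError):
            fit_pgse(curve, gmax_tm=None)

    def test_too_few_points_raises(self):
        curve = CalibrationCurve(g=np.array([0.0, 0.5, 1.0]),
                                 intensity=np.array([1.0, 0.9, 0.8]))
        with pytest.raises(ValueError):
            fit_spillover(curve)


class TestCalibrationCurve:
    def test_csv_roundtrip(self, tmp_path):
        curve, _ = generate_calibration_fixture("pgse", noise_sigma=0.01, seed=3)
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = CalibrationCurve.from_csv(path)
        assert np.allclose(back.g, curve.g)
        assert np.allclose(back.intensity, curve.intensity)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            CalibrationCurve(g=np.array([0.0, 1.0]),
                             intensity=np.array([1.0, np.nan]))

    def test_rejects_out_of_range_g(self):
        with pytest.raises(ValueError):
            CalibrationCurve(g=np.array([0.0, 1.5]),
                             intensity=np.array([1.0, 0.5]))


class TestSequenceSimulation:
    def test_reference_pgse_is_unity(self):
        spec = EnsembleSpec.voxel_grid(12, max_drift=SPILL_DRIFT)
        prog = pgse_program(gc_amplitude=0.5)
        assert simulate_sequence(prog, SYS_H, spec, "reference") == pytest.approx(1.0)

    def test_refocusing_theorem(self):
        """A refocused pathway with no spillover equals the no-gradient run."""
        spec = EnsembleSpec.voxel_grid(12, max_drift=SPILL_DRIFT)
        from cohlock.experiments import _run_scenario

        with_grad = hsqc_program(gc_amplitude=0.0)
        without = hsqc_program(gc_amplitude=0.0, phi_unit=0.0)
        s1 = _run_scenario(with_grad, SYS_HC, spec, "coupled")
        s2 = _run_scenario(without, SYS_HC, spec, "coupled")
        assert s1 == pytest.approx(s2, abs=1e-6)

    def test_pgse_sweep_matches_sinc_envelope(self):
        """Single unbalanced stray block reproduces the closed-form decay."""
        spec = EnsembleSpec.voxel_grid(64, max_drift=SPILL_DRIFT)
        for gc in (0.0, 0.3, 0.6, 0.95):
            prog = pgse_program(gc_amplitude=gc, gc_ratios=(1.0, 0.0))
            sig = simulate_sequence(prog, SYS_H, spec, "coupled")
            assert sig == pytest.approx(float(spillover_signal(gc)), abs=0.01)

    def test_unknown_scenario_raises(self):
        spec = EnsembleSpec.voxel_grid(4, max_drift=SPILL_DRIFT)
        prog = pgse_program(0.5)
        with pytest.raises(ValueError):
            simulate_sequence(prog, SYS_H, spec, "uncoupled")

    def test_cloc_window_misalignment_rejected(self, design_pulse_h):
        bad = GradientEvent(shape="trapezoid", duration=2e-3, drift_scale=1.0)
        with pytest.raises(ValueError):
            ClocWindow(bad, {"1H": design_pulse_h}).window()


VOXELS_SPILL = EnsembleSpec.voxel_grid(12, max_drift=SPILL_DRIFT)


@pytest.fixture()
def voxels():
    return VOXELS_SPILL


class TestScenarioOrdering:

    def test_pgse_with_locking(self, design_pulse_h, voxels):
        prog = pgse_program(gc_amplitude=0.95, cloc_pulse=design_pulse_h)
        sigs = scenario_signals(prog, SYS_H, voxels)
        assert sigs["coupled"] <= sigs["coupled_with_cloc"] + 1e-3
        assert sigs["coupled_with_cloc"] <= sigs["reference"] + 1e-3
        assert sigs["coupled_with_cloc"] >= 0.95

    @pytest.mark.parametrize(
        "ratios,pathway,coupled",
        [
            ((4.0, 1.0), ((0, 1), (-1, 0)), (4.0, -1.0)),
            ((4.0, -1.0), ((0, -1), (-1, 0)), (4.0, 1.0)),
        ],
    )
    def test_hsqc_with_locking(
        self, design_pulse_h, design_pulse_c, voxels, ratios, pathway, coupled
    ):
        prog = hsqc_program(
            gc_amplitude=0.95,
            ratios=ratios,
            pathway_orders=pathway,
            coupled_ratios=coupled,
            cloc_pulses={0: design_pulse_c, 1: design_pulse_h},
        )
        sigs = scenario_signals(prog, SYS_HC, voxels)
        assert sigs["coupled"] <= sigs["coupled_with_cloc"] + 1e-3
        assert sigs["coupled_with_cloc"] <= sigs["reference"] + 1e-3
        assert sigs["coupled_with_cloc"] >= 0.95
        assert sigs["coupled"] < 0.5  # strong dephasing without locking

    def test_hmqc_double_quantum_locking(
        self, design_pulse_h, design_pulse_c, voxels
    ):
        prog = hmqc_program(
            gc_amplitude=0.95,
            cloc_pulses={0: (design_pulse_h, design_pulse_c), 1: design_pulse_h},
        )
        sigs = scenario_signals(prog, SYS_HC, voxels)
        assert sigs["coupled"] <= sigs["coupled_with_cloc"] + 1e-3
        assert sigs["coupled_with_cloc"] <= sigs["reference"] + 1e-3


class TestRobustnessSweep:
    def test_chi_column_matches_aht(self, design_pulse_h, design_pair):
        from cohlock.aht import toggling_tensor

        spec = design_pair["spec_h"]
        table = robustness_sweep(design_pulse_h, "b1", [0.9, 1.0, 1.1], spec)
        for _, row in table.iterrows():
            assert row["chi"] == pytest.approx(
                toggling_tensor(design_pulse_h, 0.0, row["value"]).chi
            )

    def test_graceful_degradation_along_drift(self, design_pulse_h, design_pair):
        spec = design_pair["spec_h"]
        table = robustness_sweep(
            design_pulse_h, "drift_amplitude", [2.5e-5, 3.75e-5], spec
        )
        assert table["fidelity"].iloc[1] < table["fidelity"].iloc[0]

    def test_unknown_axis_raises(self, design_pulse_h, design_pair):
        with pytest.raises(ValueError):
            robustness_sweep(design_pulse_h, "temperature", [1.0], design_pair["spec_h"])


class TestProgramConfig:
    CFG = {
        "initial": "z",
        "target": "-",
        "pathway": {"orders": [[1], [-1]], "ratios": [1, 1]},
        "events": [
            {"type": "hard_pulse", "channel": "1H", "angle_deg": 90,
             "phase_deg": 90},
            {"type": "pathway_gradient", "ratio": 1, "step": 0},
            {"type": "spillover_gradient", "shape": "trapezoid",
             "duration": 1.0e-3, "relative_amplitude": 0.95, "drift_scale": 1.0,
             "scenarios": ["coupled"]},
            {"type": "hard_pulse", "channel": "1H", "angle_deg": 180},
            {"type": "pathway_gradient", "ratio": 1, "step": 1},
        ],
    }

    def test_config_matches_builder(self):
        from cohlock.experiments import program_from_config

        spec = EnsembleSpec.voxel_grid(16, max_drift=SPILL_DRIFT)
        prog_cfg = program_from_config(self.CFG)
        prog_builder = pgse_program(gc_amplitude=0.95, gc_ratios=(1.0, 0.0))
        s_cfg = simulate_sequence(prog_cfg, SYS_H, spec, "coupled")
        s_b = simulate_sequence(prog_builder, SYS_H, spec, "coupled")
        assert s_cfg == pytest.approx(s_b, abs=1e-12)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        from cohlock.experiments import load_program, program_from_config

        path = tmp_path / "prog.yaml"
        path.write_text(yaml.safe_dump(self.CFG))
        prog = load_program(path)
        assert prog.events == program_from_config(self.CFG).events

    def test_unknown_event_type_raises(self):
        from cohlock.experiments import program_from_config

        bad = dict(self.CFG, events=[{"type": "decoupler_on"}])
        with pytest.raises(ValueError):
            program_from_config(bad)
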