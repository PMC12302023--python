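import numpy as np
import pytest

from cohlock.cloc_design import ControlPulse, OptimizationSpec, member_fidelities
from cohlock.hamiltonians import FieldDistortion, GradientEvent
from cohlock.propagation import (
    EnsembleSpec,
    LockingWindow,
    cyclicity_defect,
    ensemble_signal,
    ensemble_trajectory,
    propagate,
    slice_propagators,
    window_propagator,
)
from cohlock.spin_algebra import SpinSystem

SYS_H = SpinSystem.single("1H")
GAMMA_H = SYS_H.gamma[0]


class TestEnsembleSpec:
    def test_voxel_grid_defaults(self):
        spec = EnsembleSpec.voxel_grid()
        assert spec.n_voxels == 12
        assert len(spec.members) == 12
        # linear map: edges at +-max_drift (voxel centres just inside)
        drifts = np.array(spec.drift_amplitudes)
        assert drifts.max() < 2.5e-5
        assert np.allclose(drifts, -drifts[::-1])

    def test_design_grid_size(self):
        spec = EnsembleSpec.design_grid()
        assert spec.size == 5 * 5 * 3

    def test_voxel_emphasis_appends_members(self):
        spec = EnsembleSpec.design_grid().with_voxel_emphasis(6)
        assert spec.size == 75 + 6
        assert all(m.b1_scale == 1.0 for m in spec.extra_members)


class TestDriftOnlyOracles:
    def test_iz_constant_under_z_drift(self):
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=2.5e-5))
        traj = propagate("z", window, FieldDistortion(b0_drift=2.5e-5), SYS_H)
        assert np.allclose(traj.member_overlaps, 1.0)

    def test_half_sine_phase_oracle(self):
        # phase = gamma * A * integral(sin) = gamma * A * 2 tau / pi, exact
        a = 2.5e-5
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=a))
        traj = propagate("-", window, FieldDistortion(b0_drift=a), SYS_H)
        phase = GAMMA_H * a * 2e-3 / np.pi
        assert traj.final == pytest.approx(np.cos(phase), abs=1e-10)

    def test_halved_slice_width_agrees(self):
        a = 1.3e-5
        g = GradientEvent(drift_scale=a)
        w1 = LockingWindow.free_evolution(g, slice_dt=4e-6)
        w2 = LockingWindow.free_evolution(g, slice_dt=2e-6)
        m = FieldDistortion(b0_drift=a)
        t1 = propagate("-", w1, m, SYS_H).final
        t2 = propagate("-", w2, m, SYS_H).final
        assert t1 == pytest.approx(t2, abs=1e-9)


class TestEnsembleSignal:
    def test_zero_gradient_gives_one(self):
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=0.0))
        spec = EnsembleSpec.voxel_grid(8, max_drift=0.0)
        assert ensemble_signal("-", window, spec, SYS_H) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [0.8, 1.53, 2.5])
    def test_sinc_limit_64_voxels(self, k):
        # peak drift chosen so the zone-edge phase equals k
        a = k / (GAMMA_H * 2e-3 / np.pi)
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=a))
        spec = EnsembleSpec.voxel_grid(64, max_drift=a)
        sig = ensemble_signal("-", window, spec, SYS_H)
        assert sig == pytest.approx(np.sin(k) / k, abs=2e-4)

    def test_discretisation_error_scales_inverse_square(self):
        k = 2.0
        a = k / (GAMMA_H * 2e-3 / np.pi)
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=a))
        exact = np.sin(k) / k
        errs = []
        for n in (8, 16, 32):
            sig = ensemble_signal(
                "-", window, EnsembleSpec.voxel_grid(n, max_drift=a), SYS_H
            )
            errs.append(abs(sig - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.2)

    def test_opposite_members_cancel_imaginary_parts(self):
        a = 1.5e-5
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=a))
        members = [FieldDistortion(b0_drift=a), FieldDistortion(b0_drift=-a)]
        traj = ensemble_trajectory("-", window, members, SYS_H)
        # the +- pair averages to a pure cosine: equal to the single-member
        # real part, no sine contribution
        phase = GAMMA_H * a * 2e-3 / np.pi
        assert traj.final == pytest.approx(np.cos(phase), abs=1e-10)

    def test_empty_ensemble_raises(self):
        window = LockingWindow.free_evolution(GradientEvent())
        with pytest.raises(ValueError):
            ensemble_trajectory("-", window, [], SYS_H)


class TestUnitarity:
    def test_propagator_unitary_and_norm_conserved(self, rng):
        pulse = ControlPulse(
            "1H", 4e-6, rng.normal(0, 1500, 250), rng.normal(0, 1500, 250), 6000.0
        )
        window = LockingWindow.from_pulses({"1H": pulse}, GradientEvent())
        member = FieldDistortion(b0_drift=2.0e-5, b1_scale=1.1, offset_hz=800.0)
        u = window_propagator(window, SYS_H, member)
        assert np.linalg.norm(u.conj().T @ u - np.eye(2)) < 1e-10

        traj = propagate("-", window, member, SYS_H)
        # overlap bounded by norm conservation
        assert np.all(np.abs(traj.member_overlaps) <= 1.0 + 1e-9)

    def test_trajectory_mean_is_member_mean(self, rng):
        window = LockingWindow.free_evolution(GradientEvent(drift_scale=1e-5))
        spec = EnsembleSpec.voxel_grid(5, max_drift=1e-5)
        traj = ensemble_trajectory("-", window, spec, SYS_H)
        assert np.allclose(traj.mean, traj.member_overlaps.mean(axis=0))


class TestCyclicityDefect:
    def test_zero_pulse_zero_drift(self):
        pulse = ControlPulse.zero(n_slices=50, slice_dt=2e-5)
        assert cyclicity_defect(pulse, FieldDistortion()) == pytest.approx(0.0)

    def test_hard_pi_pulse_defect_is_one(self):
        # pi rotation: U = -i(2Ix), trace 0
        n = 50
        dur = 1.0 / (2 * 6000.0)
        pulse = ControlPulse.constant(6000.0, 0.0, n_slices=n, slice_dt=dur / n)
        assert cyclicity_defect(pulse, FieldDistortion()) == pytest.approx(1.0)

    def test_designed_pulse_defect_small_on_nominal_member(self, design_pair):
        pulse = design_pair["pulse_h"]
        spec = design_pair["spec_h"]
        d = cyclicity_defect(
            pulse, FieldDistortion(b0_drift=2.5e-5), SYS_H, spec.gradient
        )
        assert d <= 0.01

    def test_designed_pulse_worst_member(self, design_pair):
        worst = 1.0 - design_pair["report_h"]["worst_member_fidelity"]
        assert worst <= 0.10  # graceful bound; the mean meets the 0.99 threshold


class TestDesignerSimulatorAgreement:
    def test_cyclic_fidelity_matches_propagation(self, design_pair):
        """The optimiser's fidelity and an independent re-evaluation via the
        propagation module agree to near machine precision."""
        pulse = design_pair["pulse_h"]
        spec = design_pair["spec_h"]
        fids = member_fidelities(pulse, spec)
        members = spec.ensemble.members
        window = LockingWindow.from_pulses({"1H": pulse}, spec.gradient)
        for idx in (0, len(members) // 2, len(members) - 1):
            u = window_propagator(window, SYS_H, members[idx])
            assert abs(np.trace(u)) / 2 == pytest.approx(fids[idx], abs=1e-9)


class TestWindowValidation:
    def test_misaligned_pulse_raises(self):
        pulse = ControlPulse.zero(n_slices=100, slice_dt=4e-6)  # 0.4 ms
        with pytest.raises(ValueError):
            LockingWindow.from_pulses({"1H": pulse}, GradientEvent(duration=1e-3))

    def test_misaligned_gradient_raises(self):
        pulse = ControlPulse.zero(n_slices=250, slice_dt=4e-6)
        with pytest.raises(ValueError):
            LockingWindow(
                duration=1e-3,
                n_slices=250,
                pulses={"1H": pulse},
                gradient=GradientEvent(duration=2e-3),
            )


def test_trajectory_csv_export(tmp_path):
    import pandas as pd

    window = LockingWindow.free_evolution(GradientEvent(drift_scale=1e-5))
    spec = EnsembleSpec.voxel_grid(3, max_drift=1e-5)
    traj = ensemble_trajectory("-", window, spec, SYS_H)
    path = tmp_path / "traj.csv"
    traj.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["time_s", "member_0", "member_1", "member_2", "mean"]
    assert np.allclose(df["mean"], traj.mean)
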