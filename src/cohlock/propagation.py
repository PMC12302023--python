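"""Piecewise-constant unitary propagation and ensemble averaging.

A *locking window* is the elementary simulation unit: a time span during
which zero or more shaped RF pulses play out simultaneously with an
optional shaped-gradient drift.  States evolve by exact matrix
exponentials per slice (midpoint rule for the time-dependent drift);
ensembles average the overlap with a named target coherence over voxels
and field distortions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as replace_dc
from typing import Mapping, Sequence

import numpy as np

from .hamiltonians import (
    TWO_PI,
    FieldDistortion,
    GradientEvent,
    j_coupling,
)
from .spin_algebra import SpinSystem, build_operator

__all__ = [
    "DEFAULT_SLICE_DT",
    "EnsembleSpec",
    "LockingWindow",
    "Trajectory",
    "expm_hermitian",
    "propagate",
    "ensemble_trajectory",
    "ensemble_signal",
    "cyclicity_defect",
]

DEFAULT_SLICE_DT = 4.0e-6


# ---------------------------------------------------------------------------
# batched exponentials of Hermitian generators


def expm_hermitian(h: np.ndarray, dt: float) -> np.ndarray:
    """``exp(-i * h * dt)`` for Hermitian ``h``; batched over leading axes."""
    w, v = np.linalg.eigh(h)
    phase = np.exp(-1.0j * dt * w)
    return (v * phase[..., None, :]) @ v.conj().swapaxes(-1, -2)


def expm_hermitian_and_frechet(
    h: np.ndarray, directions: Sequence[np.ndarray], dt: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Exact propagators and Frechet derivatives along constant directions.

    Returns ``U = exp(-i h dt)`` and, for each Hermitian direction ``E``,
    ``dU = d/ds exp(-i (h + s E) dt)|_{s=0}`` via the Daleckii-Krein
    divided-difference formula in the eigenbasis of ``h``.  Batched over
    the leading axes of ``h``; each direction is a plain (d, d) matrix.
    """
    w, v = np.linalg.eigh(h)
    f = np.exp(-1.0j * dt * w)
    vh = v.conj().swapaxes(-1, -2)
    u = (v * f[..., None, :]) @ vh

    # divided differences phi_ij = (f_i - f_j)/(w_i - w_j), -i dt f_i on the
    # diagonal / degenerate pairs
    dw = w[..., :, None] - w[..., None, :]
    df = f[..., :, None] - f[..., None, :]
    small = np.abs(dw) < 1e-12
    phi = np.where(small, -1.0j * dt * f[..., :, None], df / np.where(small, 1.0, dw))

    grads = []
    for e in directions:
        e_tilde = vh @ e @ v
        grads.append(v @ (phi * e_tilde) @ vh)
    return u, grads


# ---------------------------------------------------------------------------
# ensemble specification


@dataclass(frozen=True)
class EnsembleSpec:
    """Robustness grid: drift amplitudes x B1 scales x offsets.

    ``drift_amplitudes`` are peak B0 drifts in Tesla (the time profile is
    supplied by the gradient event of the window being simulated).  When
    built from a voxel grid, drifts vary linearly with voxel position
    across the detection zone so that the zone edges see ``+-max_drift``.
    """

    drift_amplitudes: tuple[float, ...] = (0.0,)
    b1_scales: tuple[float, ...] = (1.0,)
    offsets_hz: tuple[float | tuple[float, ...], ...] = (0.0,)
    n_voxels: int | None = None
    zone_length: float = 6.5e-3
    extra_members: tuple[FieldDistortion, ...] = ()

    @classmethod
    def voxel_grid(
        cls,
        n_voxels: int = 12,
        max_drift: float = 2.5e-5,
        zone_length: float = 6.5e-3,
    ) -> "EnsembleSpec":
        """Voxel centres spanning the detection zone, linear drift map.

        Voxel ``j`` at fractional position ``z_j`` sees peak drift
        ``2 * max_drift * z_j`` with ``z_j in (-1/2, 1/2)``, so the zone
        edges correspond to ``+-max_drift``.
        """
        if n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        z = (np.arange(n_voxels) + 0.5) / n_voxels - 0.5
        drifts = tuple(2.0 * max_drift * zi for zi in z)
        return cls(
            drift_amplitudes=drifts,
            n_voxels=n_voxels,
            zone_length=zone_length,
        )

    @classmethod
    def design_grid(
        cls,
        max_drift: float = 2.5e-5,
        n_drifts: int = 5,
        bandwidth_hz: float = 7000.0,
        n_offsets: int = 5,
        b1_span: float = 0.20,
        n_b1: int = 3,
    ) -> "EnsembleSpec":
        """The pulse-design robustness grid (drift x offset x B1)."""
        drifts = tuple(np.linspace(-max_drift, max_drift, n_drifts))
        offsets = tuple(np.linspace(-bandwidth_hz / 2, bandwidth_hz / 2, n_offsets))
        b1 = tuple(np.linspace(1.0 - b1_span, 1.0 + b1_span, n_b1))
        return cls(drift_amplitudes=drifts, b1_scales=b1, offsets_hz=offsets)

    @property
    def members(self) -> tuple[FieldDistortion, ...]:
        out = []
        for a, b1, off in itertools.product(
            self.drift_amplitudes, self.b1_scales, self.offsets_hz
        ):
            out.append(FieldDistortion(b0_drift=a, b1_scale=b1, offset_hz=off))
        return tuple(out) + self.extra_members

    @property
    def size(self) -> int:
        return (
            len(self.drift_amplitudes) * len(self.b1_scales) * len(self.offsets_hz)
            + len(self.extra_members)
        )

    def with_voxel_emphasis(
        self, n_extra: int = 8, max_drift: float = 2.5e-5
    ) -> "EnsembleSpec":
        """Append on-resonance, nominal-B1 drift members to the grid.

        Extra weight on the conditions under which locking trajectories
        are evaluated (linear voxel drifts, no offset, B1 = 1) without
        narrowing the robustness coverage of the product grid.
        """
        extras = tuple(
            FieldDistortion(b0_drift=a)
            for a in np.linspace(-max_drift, max_drift, n_extra)
        )
        return replace_dc(self, extra_members=self.extra_members + extras)

    def scaled_drift(self, factor: float) -> "EnsembleSpec":
        """Same grid with all drift amplitudes multiplied by ``factor``."""
        return EnsembleSpec(
            drift_amplitudes=tuple(factor * a for a in self.drift_amplitudes),
            b1_scales=self.b1_scales,
            offsets_hz=self.offsets_hz,
            n_voxels=self.n_voxels,
            zone_length=self.zone_length,
        )


# ---------------------------------------------------------------------------
# locking window


@dataclass(frozen=True)
class LockingWindow:
    """Simultaneous shaped RF pulse(s) + optional gradient drift.

    ``pulses`` maps channel label -> waveform object exposing
    ``x_hz``/``y_hz`` per-slice arrays, ``n_slices``, ``slice_dt`` and
    ``duration`` (see :class:`cohlock.cloc_design.ControlPulse`).
    All pulses and the gradient must share the window duration.
    """

    duration: float
    n_slices: int
    pulses: Mapping[str, object] = field(default_factory=dict)
    gradient: GradientEvent | None = None
    include_j: bool = True

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for ch, p in self.pulses.items():
            if abs(p.duration - self.duration) > 1e-12:
                raise ValueError(
                    f"pulse on {ch!r} (duration {p.duration}) is not "
                    f"time-aligned with the window (duration {self.duration})"
                )
            if p.n_slices != self.n_slices:
                raise ValueError("all pulses must share the window slice grid")
        if self.gradient is not None and abs(
            self.gradient.duration - self.duration
        ) > 1e-12:
            raise ValueError("gradient is not time-aligned with the window")

    @classmethod
    def from_pulses(
        cls,
        pulses: Mapping[str, object],
        gradient: GradientEvent | None = None,
        include_j: bool = True,
    ) -> "LockingWindow":
        if not pulses:
            raise ValueError("need at least one pulse; use free_evolution otherwise")
        p0 = next(iter(pulses.values()))
        return cls(
            duration=p0.duration,
            n_slices=p0.n_slices,
            pulses=dict(pulses),
            gradient=gradient,
            include_j=include_j,
        )

    @classmethod
    def free_evolution(
        cls,
        gradient: GradientEvent,
        slice_dt: float = DEFAULT_SLICE_DT,
        include_j: bool = True,
    ) -> "LockingWindow":
        n = max(1, int(round(gradient.duration / slice_dt)))
        return cls(
            duration=gradient.duration,
            n_slices=n,
            gradient=gradient,
            include_j=include_j,
        )

    @property
    def slice_dt(self) -> float:
        return self.duration / self.n_slices

    @property
    def midpoints(self) -> np.ndarray:
        dt = self.slice_dt
        return (np.arange(self.n_slices) + 0.5) * dt


def window_hamiltonians(
    window: LockingWindow,
    system: SpinSystem,
    members: Sequence[FieldDistortion],
) -> np.ndarray:
    """Per-slice Hamiltonians for every ensemble member, shape (M, S, d, d).

    Within a slice the RF amplitudes are constant and the gradient drift
    is evaluated at the slice midpoint.
    """
    m, s, d = len(members), window.n_slices, system.dim
    h = np.zeros((m, s, d, d), dtype=complex)

    iz = []
    for k in range(system.n_spins):
        fac = ["1"] * system.n_spins
        fac[k] = "z"
        iz.append(build_operator("".join(fac), system))

    prof = (
        window.gradient.slice_averages(s) * window.gradient.relative_amplitude
        if window.gradient is not None
        else np.zeros(s)
    )

    for i, mem in enumerate(members):
        extra = mem.offsets(system.n_spins)
        for k in range(system.n_spins):
            w_z = (
                TWO_PI * (system.offset_hz[k] + extra[k])
                + system.gamma[k] * mem.b0_drift * prof
            )  # (s,)
            h[i] += w_z[:, None, None] * iz[k]

    for ch, p in window.pulses.items():
        k = system.channel_index(ch)
        fx = ["1"] * system.n_spins
        fy = ["1"] * system.n_spins
        fx[k], fy[k] = "x", "y"
        ix = build_operator("".join(fx), system)
        iy = build_operator("".join(fy), system)
        x = np.asarray(p.x_hz, dtype=float)
        y = np.asarray(p.y_hz, dtype=float)
        for i, mem in enumerate(members):
            b1 = mem.b1_scale
            h[i] += TWO_PI * b1 * (
                x[:, None, None] * ix + y[:, None, None] * iy
            )

    if system.n_spins == 2 and window.include_j and system.j_coupling_hz() != 0.0:
        h += j_coupling(system, "weak")

    for i in range(m):
        if not np.allclose(h[i], h[i].conj().swapaxes(-1, -2), atol=1e-9):
            raise RuntimeError("non-Hermitian Hamiltonian slice")
    return h


def slice_propagators(
    window: LockingWindow,
    system: SpinSystem,
    members: Sequence[FieldDistortion],
) -> np.ndarray:
    """Per-slice unitaries, shape (M, S, d, d)."""
    h = window_hamiltonians(window, system, members)
    return expm_hermitian(h, window.slice_dt)


def window_propagator(
    window: LockingWindow,
    system: SpinSystem,
    member: FieldDistortion,
) -> np.ndarray:
    """Net unitary over the window for one ensemble member."""
    us = slice_propagators(window, system, [member])[0]
    u = np.eye(system.dim, dtype=complex)
    for k in range(us.shape[0]):
        u = us[k] @ u
    return u


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Overlap-vs-time series for each ensemble member plus their mean."""

    times: np.ndarray  # (S+1,)
    member_overlaps: np.ndarray  # (M, S+1)

    @property
    def mean(self) -> np.ndarray:
        return self.member_overlaps.mean(axis=0)

    @property
    def final(self) -> float:
        return float(self.mean[-1])

    def to_csv(self, path) -> None:
        import pandas as pd

        data = {"time_s": self.times}
        for i in range(self.member_overlaps.shape[0]):
            data[f"member_{i}"] = self.member_overlaps[i]
        data["mean"] = self.mean
        pd.DataFrame(data).to_csv(path, index=False)


def ensemble_trajectory(
    initial,
    window: LockingWindow,
    spec_or_members: EnsembleSpec | Sequence[FieldDistortion],
    system: SpinSystem,
    target=None,
) -> Trajectory:
    """Propagate an initial coherence through a window for every member.

    ``target`` defaults to the initial coherence; the returned trajectory
    holds ``Re<target|rho(t)>`` (self-normalised) per member per slice
    boundary.
    """
    members = (
        spec_or_members.members
        if isinstance(spec_or_members, EnsembleSpec)
        else tuple(spec_or_members)
    )
    if not members:
        raise ValueError("empty ensemble")
    target = initial if target is None else target
    rho0 = build_operator(initial, system)
    tmat = build_operator(target, system)
    tnorm2 = np.real(np.trace(tmat.conj().T @ tmat))

    us = slice_propagators(window, system, members)  # (M,S,d,d)
    m, s = us.shape[0], us.shape[1]
    out = np.empty((m, s + 1))
    rho = np.broadcast_to(rho0, (m,) + rho0.shape).copy()
    tdag = tmat.conj().T
    out[:, 0] = np.real(np.einsum("ij,mji->m", tdag, rho)) / tnorm2
    for k in range(s):
        uk = us[:, k]
        rho = uk @ rho @ uk.conj().swapaxes(-1, -2)
        out[:, k + 1] = np.real(np.einsum("ij,mji->m", tdag, rho)) / tnorm2
    times = np.arange(s + 1) * window.slice_dt
    return Trajectory(times=times, member_overlaps=out)


def propagate(
    initial,
    window: LockingWindow,
    member: FieldDistortion,
    system: SpinSystem,
    target=None,
) -> Trajectory:
    """Single-member trajectory (see :func:`ensemble_trajectory`)."""
    return ensemble_trajectory(initial, window, [member], system, target)


def ensemble_signal(
    initial,
    window: LockingWindow,
    spec: EnsembleSpec | Sequence[FieldDistortion],
    system: SpinSystem,
    target=None,
) -> float:
    """Mean final overlap over the ensemble (the detected signal)."""
    return ensemble_trajectory(initial, window, spec, system, target).final


def cyclicity_defect(
    pulse,
    member: FieldDistortion,
    system: SpinSystem | None = None,
    gradient: GradientEvent | None = None,
) -> float:
    """``1 - |Tr(U)| / 2**n`` for the net propagator over the pulse window.

    Zero iff the window acts as the identity up to a global phase.
    """
    if system is None:
        system = SpinSystem.single(pulse.channel)
    window = LockingWindow.from_pulses({pulse.channel: pulse}, gradient)
    u = window_propagator(window, system, member)
    return float(1.0 - abs(np.trace(u)) / system.dim)
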