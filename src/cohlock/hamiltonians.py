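"""Hamiltonian constructors: Zeeman drift, shaped-gradient drift, RF fields,
resonance offsets and heteronuclear scalar coupling.

All Hamiltonians are returned in angular-frequency units (rad/s) as dense
Hermitian matrices in the product basis of the given :class:`SpinSystem`.
Sign convention: the rotating-frame Hamiltonian is written ``+gamma*B*Iz``
(offset ``= +gamma*dB/2pi`` in Hz); propagators are ``exp(-i H t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spin_algebra import SpinSystem, build_operator

__all__ = [
    "GradientEvent",
    "FieldDistortion",
    "zeeman_drift",
    "gradient_drift",
    "offset_hamiltonian",
    "rf_hamiltonian",
    "j_coupling",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class GradientEvent:
    """A shaped gradient pulse seen as a time-dependent B0 drift.

    ``drift_scale`` is the peak equivalent B0 drift (Tesla) at the
    reference position for the pulse at 100 % amplitude;
    ``relative_amplitude`` scales it.  ``half_sine`` evaluates to
    ``sin(pi t/tau)`` on [0, tau]; ``trapezoid`` has symmetric ramps set
    so that the shape integral equals ``time_integral`` (default 0.9 ms
    for a 1 ms pulse).
    """

    shape: str = "half_sine"
    duration: float = 1.0e-3
    relative_amplitude: float = 1.0
    drift_scale: float = 2.5e-5
    time_integral: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("half_sine", "trapezoid"):
            raise ValueError(f"unknown gradient shape {self.shape!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.shape == "trapezoid":
            ti = self.time_integral
            if ti is None:
                ti = 0.9 * self.duration
                object.__setattr__(self, "time_integral", ti)
            if not 0.5 * self.duration <= ti <= self.duration:
                raise ValueError(
                    "trapezoid time_integral must lie in [tau/2, tau]"
                )
        elif self.time_integral is None:
            object.__setattr__(
                self, "time_integral", 2.0 * self.duration / np.pi
            )

    def profile(self, t: float | np.ndarray) -> np.ndarray:
        """Dimensionless shape value in [0, 1] at time ``t`` in [0, tau]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-15) or np.any(t > self.duration + 1e-15):
            raise ValueError("t outside [0, tau]")
        if self.shape == "half_sine":
            return np.sin(np.pi * t / self.duration)
        ramp = self.duration - self.time_integral  # rise = fall = ramp
        up = np.clip(t / ramp, 0.0, 1.0)
        down = np.clip((self.duration - t) / ramp, 0.0, 1.0)
        return np.minimum(up, down)

    def slice_averages(self, n_slices: int) -> np.ndarray:
        """Exact slice-averaged shape values on a uniform grid.

        Using the average (integral over the slice divided by its width)
        instead of the midpoint sample makes accumulated phases exact for
        commuting (drift-only) evolution.
        """
        edges = np.linspace(0.0, self.duration, n_slices + 1)
        if self.shape == "half_sine":
            ct = np.cos(np.pi * edges / self.duration)
            return (ct[:-1] - ct[1:]) * self.duration / (np.pi * np.diff(edges))
        # piecewise-linear trapezoid: dense sub-sampling per slice
        fine = np.linspace(0.0, self.duration, 40 * n_slices + 1)
        vals = self.profile(fine)
        cum = np.concatenate(
            [[0.0], np.cumsum(0.5 * (vals[1:] + vals[:-1]) * np.diff(fine))]
        )
        idx = np.searchsorted(fine, edges)
        return np.diff(cum[idx]) / np.diff(edges)

    def b0(self, t: float | np.ndarray) -> np.ndarray:
        """Equivalent B0 drift (Tesla) at time t."""
        return self.drift_scale * self.relative_amplitude * self.profile(t)

    @property
    def area(self) -> float:
        """Integral of the drift over the pulse, Tesla * s."""
        return self.drift_scale * self.relative_amplitude * self.time_integral


@dataclass(frozen=True)
class FieldDistortion:
    """One ensemble member: static B0 drift amplitude, B1 scale, offset.

    ``b0_drift`` is the peak (Tesla) of the member's drift profile — the
    time profile itself comes from the :class:`GradientEvent` it is paired
    with.  ``offset_hz`` may be a scalar (broadcast to all spins) or a
    per-spin tuple.
    """

    b0_drift: float = 0.0
    b1_scale: float = 1.0
    offset_hz: float | tuple[float, ...] = 0.0

    def __post_init__(self) -> None:
        if self.b1_scale <= 0:
            raise ValueError("b1_scale must be positive")

    def offsets(self, n_spins: int) -> tuple[float, ...]:
        if np.isscalar(self.offset_hz):
            return (float(self.offset_hz),) * n_spins
        off = tuple(float(o) for o in self.offset_hz)
        if len(off) != n_spins:
            raise ValueError("offset tuple length must match spin count")
        return off


def _iz(system: SpinSystem, k: int) -> np.ndarray:
    factors = ["1"] * system.n_spins
    factors[k] = "z"
    return build_operator("".join(factors), system)


def zeeman_drift(system: SpinSystem, b0: float) -> np.ndarray:
    """``sum_k gamma_k * b0 * Iz_k`` in rad/s.  Linear in b0."""
    if not np.isfinite(b0):
        raise ValueError("b0 must be finite")
    h = np.zeros((system.dim, system.dim), dtype=complex)
    for k in range(system.n_spins):
        h += system.gamma[k] * b0 * _iz(system, k)
    return h


def gradient_drift(
    event: GradientEvent, t: float, system: SpinSystem
) -> np.ndarray:
    """Drift Hamiltonian of a shaped gradient at time ``t`` in [0, tau]."""
    return zeeman_drift(system, float(event.b0(t)))


def offset_hamiltonian(
    system: SpinSystem, extra_hz: tuple[float, ...] | None = None
) -> np.ndarray:
    """Resonance-offset Hamiltonian ``sum_k 2pi(offset_k + extra_k) Iz_k``."""
    h = np.zeros((system.dim, system.dim), dtype=complex)
    extra = extra_hz or (0.0,) * system.n_spins
    for k in range(system.n_spins):
        h += TWO_PI * (system.offset_hz[k] + extra[k]) * _iz(system, k)
    return h


def rf_hamiltonian(
    system: SpinSystem,
    channel: str,
    amp_hz: float,
    phase: float = 0.0,
    b1_scale: float = 1.0,
) -> np.ndarray:
    """RF field ``2pi * amp * b1_scale * (cos(phi) Ix + sin(phi) Iy)`` on
    one channel; every other spin untouched."""
    if amp_hz < 0:
        raise ValueError("amp_hz must be non-negative")
    k = system.channel_index(channel)
    fx = ["1"] * system.n_spins
    fy = ["1"] * system.n_spins
    fx[k], fy[k] = "x", "y"
    ix = build_operator("".join(fx), system)
    iy = build_operator("".join(fy), system)
    w1 = TWO_PI * amp_hz * b1_scale
    return w1 * (np.cos(phase) * ix + np.sin(phase) * iy)


def j_coupling(system: SpinSystem, regime: str = "weak") -> np.ndarray:
    """Scalar-coupling Hamiltonian of a two-spin system.

    ``weak`` (secular heteronuclear form) returns ``2pi J IzSz``; ``full``
    returns the isotropic ``2pi J (IxSx + IySy + IzSz)``.
    """
    if system.n_spins != 2:
        raise ValueError("j_coupling requires a 2-spin system")
    if regime not in ("weak", "full"):
        raise ValueError(f"unknown regime {regime!r}")
    j = system.j_coupling_hz()
    h = TWO_PI * j * build_operator("zz", system)
    if regime == "full":
        h = h + TWO_PI * j * (
            build_operator("xx", system) + build_operator("yy", system)
        )
    return h
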