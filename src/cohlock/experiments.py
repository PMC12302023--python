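"""Sequence-level simulators and calibration fits.

Covers the desk-scale validation experiments:

* diffusion attenuation of a pulsed-gradient spin echo (gradient-strength
  calibration),
* the sinc signal decay caused by a neighbouring detector's gradient
  spilling a linear stray field across the detection zone (spillover-ratio
  calibration),
* gradient-selected heteronuclear 2D sequences (HSQC / HMQC variants)
  with coherence-pathway bookkeeping, spillover gradients and optional
  locking-pulse windows,
* robustness sweeps of a designed pulse along bandwidth / B1 / drift axes.

Pathway-selection gradients are ideal (instantaneous phase relabelling +
projection onto the declared coherence orders); spillover gradients and
locking windows act on the voxel ensemble.  Locking windows are excluded
from scalar-coupling evolution bookkeeping (the J delays of a sequence are
counted in its explicit delays only).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .hamiltonians import FieldDistortion, GradientEvent, j_coupling, offset_hamiltonian
from .propagation import (
    EnsembleSpec,
    LockingWindow,
    expm_hermitian,
    window_propagator,
)
from .spin_algebra import GAMMA, SpinSystem, build_operator

__all__ = [
    "PathwaySpec",
    "CalibrationCurve",
    "SequenceProgram",
    "HardPulse",
    "Delay",
    "PathwayGradient",
    "SpilloverGradient",
    "ClocWindow",
    "pathway_phase",
    "pgse_attenuation",
    "fit_pgse",
    "spillover_signal",
    "fit_spillover",
    "simulate_sequence",
    "scenario_signals",
    "pgse_program",
    "hsqc_program",
    "hmqc_program",
    "robustness_sweep",
    "FitResult",
    "program_from_config",
    "load_program",
]

SCENARIOS = ("reference", "coupled", "coupled_with_cloc")

GAMMA_H = GAMMA["1H"]


# ---------------------------------------------------------------------------
# coherence-pathway arithmetic


@dataclass(frozen=True)
class PathwaySpec:
    """Coherence orders per spin between gradients, plus gradient ratios.

    ``orders[i]`` is the per-spin coherence-order tuple in force while
    gradient ``i`` plays; ``ratios[i]`` is the signed relative amplitude
    of gradient ``i``.
    """

    orders: tuple[tuple[int, ...], ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.orders) != len(self.ratios):
            raise ValueError("orders and ratios must have equal length")


def _gamma_weights(system: SpinSystem, convention: str) -> tuple[float, ...]:
    if convention == "nominal4":
        table = {"1H": 4.0, "13C": 1.0}
        try:
            return tuple(table[lab] for lab in system.labels)
        except KeyError as exc:
            raise ValueError(
                f"nominal4 convention defined for 1H/13C only, got {exc}"
            ) from None
    if convention == "exact":
        ref = min(abs(g) for g in system.gamma)
        return tuple(g / ref for g in system.gamma)
    raise ValueError(f"unknown gamma convention {convention!r}")


def pathway_phase(
    pathway: PathwaySpec,
    system: SpinSystem,
    gamma_convention: str = "nominal4",
) -> float:
    """Net gradient phase of a coherence pathway, in units of the
    reference-gamma x unit-gradient moment.  Zero iff refocused."""
    w = _gamma_weights(system, gamma_convention)
    total = 0.0
    for orders, ratio in zip(pathway.orders, pathway.ratios):
        if len(orders) != system.n_spins:
            raise ValueError("pathway order tuple length must match spin count")
        total += ratio * sum(p * wk for p, wk in zip(orders, w))
    return total


# ---------------------------------------------------------------------------
# analytic calibration models


def pgse_attenuation(
    g_tm: float | np.ndarray,
    delta: float = 1.0e-3,
    big_delta: float = 7.0e-3,
    diffusion: float = 1.9e-9,
    gamma: float = GAMMA_H,
) -> np.ndarray:
    """Spin-echo diffusion attenuation ``exp(-gamma^2 delta^2 G^2 (Delta-delta) D)``.

    ``g_tm`` is the gradient amplitude in T/m; all times in seconds.
    """
    if delta <= 0 or big_delta <= 0 or diffusion <= 0:
        raise ValueError("delta, Delta and D must be positive")
    if big_delta <= delta:
        raise ValueError("Delta must exceed delta")
    g = np.asarray(g_tm, dtype=float)
    return np.exp(-(gamma**2) * delta**2 * g**2 * (big_delta - delta) * diffusion)


def spillover_signal(
    g: float | np.ndarray,
    rg: float = 1.9e-3,
    gmax_tm: float = 1.0306,
    zone_length: float = 6.5e-3,
    g_integral: float = 0.9e-3,
    gamma: float = GAMMA_H,
) -> np.ndarray:
    """Sinc decay of a pulse-acquire signal under a linear stray gradient.

    ``sin(k g)/(k g)`` with ``k = (l/2) * gamma * RG * Gmax * integral(g dt)``;
    continuous at g = 0.
    """
    k = 0.5 * zone_length * gamma * rg * gmax_tm * g_integral
    x = k * np.asarray(g, dtype=float)
    return np.sinc(x / np.pi)


# ---------------------------------------------------------------------------
# calibration data + least-squares fits


@dataclass
class CalibrationCurve:
    """(gradient fraction, signal intensity) pairs with a noise tag."""

    g: np.ndarray
    intensity: np.ndarray
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.g.shape != self.intensity.shape:
            raise ValueError("g and intensity must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if np.any(self.g < 0) or np.any(self.g > 1.0 + 1e-12):
            raise ValueError("g must be normalised to [0, 1]")

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"g": self.g, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, noise_sigma: float = 0.0) -> "CalibrationCurve":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["g"].to_numpy(), df["intensity"].to_numpy(), noise_sigma)


@dataclass(frozen=True)
class FitResult:
    estimate: float
    ci_low: float
    ci_high: float
    scale: float  # fitted I0
    name: str

    def __iter__(self):
        yield self.estimate
        yield (self.ci_low, self.ci_high)


def _bootstrap_ci(fit_once, g, resid, yhat, rng, n_boot):
    ests = []
    n = len(g)
    for _ in range(n_boot):
        y = yhat + resid[rng.integers(0, n, n)]
        try:
            ests.append(fit_once(g, y))
        except RuntimeError:
            continue
    if not ests:
        return np.nan, np.nan
    lo, hi = np.percentile(ests, [2.5, 97.5])
    return float(lo), float(hi)


def fit_pgse(
    curve: CalibrationCurve,
    delta: float = 1.0e-3,
    big_delta: float = 7.0e-3,
    diffusion: float | None = 1.9e-9,
    gmax_tm: float | None = None,
    gamma: float = GAMMA_H,
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Least-squares fit of the diffusion model with ``G = g * Gmax``.

    Exactly one of ``diffusion`` / ``gmax_tm`` must be ``None``: that one
    is fitted (together with the overall intensity scale).  Returns the
    estimate with a 95 % residual-bootstrap confidence interval.
    """
    if (diffusion is None) == (gmax_tm is None):
        raise ValueError("exactly one of diffusion/gmax_tm must be unknown (None)")
    if len(curve.g) < 4:
        raise ValueError("need at least 4 points")
    if np.allclose(curve.g, curve.g[0]):
        raise ValueError("degenerate curve: all g equal")

    if gmax_tm is None:
        name = "gmax_tm"

        def model(g, i0, p):
            return i0 * pgse_attenuation(g * p, delta, big_delta, diffusion, gamma)

        p0 = (float(np.max(curve.intensity)), 1.0)
    else:
        name = "diffusion"

        def model(g, i0, p):
            return i0 * pgse_attenuation(g * gmax_tm, delta, big_delta, p, gamma)

        p0 = (float(np.max(curve.intensity)), 1e-9)

    def fit_once(g, y):
        popt, _ = curve_fit(model, g, y, p0=p0, maxfev=20000)
        return popt[1]

    popt, _ = curve_fit(model, curve.g, curve.intensity, p0=p0, maxfev=20000)
    yhat = model(curve.g, *popt)
    resid = curve.intensity - yhat
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_ci(fit_once, curve.g, resid, yhat, rng, n_boot)
    return FitResult(float(popt[1]), lo, hi, float(popt[0]), name)


def fit_spillover(
    curve: CalibrationCurve,
    gmax_tm: float = 1.0306,
    zone_length: float = 6.5e-3,
    g_integral: float = 0.9e-3,
    gamma: float = GAMMA_H,
    n_boot: int = 200,
    seed: int = 0,
) -> FitResult:
    """Fit the spillover ratio RG of the sinc decay model."""
    if len(curve.g) < 4:
        raise ValueError("need at least 4 points")
    if np.allclose(curve.g, curve.g[0]):
        raise ValueError("degenerate curve: all g equal")

    def model(g, i0, rg):
        return i0 * spillover_signal(g, rg, gmax_tm, zone_length, g_integral, gamma)

    p0 = (float(np.max(curve.intensity)), 1e-3)

    def fit_once(g, y):
        popt, _ = curve_fit(model, g, y, p0=p0, maxfev=20000)
        return popt[1]

    popt, _ = curve_fit(model, curve.g, curve.intensity, p0=p0, maxfev=20000)
    yhat = model(curve.g, *popt)
    resid = curve.intensity - yhat
    rng = np.random.default_rng(seed)
    lo, hi = _bootstrap_ci(fit_once, curve.g, resid, yhat, rng, n_boot)
    return FitResult(float(popt[1]), lo, hi, float(popt[0]), "rg")


# ---------------------------------------------------------------------------
# sequence events


@dataclass(frozen=True)
class HardPulse:
    """Ideal zero-duration rotation on one channel."""

    channel: str
    angle: float  # rad
    phase: float = 0.0
    scenarios: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Delay:
    """Free evolution under offsets and (for 2 spins) weak J coupling."""

    duration: float
    scenarios: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PathwayGradient:
    """In-detector pathway-selection gradient: instantaneous, ideal.

    Projects the state onto the coherence orders of pathway step ``step``
    and imprints the order- and voxel-dependent phase ``ratio * phi_unit *
    z_frac`` weighted by the gamma convention.
    """

    ratio: float
    step: int
    scenarios: tuple[str, ...] | None = None


@dataclass(frozen=True)
class SpilloverGradient:
    """Stray gradient from a neighbouring detector: pure z-phase per voxel."""

    event: GradientEvent
    scenarios: tuple[str, ...] | None = ("coupled",)


@dataclass(frozen=True)
class ClocWindow:
    """Locking pulse(s) time-aligned with a spillover gradient."""

    gradient: GradientEvent
    pulses: Mapping[str, object]
    scenarios: tuple[str, ...] | None = ("coupled_with_cloc",)

    def window(self) -> LockingWindow:
        return LockingWindow.from_pulses(
            dict(self.pulses), self.gradient, include_j=False
        )


@dataclass(frozen=True)
class SequenceProgram:
    """Ordered events plus the pathway and acquisition target."""

    events: tuple
    pathway: PathwaySpec
    initial: str
    target: str
    gamma_convention: str = "nominal4"
    phi_unit: float = 30.0  # rad of unit-ratio crusher phase at zone edge
    receiver_phase: float = 0.0  # rad; detected signal is Re(e^{i phi} <T|rho>)

    def events_for(self, scenario: str):
        if scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {scenario!r}")
        out = []
        for ev in self.events:
            if ev.scenarios is None or scenario in ev.scenarios:
                out.append(ev)
        return out


# ---------------------------------------------------------------------------
# simulator


def _order_table(system: SpinSystem) -> np.ndarray:
    """Per-element per-spin coherence orders, shape (d, d, n_spins)."""
    n = system.n_spins
    ms = []  # magnetic quantum number per basis state per spin
    for idx in range(system.dim):
        bits = [(idx >> (n - 1 - k)) & 1 for k in range(n)]
        ms.append([0.5 - b for b in bits])
    ms = np.array(ms)  # (d, n)
    return ms[:, None, :] - ms[None, :, :]


def _rotation(system: SpinSystem, channel: str, angle: float, phase: float):
    k = system.channel_index(channel)
    fx = ["1"] * system.n_spins
    fy = ["1"] * system.n_spins
    fx[k], fy[k] = "x", "y"
    gen = np.cos(phase) * build_operator("".join(fx), system) + np.sin(
        phase
    ) * build_operator("".join(fy), system)
    return expm_hermitian(gen, angle)


def _free_unitary(system: SpinSystem, duration: float):
    h = offset_hamiltonian(system)
    if system.n_spins == 2 and system.j_coupling_hz() != 0.0:
        h = h + j_coupling(system, "weak")
    return expm_hermitian(h, duration)


def _zphase_unitary(system: SpinSystem, phis: Sequence[float], orders):
    """Diagonal unitary multiplying each element by exp(-i sum_s p_s phi_s)."""
    d = system.dim
    phase = np.zeros((d, d))
    for s in range(system.n_spins):
        phase += orders[:, :, s] * phis[s]
    return np.exp(-1.0j * phase)


def _voxel_fractions(spec: EnsembleSpec) -> np.ndarray:
    n = spec.n_voxels
    if n is None:
        raise ValueError("sequence simulation needs a voxel-grid EnsembleSpec")
    return (np.arange(n) + 0.5) / n - 0.5


def _run_scenario(
    program: SequenceProgram,
    system: SpinSystem,
    spec: EnsembleSpec,
    scenario: str,
) -> float:
    events = program.events_for(scenario)
    orders = _order_table(system)
    zfrac = _voxel_fractions(spec)
    drifts = np.asarray(spec.drift_amplitudes)  # peak spillover drift per voxel
    if len(drifts) != len(zfrac):
        raise ValueError("EnsembleSpec must be a voxel grid (one drift per voxel)")
    w = _gamma_weights(system, program.gamma_convention)

    # validate locking windows once (raises on misalignment)
    for ev in events:
        if isinstance(ev, ClocWindow):
            ev.window()

    signals = np.empty(len(zfrac))
    rho0 = build_operator(program.initial, system)
    tmat = build_operator(program.target, system)
    tnorm2 = np.real(np.trace(tmat.conj().T @ tmat))
    rx = np.exp(1.0j * program.receiver_phase)
    for j, (zf, aj) in enumerate(zip(zfrac, drifts)):
        rho = rho0.copy()
        for ev in events:
            if isinstance(ev, HardPulse):
                u = _rotation(system, ev.channel, ev.angle, ev.phase)
                rho = u @ rho @ u.conj().T
            elif isinstance(ev, Delay):
                u = _free_unitary(system, ev.duration)
                rho = u @ rho @ u.conj().T
            elif isinstance(ev, PathwayGradient):
                step = program.pathway.orders[ev.step]
                mask = np.all(
                    orders == np.asarray(step)[None, None, :], axis=-1
                )
                rho = np.where(mask, rho, 0.0)
                phis = [wk * ev.ratio * program.phi_unit * 2.0 * zf for wk in w]
                dphase = _zphase_unitary(system, phis, orders)
                rho = dphase * rho
            elif isinstance(ev, SpilloverGradient):
                phi = aj * ev.event.relative_amplitude * ev.event.time_integral
                phis = [g * phi for g in system.gamma]
                dphase = _zphase_unitary(system, phis, orders)
                rho = dphase * rho
            elif isinstance(ev, ClocWindow):
                member = FieldDistortion(b0_drift=aj)
                u = window_propagator(ev.window(), system, member)
                rho = u @ rho @ u.conj().T
            else:
                raise TypeError(f"unknown event {ev!r}")
        signals[j] = np.real(rx * np.trace(tmat.conj().T @ rho) / tnorm2)
    return float(signals.mean())


def simulate_sequence(
    program: SequenceProgram,
    system: SpinSystem,
    spec: EnsembleSpec,
    scenario: str = "reference",
) -> float:
    """Ensemble-mean acquired signal, normalised to the reference scenario."""
    ref = _run_scenario(program, system, spec, "reference")
    if scenario == "reference":
        return 1.0 if ref != 0 else 0.0
    sig = _run_scenario(program, system, spec, scenario)
    if ref == 0:
        raise ValueError("reference scenario produced zero signal")
    return sig / ref


def scenario_signals(
    program: SequenceProgram, system: SpinSystem, spec: EnsembleSpec
) -> dict[str, float]:
    """All three scenario signals, normalised to the reference."""
    return {sc: simulate_sequence(program, system, spec, sc) for sc in SCENARIOS}


# ---------------------------------------------------------------------------
# program builders


def pgse_program(
    gc_amplitude: float,
    spill_gradient: GradientEvent | None = None,
    gc_ratios: tuple[float, float] = (1.0, -1.0),
    cloc_pulse=None,
    phi_unit: float = 30.0,
) -> SequenceProgram:
    """Spin echo with primary balanced gradients plus a coupled stray pair.

    The stray pair plays once on each side of the inversion pulse with
    signed relative amplitudes ``gc_ratios * gc_amplitude`` (the default
    opposite-sign pair models a neighbouring echo sequence of opposite
    gradient polarity, whose spillover does *not* self-refocus along the
    ``I+ -> I-`` pathway).  With a locking pulse supplied, one locking
    window is aligned with each stray block.
    """
    if spill_gradient is None:
        spill_gradient = GradientEvent(shape="trapezoid", drift_scale=1.0)
    g1 = replace(
        spill_gradient, relative_amplitude=gc_ratios[0] * gc_amplitude
    )
    g2 = replace(
        spill_gradient, relative_amplitude=gc_ratios[1] * gc_amplitude
    )
    events: list = [
        HardPulse("1H", np.pi / 2, np.pi / 2),  # Iz -> I+/I- superposition (Ix)
        PathwayGradient(ratio=1.0, step=0),
        SpilloverGradient(g1),
    ]
    if cloc_pulse is not None:
        events.append(ClocWindow(g1, {cloc_pulse.channel: cloc_pulse}))
    events += [
        HardPulse("1H", np.pi, 0.0),
        SpilloverGradient(g2),
    ]
    if cloc_pulse is not None:
        events.append(ClocWindow(g2, {cloc_pulse.channel: cloc_pulse}))
    events.append(PathwayGradient(ratio=1.0, step=1))
    pathway = PathwaySpec(orders=((1,), (-1,)), ratios=(1.0, 1.0))
    return SequenceProgram(
        events=tuple(events),
        pathway=pathway,
        initial="z",
        target="-",
        phi_unit=phi_unit,
    )


def _inept(delta: float):
    """Delay - simultaneous pi - delay block (J refocused into antiphase)."""
    return [
        Delay(delta),
        HardPulse("1H", np.pi, 0.0),
        HardPulse("13C", np.pi, 0.0),
        Delay(delta),
    ]


def hsqc_program(
    gc_amplitude: float,
    j_hz: float = 145.0,
    ratios: tuple[float, float] = (4.0, 1.0),
    pathway_orders: tuple[tuple[int, int], ...] = ((0, 1), (-1, 0)),
    coupled_ratios: tuple[float, float] = (4.0, -1.0),
    spill_gradient: GradientEvent | None = None,
    cloc_pulses: Mapping[int, object] | None = None,
    phi_unit: float = 30.0,
) -> SequenceProgram:
    """Gradient-selected two-spin HSQC with spillover from a neighbour.

    Detector 1 selects its pathway with gradient amplitudes ``ratios``
    (e.g. 4:1 for ``S+ -> I-``); the neighbouring detector runs the
    mirrored experiment with ``coupled_ratios`` (e.g. 4:-1), whose stray
    field dephases the local coherences.  ``cloc_pulses`` maps pathway
    step index -> locking pulse; the pulse channel must match the spin
    carrying coherence during that step (13C first, 1H last).
    """
    if spill_gradient is None:
        spill_gradient = GradientEvent(shape="trapezoid", drift_scale=1.0)
    delta = 1.0 / (4.0 * j_hz)
    cloc_pulses = dict(cloc_pulses or {})

    events: list = [HardPulse("1H", np.pi / 2, 0.0)]
    events += _inept(delta)  # -> antiphase 2IxSz (up to phases)
    events += [HardPulse("1H", np.pi / 2, np.pi / 2), HardPulse("13C", np.pi / 2, 0.0)]
    # t1 = 0: no evolution period; S coherence selected by gradient 1
    for step, (ratio, cratio) in enumerate(zip(ratios, coupled_ratios)):
        if step == len(ratios) - 1:
            # back-transfer before the final (refocusing) gradient
            events += [
                HardPulse("13C", np.pi / 2, 0.0),
                HardPulse("1H", np.pi / 2, 0.0),
            ]
            events += _inept(delta)
        events.append(PathwayGradient(ratio=ratio, step=step))
        gspill = replace(spill_gradient, relative_amplitude=cratio * gc_amplitude)
        events.append(SpilloverGradient(gspill))
        if step in cloc_pulses:
            p = cloc_pulses[step]
            events.append(ClocWindow(gspill, {p.channel: p}))
    pathway = PathwaySpec(orders=pathway_orders, ratios=ratios)
    return SequenceProgram(
        events=tuple(events),
        pathway=pathway,
        initial="z1",
        target="-1",
        phi_unit=phi_unit,
    )


def hmqc_program(
    gc_amplitude: float,
    j_hz: float = 145.0,
    ratios: tuple[float, float] = (4.0, 5.0),
    spill_gradient: GradientEvent | None = None,
    cloc_pulses: Mapping[int, object] | None = None,
    phi_unit: float = 30.0,
) -> SequenceProgram:
    """Double-quantum variant: the first gradient plays on ``I+S+``.

    The 4:5 ratio refocuses the ``I+S+ -> I-`` pathway under the nominal
    gamma ratio (weight 4+1 = 5 against 4).  Locking the double-quantum
    coherence requires simultaneous pulses on both channels, supplied as
    ``cloc_pulses = {0: (pulse_1h, pulse_13c), 1: pulse_1h}``.
    """
    if spill_gradient is None:
        spill_gradient = GradientEvent(shape="trapezoid", drift_scale=1.0)
    delta = 1.0 / (2.0 * j_hz)
    cloc_pulses = dict(cloc_pulses or {})

    events: list = [
        HardPulse("1H", np.pi / 2, 0.0),
        Delay(delta),  # antiphase 2IxSz
        HardPulse("13C", np.pi / 2, 0.0),  # -> MQ (DQ+ZQ mixture)
    ]
    pathway_orders = ((1, 1), (-1, 0))
    for step, ratio in enumerate(ratios):
        if step == len(ratios) - 1:
            events += [
                HardPulse("13C", np.pi / 2, 0.0),
                Delay(delta),
                HardPulse("1H", np.pi, 0.0),
            ]
        events.append(PathwayGradient(ratio=ratio, step=step))
        gspill = replace(spill_gradient, relative_amplitude=gc_amplitude)
        events.append(SpilloverGradient(gspill))
        if step in cloc_pulses:
            ps = cloc_pulses[step]
            if not isinstance(ps, (tuple, list)):
                ps = (ps,)
            events.append(ClocWindow(gspill, {p.channel: p for p in ps}))
    pathway = PathwaySpec(orders=pathway_orders, ratios=ratios)
    return SequenceProgram(
        events=tuple(events),
        pathway=pathway,
        initial="z1",
        target="-1",
        phi_unit=phi_unit,
        receiver_phase=-np.pi / 2,
    )


# ---------------------------------------------------------------------------
# robustness sweeps


def robustness_sweep(pulse, axis: str, values: Sequence[float], spec):
    """Fidelity (and chi where meaningful) of a pulse along one axis.

    ``spec`` is an :class:`cohlock.cloc_design.OptimizationSpec`; each
    grid point replaces the corresponding ensemble dimension with the
    single swept value.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .aht import toggling_tensor
    from .cloc_design import fidelity

    rows = []
    ens = spec.ensemble
    for v in values:
        if axis in ("bandwidth", "offset"):
            e = replace(ens, offsets_hz=(float(v),))
            chi_v = toggling_tensor(pulse, float(v), 1.0).chi
        elif axis == "b1":
            e = replace(ens, b1_scales=(float(v),))
            chi_v = toggling_tensor(pulse, 0.0, float(v)).chi
        elif axis == "drift_amplitude":
            e = replace(ens, drift_amplitudes=(float(v), -float(v)))
            chi_v = toggling_tensor(pulse, 0.0, 1.0).chi
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        f = fidelity(pulse, replace(spec, ensemble=e))
        rows.append({"axis": axis, "value": float(v), "fidelity": f, "chi": chi_v})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence-program configuration files


def program_from_config(cfg: dict) -> SequenceProgram:
    """Build a :class:`SequenceProgram` from a plain-dict (YAML-able) config.

    Schema::

        initial: "z1"            # coherence labels, one factor per spin
        target: "-1"
        gamma_convention: nominal4   # optional
        phi_unit: 30.0               # optional, rad
        receiver_phase_deg: 0.0      # optional
        pathway:
          orders: [[0, 1], [-1, 0]]
          ratios: [4, 1]
        events:
          - {type: hard_pulse, channel: "1H", angle_deg: 90, phase_deg: 0}
          - {type: delay, duration: 1.724e-3}
          - {type: pathway_gradient, ratio: 4, step: 0}
          - {type: spillover_gradient, shape: trapezoid, duration: 1.0e-3,
             relative_amplitude: 0.95, scenarios: [coupled]}
          - {type: cloc_window, shape_files: {"13C": "cl1.jcamp"},
             gradient: {shape: trapezoid, duration: 1.0e-3,
                        relative_amplitude: 0.95}}

    Angles in config files are degrees (internal maths is radians); shaped
    pulses are referenced by file path and read with the shape reader.
    """
    events: list = []
    for ev in cfg["events"]:
        kind = ev["type"]
        scen = tuple(ev["scenarios"]) if "scenarios" in ev else None
        if kind == "hard_pulse":
            events.append(
                HardPulse(
                    channel=ev["channel"],
                    angle=np.radians(float(ev["angle_deg"])),
                    phase=np.radians(float(ev.get("phase_deg", 0.0))),
                    scenarios=scen,
                )
            )
        elif kind == "delay":
            events.append(Delay(duration=float(ev["duration"]), scenarios=scen))
        elif kind == "pathway_gradient":
            events.append(
                PathwayGradient(
                    ratio=float(ev["ratio"]), step=int(ev["step"]), scenarios=scen
                )
            )
        elif kind == "spillover_gradient":
            gcfg = {k: v for k, v in ev.items() if k not in ("type", "scenarios")}
            events.append(
                SpilloverGradient(
                    event=GradientEvent(**gcfg),
                    scenarios=scen or ("coupled",),
                )
            )
        elif kind == "cloc_window":
            from .io_cli.shapes import read_shape

            pulses = {
                ch: read_shape(path) for ch, path in ev["shape_files"].items()
            }
            events.append(
                ClocWindow(
                    gradient=GradientEvent(**ev["gradient"]),
                    pulses=pulses,
                    scenarios=scen or ("coupled_with_cloc",),
                )
            )
        else:
            raise ValueError(f"unknown event type {kind!r}")
    pw = cfg["pathway"]
    pathway = PathwaySpec(
        orders=tuple(tuple(int(p) for p in row) for row in pw["orders"]),
        ratios=tuple(float(r) for r in pw["ratios"]),
    )
    return SequenceProgram(
        events=tuple(events),
        pathway=pathway,
        initial=cfg["initial"],
        target=cfg["target"],
        gamma_convention=cfg.get("gamma_convention", "nominal4"),
        phi_unit=float(cfg.get("phi_unit", 30.0)),
        receiver_phase=np.radians(float(cfg.get("receiver_phase_deg", 0.0))),
    )


def load_program(path) -> SequenceProgram:
    """Read a YAML sequence-program file (see :func:`program_from_config`)."""
    import yaml

    with open(path) as fh:
        return program_from_config(yaml.safe_load(fh))
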