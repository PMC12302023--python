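"""Residual heteronuclear coupling under a locking pulse, to first order.

The weak heteronuclear coupling ``2 pi J IzSz`` is transformed into the
toggling frame of the RF-plus-offset propagator.  For single-channel
irradiation the toggled ``Iz`` stays a unit 3-vector ``c(t)``; for
dual-channel irradiation the coupling becomes the 3x3 outer-product
tensor of the two toggled z-directions.  The time average ``c_bar`` gives
the first-order effective coupling, and its (Euclidean / Frobenius) norm
is the coupling scale factor ``chi`` in [0, 1]: 1 means the coupling is
fully retained, 0 means perfect decoupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hamiltonians import TWO_PI
from .propagation import expm_hermitian

__all__ = ["ToggleTensor", "toggling_tensor", "chi", "chi_table", "negligibility"]

_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)
_PAULI_HALF = (_SX, _SY, _SZ)


@dataclass
class ToggleTensor:
    """Toggling-frame coupling coefficients and their time average.

    ``c`` has shape (S, 3) for single-channel irradiation or (S, 3, 3)
    for dual-channel; ``cbar`` is the per-slice arithmetic mean.
    """

    times: np.ndarray
    c: np.ndarray
    n_channels: int

    @property
    def cbar(self) -> np.ndarray:
        return self.c.mean(axis=0)

    @property
    def chi(self) -> float:
        """Euclidean (Frobenius) norm of the averaged tensor."""
        return float(np.linalg.norm(self.cbar))


def _toggled_z(pulse, offset_hz: float, b1_scale: float) -> np.ndarray:
    """Unit 3-vector series: the z operator toggled by RF + offset.

    Evaluated at slice midpoints to match the propagation discretisation.
    """
    x = np.asarray(pulse.x_hz, float)
    y = np.asarray(pulse.y_hz, float)
    s = x.shape[0]
    dt = pulse.slice_dt
    h = (
        TWO_PI * offset_hz * _SZ
        + TWO_PI * b1_scale * (x[:, None, None] * _SX + y[:, None, None] * _SY)
    )
    u_half = expm_hermitian(h, dt / 2.0)
    u_full = expm_hermitian(h, dt)
    c = np.empty((s, 3))
    u = np.eye(2, dtype=complex)
    for k in range(s):
        um = u_half[k] @ u
        a = um.conj().T @ _SZ @ um
        for j, op in enumerate(_PAULI_HALF):
            c[k, j] = 2.0 * np.real(np.trace(op @ a))
        u = u_full[k] @ u
    return c


def toggling_tensor(
    pulses,
    offset_hz: float | tuple[float, float] = 0.0,
    b1_scale: float | tuple[float, float] = 1.0,
) -> ToggleTensor:
    """Toggling-frame coupling tensor of one or two locking pulses.

    ``pulses`` is a single waveform (single-channel irradiation: the
    other spin is untouched, so the tensor is the toggled z 3-vector) or
    a pair of waveforms applied simultaneously on the two channels
    (3x3 outer-product tensor).  Scalars for ``offset_hz``/``b1_scale``
    are broadcast to both channels ("nu0 and nu1 aligned").
    """
    if isinstance(pulses, (tuple, list)):
        if len(pulses) > 2:
            raise ValueError("at most 2 channels supported")
        if len(pulses) == 1:
            return toggling_tensor(pulses[0], offset_hz, b1_scale)
        p1, p2 = pulses
        if p1.n_slices != p2.n_slices or abs(p1.slice_dt - p2.slice_dt) > 1e-15:
            raise ValueError("dual-channel pulses must share the slice grid")
        off = (offset_hz, offset_hz) if np.isscalar(offset_hz) else offset_hz
        b1 = (b1_scale, b1_scale) if np.isscalar(b1_scale) else b1_scale
        ci = _toggled_z(p1, off[0], b1[0])
        cs = _toggled_z(p2, off[1], b1[1])
        c = np.einsum("tk,tl->tkl", ci, cs)
        times = (np.arange(p1.n_slices) + 0.5) * p1.slice_dt
        return ToggleTensor(times=times, c=c, n_channels=2)

    c = _toggled_z(pulses, float(offset_hz), float(b1_scale))
    times = (np.arange(pulses.n_slices) + 0.5) * pulses.slice_dt
    return ToggleTensor(times=times, c=c, n_channels=1)


def chi(
    pulses,
    offsets_hz: Sequence[float],
    b1_scales: Sequence[float],
) -> np.ndarray:
    """Coupling scale factor on an offset x B1 grid.

    Returns an array of shape ``(len(offsets_hz), len(b1_scales))``.
    """
    offsets_hz = list(offsets_hz)
    b1_scales = list(b1_scales)
    if not offsets_hz or not b1_scales:
        raise ValueError("empty grid")
    out = np.empty((len(offsets_hz), len(b1_scales)))
    for i, off in enumerate(offsets_hz):
        for j, b1 in enumerate(b1_scales):
            out[i, j] = toggling_tensor(pulses, off, b1).chi
    return out


def chi_table(pulses, offsets_hz, b1_scales):
    """Long-format table (offset_hz, b1_scale, chi) for CSV export."""
    import pandas as pd

    grid = chi(pulses, offsets_hz, b1_scales)
    rows = [
        {"offset_hz": off, "b1_scale": b1, "chi": grid[i, j]}
        for i, off in enumerate(offsets_hz)
        for j, b1 in enumerate(b1_scales)
    ]
    return pd.DataFrame(rows)


def negligibility(
    chi_value: float, j_hz: float, tau_s: float, threshold: float = 0.05
) -> tuple[float, bool]:
    """Residual coupling evolution ``chi * J * tau`` in cycles, with verdict.

    The coupling can be ignored over the locking window when the product
    is much smaller than one cycle (default threshold 0.05).
    """
    if chi_value < 0 or j_hz < 0 or tau_s < 0:
        raise ValueError("inputs must be non-negative")
    product = chi_value * j_hz * tau_s
    return product, bool(product < threshold)
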