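"""Product-operator algebra for one- and two-spin-1/2 systems.

Every coherence handled by the package (``I+``, ``I-``, ``Iz``, ``S+``,
``I-S+`` ...) is expressed as a short label string, one factor character
per spin, drawn from ``{1, x, y, z, +, -}``.  Operators are dense complex
matrices built by Kronecker products of the single-spin factors.

Conventions (fixed once, used everywhere):

* ``+`` means ``Ix + i*Iy`` (raising under the +1 coherence order tag),
  ``-`` means ``Ix - i*Iy``.
* The inner product is ``<A|B> = Tr(A^dagger B)``; :func:`overlap`
  self-normalises against the target so that ``overlap(T, T) == 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np

__all__ = [
    "GAMMA",
    "SpinSystem",
    "CoherenceLabel",
    "build_operator",
    "coherence_order",
    "overlap",
    "norm",
]

# gyromagnetic ratios, rad s^-1 T^-1
GAMMA: dict[str, float] = {
    "1H": 2.675e8,
    "13C": 0.67262e8,
    "15N": -0.27116e8,
    "19F": 2.5162e8,
}

_I2 = np.eye(2, dtype=complex)
_SX = 0.5 * np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex)
_SY = 0.5 * np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex)
_SZ = 0.5 * np.array([[1.0, 0.0], [0.0, -1.0]], dtype=complex)

_FACTORS: dict[str, np.ndarray] = {
    "1": _I2,
    "x": _SX,
    "y": _SY,
    "z": _SZ,
    "+": _SX + 1.0j * _SY,
    "-": _SX - 1.0j * _SY,
}

_ORDERS: dict[str, int] = {"1": 0, "x": 0, "y": 0, "z": 0, "+": 1, "-": -1}


@dataclass(frozen=True)
class SpinSystem:
    """Isotope labels, gyromagnetic ratios, offsets and scalar couplings.

    Parameters
    ----------
    labels
        Isotope name per spin, e.g. ``("1H",)`` or ``("1H", "13C")``.
    gamma
        Gyromagnetic ratio per spin in rad s^-1 T^-1.  Defaults looked up
        from :data:`GAMMA` by label.
    offset_hz
        Resonance offset per spin in Hz (rotating frame).
    j_hz
        Symmetric scalar-coupling table in Hz with zero diagonal.
    """

    labels: tuple[str, ...]
    gamma: tuple[float, ...] = ()
    offset_hz: tuple[float, ...] = ()
    j_hz: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not 1 <= n <= 2:
            raise ValueError(f"1 or 2 spins supported, got {n}")
        if not self.gamma:
            object.__setattr__(
                self, "gamma", tuple(GAMMA[lab] for lab in self.labels)
            )
        if not self.offset_hz:
            object.__setattr__(self, "offset_hz", (0.0,) * n)
        if not self.j_hz:
            object.__setattr__(
                self, "j_hz", tuple(tuple(0.0 for _ in range(n)) for _ in range(n))
            )
        if len(self.gamma) != n or len(self.offset_hz) != n:
            raise ValueError("gamma/offset_hz length must match labels")
        j = np.asarray(self.j_hz, dtype=float)
        if j.shape != (n, n):
            raise ValueError("j_hz must be n x n")
        if np.any(np.diag(j) != 0.0):
            raise ValueError("j_hz diagonal must be zero")
        if not np.allclose(j, j.T):
            raise ValueError("j_hz must be symmetric")

    # -- convenience constructors -------------------------------------

    @classmethod
    def single(cls, label: str = "1H", offset_hz: float = 0.0) -> "SpinSystem":
        return cls(labels=(label,), offset_hz=(offset_hz,))

    @classmethod
    def heteronuclear(
        cls,
        labels: tuple[str, str] = ("1H", "13C"),
        j_hz: float = 145.0,
        offsets_hz: tuple[float, float] = (0.0, 0.0),
    ) -> "SpinSystem":
        """IS pair (defaults: 1H-13C, J = 145 Hz, both on resonance)."""
        return cls(
            labels=labels,
            offset_hz=offsets_hz,
            j_hz=((0.0, j_hz), (j_hz, 0.0)),
        )

    @property
    def n_spins(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return 2 ** self.n_spins

    def channel_index(self, channel: str) -> int:
        try:
            return self.labels.index(channel)
        except ValueError:
            raise KeyError(
                f"channel {channel!r} not in system {self.labels}"
            ) from None

    def j_coupling_hz(self) -> float:
        """The single scalar coupling of a two-spin system, Hz."""
        if self.n_spins != 2:
            raise ValueError("j_coupling_hz requires a 2-spin system")
        return float(self.j_hz[0][1])


@dataclass(frozen=True)
class CoherenceLabel:
    """A product-operator label: one factor character per spin."""

    factors: tuple[str, ...]
    convention: str = "plus=x+iy"

    def __post_init__(self) -> None:
        for f in self.factors:
            if f not in _FACTORS:
                raise ValueError(f"unknown factor symbol {f!r}")

    @classmethod
    def parse(cls, label: "CoherenceLabel | str") -> "CoherenceLabel":
        if isinstance(label, CoherenceLabel):
            return label
        return cls(factors=tuple(label))

    def __str__(self) -> str:
        return "".join(self.factors)

    @property
    def order(self) -> int:
        return sum(_ORDERS[f] for f in self.factors)

    @property
    def orders(self) -> tuple[int, ...]:
        """Per-spin coherence orders."""
        return tuple(_ORDERS[f] for f in self.factors)


def build_operator(
    label: CoherenceLabel | str, system: SpinSystem | int | None = None
) -> np.ndarray:
    """Dense matrix of the product operator named by ``label``.

    ``system`` may be a :class:`SpinSystem`, a spin count, or ``None``
    (arity taken from the label itself).  Raises on arity mismatch.
    """
    lab = CoherenceLabel.parse(label)
    n = len(lab.factors)
    if isinstance(system, SpinSystem):
        if system.n_spins != n:
            raise ValueError(
                f"label arity {n} does not match system size {system.n_spins}"
            )
    elif isinstance(system, int) and system != n:
        raise ValueError(f"label arity {n} does not match requested size {system}")
    return reduce(np.kron, (_FACTORS[f] for f in lab.factors))


def coherence_order(label: CoherenceLabel | str) -> int:
    """Net coherence order: sum of per-spin orders (+1 for '+', -1 for '-')."""
    return CoherenceLabel.parse(label).order


def norm(state: np.ndarray) -> float:
    """Frobenius norm sqrt(Tr(A^dagger A))."""
    return float(np.sqrt(np.real(np.trace(state.conj().T @ state))))


def overlap(
    state: np.ndarray,
    target: CoherenceLabel | str | np.ndarray,
    system: SpinSystem | int | None = None,
) -> float:
    """Real part of the self-normalised inner product of state onto target.

    Returns ``Re Tr(T^dagger rho) / Tr(T^dagger T)`` so that a state equal
    to the target reads 1.  Bounded by Cauchy-Schwarz for norm-preserving
    evolution of an initial pure target coherence.
    """
    if isinstance(target, np.ndarray):
        t = target
    else:
        t = build_operator(target, system)
    if t.shape != state.shape:
        raise ValueError(f"dimension mismatch: {t.shape} vs {state.shape}")
    tnorm2 = np.real(np.trace(t.conj().T @ t))
    if tnorm2 <= 0.0:
        raise ValueError("zero-norm target")
    return float(np.real(np.trace(t.conj().T @ state)) / tnorm2)
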