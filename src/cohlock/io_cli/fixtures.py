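"""Deterministic synthetic calibration curves.

Emulates the two probe-calibration measurements — diffusion attenuation
of a spin echo versus gradient amplitude, and pulse-acquire signal versus
coupling-gradient amplitude — with seed-fixed multiplicative Gaussian
noise, so every fitting routine is testable without downloads.  The
generating parameters are returned as a sidecar manifest for
parameter-recovery tests.
"""

from __future__ import annotations

import json

import numpy as np

from ..experiments import CalibrationCurve, pgse_attenuation, spillover_signal

__all__ = ["generate_calibration_fixture"]

_PGSE_DEFAULTS = {
    "gmax_tm": 1.0306,
    "delta": 1.0e-3,
    "big_delta": 7.0e-3,
    "diffusion": 1.9e-9,
    "gamma": 2.675e8,
}

_SPILLOVER_DEFAULTS = {
    "rg": 1.9e-3,
    "gmax_tm": 1.0306,
    "zone_length": 6.5e-3,
    "g_integral": 0.9e-3,
    "gamma": 2.675e8,
}


def generate_calibration_fixture(
    kind: str,
    params: dict | None = None,
    noise_sigma: float = 0.01,
    seed: int = 0,
    n_points: int = 24,
    g_max_fraction: float = 0.95,
) -> tuple[CalibrationCurve, dict]:
    """Synthetic (gradient fraction, intensity) curve plus its manifest.

    ``kind`` is ``"pgse"`` or ``"spillover"``; ``params`` overrides the
    model defaults.  Noise is multiplicative Gaussian with relative sigma
    ``noise_sigma``; two calls with the same seed give identical curves.
    """
    rng = np.random.default_rng(seed)
    g = np.linspace(0.0, g_max_fraction, n_points)
    if kind == "pgse":
        p = dict(_PGSE_DEFAULTS)
        p.update(params or {})
        clean = pgse_attenuation(
            g * p["gmax_tm"], p["delta"], p["big_delta"], p["diffusion"], p["gamma"]
        )
    elif kind == "spillover":
        p = dict(_SPILLOVER_DEFAULTS)
        p.update(params or {})
        clean = spillover_signal(
            g, p["rg"], p["gmax_tm"], p["zone_length"], p["g_integral"], p["gamma"]
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    intensity = clean * (1.0 + noise_sigma * rng.standard_normal(g.shape))
    curve = CalibrationCurve(g=g, intensity=intensity, noise_sigma=noise_sigma)
    manifest = {
        "kind": kind,
        "params": p,
        "noise_sigma": noise_sigma,
        "seed": seed,
        "n_points": n_points,
        "g_max_fraction": g_max_fraction,
    }
    return curve, manifest


def write_fixture(curve: CalibrationCurve, manifest: dict, csv_path, manifest_path):
    curve.to_csv(csv_path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
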