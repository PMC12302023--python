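"""Shaped-pulse exchange formats.

Two formats are supported:

* a Bruker-style JCAMP-DX shape table (``##NPOINTS``, amplitude-percent /
  phase-degree ``##XYPOINTS`` pairs).  Amplitudes are stored as percent of
  the pulse maximum; the absolute scale (Hz), slice duration, channel and
  nominal amplitude travel in ``$$`` comment records so a round trip
  reproduces the waveform to better than 1e-9 relative.
* a lossless native CSV (``slice, x_hz, y_hz``) whose round trip is
  bit-exact (17 significant digits).
"""

from __future__ import annotations

import numpy as np

from ..cloc_design import ControlPulse

__all__ = ["write_shape", "read_shape", "write_shape_csv", "read_shape_csv"]


def write_shape(pulse: ControlPulse, path, title: str = "cohlock shaped pulse") -> None:
    """Write a JCAMP-DX shape file (amplitude %, phase degrees)."""
    amp = pulse.amplitude_hz
    phase = np.degrees(pulse.phase_rad) % 360.0
    max_amp = float(np.max(amp)) if amp.size else 0.0
    pct = amp / max_amp * 100.0 if max_amp > 0 else np.zeros_like(amp)
    lines = [
        f"##TITLE= {title}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= Shape Data",
        "##ORIGIN= cohlock",
        f"##MINX= {pct.min() if pct.size else 0.0:.6e}",
        f"##MAXX= {pct.max() if pct.size else 0.0:.6e}",
        "##XUNITS= %",
        "##YUNITS= degrees",
        f"$$ channel= {pulse.channel}",
        f"$$ slice_dt_s= {float(pulse.slice_dt)!r}",
        f"$$ max_amp_hz= {max_amp!r}",
        f"$$ nominal_amp_hz= {float(pulse.nominal_amp_hz)!r}",
        f"##NPOINTS= {pulse.n_slices}",
        "##XYPOINTS= (XY..XY)",
    ]
    for a, p in zip(pct, phase):
        lines.append(f" {a:.12e}, {p:.12e}")
    lines.append("##END=")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_shape(path) -> ControlPulse:
    """Read a JCAMP-DX shape file written by :func:`write_shape`.

    Raises ``ValueError`` on malformed headers or point-count mismatch.
    """
    meta: dict[str, str] = {}
    points: list[tuple[float, float]] = []
    in_table = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##END"):
                in_table = False
                continue
            if line.startswith("##XYPOINTS"):
                in_table = True
                continue
            if line.startswith("$$"):
                body = line[2:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if line.startswith("##"):
                k, _, v = line[2:].partition("=")
                meta[k.strip()] = v.strip()
                continue
            if in_table:
                parts = line.replace(",", " ").split()
                if len(parts) != 2:
                    raise ValueError(f"malformed shape record: {raw!r}")
                points.append((float(parts[0]), float(parts[1])))
    if "NPOINTS" not in meta:
        raise ValueError("malformed header: missing ##NPOINTS")
    n = int(meta["NPOINTS"])
    if len(points) != n:
        raise ValueError(
            f"point-count mismatch: header says {n}, table has {len(points)}"
        )
    for key in ("slice_dt_s", "max_amp_hz", "nominal_amp_hz"):
        if key not in meta:
            raise ValueError(f"malformed header: missing $$ {key}")
    pct = np.array([p[0] for p in points])
    phase = np.radians(np.array([p[1] for p in points]))
    amp = pct / 100.0 * float(meta["max_amp_hz"])
    return ControlPulse(
        channel=meta.get("channel", "1H"),
        slice_dt=float(meta["slice_dt_s"]),
        x_hz=amp * np.cos(phase),
        y_hz=amp * np.sin(phase),
        nominal_amp_hz=float(meta["nominal_amp_hz"]),
    )


def write_shape_csv(pulse: ControlPulse, path) -> None:
    """Lossless native table: slice index, x_hz, y_hz."""
    with open(path, "w") as fh:
        fh.write(f"# channel= {pulse.channel}\n")
        fh.write(f"# slice_dt_s= {float(pulse.slice_dt)!r}\n")
        fh.write(f"# nominal_amp_hz= {float(pulse.nominal_amp_hz)!r}\n")
        fh.write("slice,x_hz,y_hz\n")
        for i, (x, y) in enumerate(zip(pulse.x_hz, pulse.y_hz)):
            fh.write(f"{i},{float(x)!r},{float(y)!r}\n")


def read_shape_csv(path) -> ControlPulse:
    meta: dict[str, str] = {}
    xs, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
            elif line and not line.startswith("slice,"):
                _, x, y = line.split(",")
                xs.append(float(x))
                ys.append(float(y))
    return ControlPulse(
        channel=meta.get("channel", "1H"),
        slice_dt=float(meta["slice_dt_s"]),
        x_hz=np.array(xs),
        y_hz=np.array(ys),
        nominal_amp_hz=float(meta["nominal_amp_hz"]),
    )
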