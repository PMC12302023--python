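# cohlock

Coherence-locking pulse design and spin-dynamics simulation for parallel-NMR
probes whose pulsed-field-gradient coils leak stray fields into neighbouring
detectors.

A gradient pulse fired in one detector of a parallel probe spills a small,
time-dependent B0 drift across the sample of its neighbour, dephasing any
transverse coherence there.  `cohlock` designs *coherence-locking* RF pulses
by optimal control — piecewise-constant waveforms, played simultaneously with
the stray gradient, whose net propagator is the identity over a whole
robustness ensemble of drift amplitudes, resonance offsets and B1 scales — and
provides the simulation and calibration machinery to validate them at desk
scale:

- **`spin_algebra`** — product operators (`I+`, `Iz`, `I-S+`, ...) for one-
  and two-spin-1/2 systems, coherence orders, self-normalised overlaps.
- **`hamiltonians`** — Zeeman/gradient drifts (half-sine and trapezoid
  shapes), RF fields with B1 scaling, resonance offsets, weak/isotropic
  heteronuclear J coupling.
- **`propagation`** — exact piecewise-constant unitary propagation of locking
  windows, voxel/field-distortion ensembles, locking trajectories, cyclicity
  defect.
- **`cloc_design`** — the GRAPE-style optimiser: exact fidelity gradients via
  Frechet derivatives of slice propagators, cyclic-propagator and state-lock
  targets, smooth amplitude clipping, seeded multi-restart L-BFGS, plus an
  optional penalty that averages out the first-order residual heteronuclear
  coupling.
- **`aht`** — toggling-frame analysis: the time-averaged coupling tensor and
  its norm `chi` (the J-coupling scale factor), offset x B1 `chi` maps, and
  the `chi*J*tau` negligibility check.
- **`experiments`** — sequence-level simulators and fits: spin-echo diffusion
  attenuation (gradient calibration), sinc spillover decay (spillover-ratio
  calibration), gradient-selected HSQC/HMQC with coherence-pathway
  bookkeeping and locking-window insertion, robustness sweeps.
- **`io_cli`** — Bruker-style JCAMP-DX shaped-pulse files, lossless CSV
  tables, deterministic synthetic calibration fixtures, and the `cohlock`
  command-line interface.

## CLI

```sh
cohlock design --channel 1H --seed 20250717 --out-dir out/   # optimise a pulse
cohlock chi out/pulse.jcamp --out-dir chi/                   # residual-coupling map
cohlock simulate --sequence hsqc --scenario all \
    --shape-1h out/pulse.jcamp --shape-13c out13c/pulse.jcamp
cohlock fixture --kind pgse --noise-sigma 0.01 --seed 1      # synthetic curve
cohlock fit fixture_out/pgse_curve.csv --kind pgse           # calibration fit
```

Every run writes a `manifest.json` provenance block (options, seed, version,
config hash) next to its outputs.

## Conventions

- `+` means `Ix + i Iy`; rotating-frame Hamiltonians are `+gamma B Iz` with
  propagators `exp(-i H t)`; all internal angles in radians, file formats in
  degrees/percent.
- Overlaps are normalised so that `overlap(T, T) = 1`; state-lock fidelities
  are reported as `(1 + Re<T|rho>)/2`.
- Gradient pathway bookkeeping defaults to the nominal gyromagnetic ratio
  4 : 1 for 1H : 13C; the `exact` mode reports the small residual phase
  instead.
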