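# depsep — dielectrophoretic size separation in a sidewall-electrode microchannel

`depsep` simulates a lab-on-chip device that separates a binary mixture of
microparticles by size. The channel (cross-section W×H, typically
100 µm × 100 µm) carries vertical interdigitated electrodes on *both*
sidewalls, each set independently driven. It is written for microfluidics
researchers who want to predict capture, sedimentation, and
separation-performance numbers for such a device before fabricating it.

## The physics

A polarizable sphere of radius *r* in a non-uniform AC field feels the
dielectrophoretic (DEP) force

```
F_DEP = 2π ε_m ε0 r³ Re[f_CM](ω) ∇E²_RMS
```

where the real part of the Clausius–Mossotti factor,

```
Re[f_CM] = [(ε_e−ε_m)(ε_e+2ε_m) ω² + (σ_e−σ_m)(σ_e+2σ_m)] /
           [(ε_e+2ε_m)² ω² + (σ_e+2σ_m)²]
```

sets the sign of the force. The effective particle conductivity
σ_e = σ_bulk + 2K_s/r includes surface conduction, so *smaller* particles
are effectively more conductive. At the crossover frequency

```
N_cr = (1/2π) √[(σ_e+2σ_m)(σ_m−σ_e) / ((ε_e+2ε_m)(ε_e−ε_m))]
```

Re[f_CM] = 0. Driving the device at the crossover of the *big* particle
makes it DEP-blind while the small particle still feels positive DEP and is
pulled onto the electrodes: big particles are collected at the outlet
during processing, the captured small ones afterwards by flushing with the
field off.

The simulator couples four pieces, each behind its own module:

- **`dielectrics`** — Re[f_CM], effective conductivity, crossover frequency;
- **`field`** — finite-difference Laplace solve of the RMS potential on one
  repeating electrode unit (Gauss–Seidel, insulated non-electrode
  boundaries), then E, E², ∇E², tiled periodically over the array;
- **`flow`** — the analytical rectangular-duct Fourier series for the
  axial velocity, parameterized by volumetric flow rate;
- **`dynamics`** — Newtonian tracking of each particle under gravity,
  buoyancy, Stokes drag, and DEP with a semi-implicit central-difference
  scheme at Δt = 10⁻⁵ s;
- **`metrics`** — 9×9 uniform inlet release per size, separation efficiency
  SE and purity SP, cached parametric sweeps;
- **`config`/`cli`** — YAML scenarios with unit-suffixed keys and a thin
  `depsep` command-line front end (`crossover`, `cm-spectrum`,
  `solve-field`, `flow-profile`, `simulate`, `sweep`).

## Worked example

```python
import depsep as ds
from depsep.metrics import Scenario, run_scenario

scenario = Scenario(
    geometry=ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30, 20.0, 12.5),
    medium=ds.Medium(),                       # ε=78.5, σ=1e-4 S/m, water
    particle_small=ds.Particle(2.5e-6, ds.POLYSTYRENE),
    particle_big=ds.Particle(5.0e-6, ds.POLYSTYRENE),
    flow_rate=ds.ul_per_h_to_m3_per_s(200),
    spacing=5e-6,                             # field grid (1 µm = production)
)
res = run_scenario(scenario)
```

prints (see `examples/separation_run.py`):

```
operating frequency: 192.8 kHz (Re[f_CM] small +0.442, big +0.0e+00)
2.5 um: {'captured_electrode': 64, 'settled_bottom': 0, 'exited': 17, 'timeout': 0, 'released': 81}
5.0 um: {'captured_electrode': 0, 'settled_bottom': 2, 'exited': 79, 'timeout': 0, 'released': 81}
SE(2.5 um) = 79.0%   SE(5 um) = 97.5%
SP(2.5 um) = 97.0%   SP(5 um) = 82.3%
```

Reading: the drive sits at the 5 µm particle's crossover (192.8 kHz), so
the big particles cross the 4.5 mm electrode array untouched — 79 of 81
exit; the two released nearest the bottom corners sediment onto the floor
first. 64 of 81 small particles are pulled onto the electrodes; the 17 that
escape were released near the zero-DEP vertical plane (y ≈ 55–65 µm, offset
toward the weaker-driven wall), the device's intrinsic blind spot. SP of
the flushed small fraction is 64/66 = 97% because the two settled big
particles are flushed out with it.

More narrative scripts live in `examples/`: dispersion spectra and
crossover, duct flow profile, repeating-unit field structure, a single
capture trajectory, and a voltage sweep.

Everything is deterministic — identical configurations reproduce outcome
files byte for byte.

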