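# Methods

This note records the model, the numerical choices, and the limits of what
the simulator can show. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Model overview

The device is a straight rectangular microchannel (width W_ch spanwise,
height H_ch vertical) whose two sidewalls carry vertical interdigitated
electrodes: on each wall, signal and ground fingers of axial length l
alternate with gaps d, n fingers per side, the two walls independently
driven at peak-to-peak amplitudes V_pp1 and V_pp2 with a shared ground.
The electrode array spans L_arr = (n/2)·2(l+d) from the inlet; the channel
ends at the array's downstream edge (no outlet lead by default).

Three fields are combined, then each particle is tracked as a point mass:

1. **Polarization.** A homogeneous-sphere Clausius–Mossotti model with
   surface conduction folded into the effective conductivity
   σ_e = σ_bulk + 2K_s/r. Built-in materials: polystyrene (ε=2.55,
   K_s=2.85 nS) and silica (ε=3.8, K_s=0.82 nS). The medium defaults to a
   dilute aqueous buffer: ε_m = 78.5, σ_m = 1e-4 S/m, μ = 1 mPa·s,
   ρ = 1000 kg/m³. ε_m is not printed anywhere in the device description;
   78.5 (water at ~25 °C) reproduces the 5 µm polystyrene crossover of
   192.8 kHz from the closed form to four significant figures, which the
   test suite verifies together with an independent bisection on Re[f_CM].
   ε0 is taken as 8.854e-12 F/m, the precision at which that crossover
   value is quoted.

2. **Electrostatics.** The RMS potential obeys Laplace's equation with
   Dirichlet values V_pp/(2√2) on signal electrodes, 0 on grounds, and
   insulated (zero normal derivative) boundaries elsewhere — electrode
   polarization, double layers, and Joule heating are outside the model.
   The problem is solved on one repeating unit and tiled. **Axial cut
   placement:** the unit is cut through the *midplanes of the signal
   electrodes* ([signal/2 | gap | ground | gap | signal/2]). For an
   aligned array these planes are exact mirror planes of the infinite
   periodic solution, so insulated ends reproduce the periodic field and
   the tiled ∇E² is continuous across unit boundaries; a `periodic` axial
   option exists and agrees to solver tolerance (tested). Cutting at an
   electrode edge instead would make the insulated condition inconsistent
   with tiling. Opposing electrodes are axially aligned (the equal-voltage
   mirror symmetry the device concept relies on); a staggered layout is
   not implemented.

3. **Hydrodynamics.** Fully developed pressure-driven duct flow,
   parameterized directly by flow rate Q_m through the classical double
   hyperbolic-cosine series (odd harmonics). The bracketed tanh
   normalization makes the cross-section integral exactly Q_m, verified
   against 2-D Simpson quadrature to 0.1%. The series converges only as
   1/i³, so 100 odd terms (i ≤ 199) are kept — truncation at i ≤ 25
   differs at the 1e-5 level, i ≤ 199 at ~1e-8 (tested). Hyperbolic
   ratios are evaluated in log space to survive extreme aspect ratios.

4. **Particle dynamics.** Newton's second law with gravity, buoyancy,
   Stokes drag 6πμr(u−v) (fluid velocity axial only, evaluated at the
   particle center, no wall corrections), and DEP
   2π ε_m ε0 r³ Re[f_CM] ∇E²_RMS. Brownian motion and particle–particle
   interactions are neglected (particles ≫ 1 µm, dilute suspension).
   Particle densities default to 1050 kg/m³ (polystyrene).

## Integration scheme

The second derivative is replaced by the three-point central difference
and the drag velocity by the *centered* difference (x_{n+1}−x_{n−1})/2Δt,
giving a per-component linear update solved for x_{n+1}. The homogeneous
amplification factors are 1 and (a−b)/(a+b) with a = m/Δt², b = 3πμr/Δt,
so the scheme is unconditionally stable — essential because the momentum
relaxation time τ = m/(6πμr) (≈1.5 µs for a 2.5 µm sphere) is far below
the working time step Δt = 1e-5 s; a fully explicit drag term diverges at
this Δt (regression-tested). For Δt > 2τ the drag mode is negative:
velocities approach terminal values through damped alternation while
positions remain monotone. The first step is bootstrapped with
x_{−1} = x_0 − v_0Δt; release velocity equals the local fluid velocity.
Terminal settling speeds for r = 1/2.5/5 µm match the closed form
2Δρgr²/(9μ) to better than 1%, and halving Δt moves a reference capture
point by well under 1 µm.

An alternative `exponential_drag` integrator (exact integration of the
linear drag over one step with forcing frozen at the step start) is
available as a cross-check and agrees with the central-difference scheme
on settling and transit outcomes.

**Events.** A particle is *captured* when its surface touches a sidewall
(y ≤ r or y ≥ W−r) inside the array, *settled* when it touches the floor
(z ≤ r), *exited* when x ≥ L_arr. The contact distance (one radius) is a
modeling choice; top-wall contact clamps z without terminating. Captured
and settled states are absorbing — no resuspension. Particles still in
transit at `max_time` (default 60 s) are reported as timeouts, kept in SE
denominators, and never dropped.

**Hot path.** The Gauss–Seidel sweeps and the time-stepping loop are
numba-compiled. Inside the integrator the duct velocity is sampled from a
bilinear table at 0.5 µm resolution (interpolation error a few 1e-5 of the
centerline velocity, tested) rather than re-summing ~100 hyperbolic terms
per step; the public `axial_velocity` always evaluates the series. ∇E² is
sampled trilinearly from the unit grid with the axial coordinate reduced
modulo the unit period. A pure-Python stepper mirrors the kernel and the
two are cross-validated step-by-step in the tests.

## Field solver numerics

7-point Laplacian, mirror-node Neumann boundaries, plain Gauss–Seidel
(an over-relaxation factor is available but defaults off). Iteration stops
when the largest node update of a sweep falls below tol·max|V_electrode|
(tol default 1e-6, max 200k sweeps; convergence failure raises an error
carrying the residual). Note the update-based criterion understates the
true iteration error by roughly the 1/(1−ρ) convergence factor of the
grid; tests that compare against the sparse-direct 2-D oracle therefore
solve at tighter tolerance and allow that amplification. Grid refinement
shows the expected second-order convergence (observed order ≥ 1.7 on a
three-level refinement). Production grid spacing is 1 µm; tests and the
acceptance script run at 5 µm ("desk scale"), where SE/SP change by at
most a few per cent versus 2.5 µm (checked).

## Release conditions and metrics

Each size is released from 81 points: the centers of the 9×9 equal-area
cells of [m, W−m]×[m, H−m] with wall margin m equal to the particle radius.
Cell centers keep every seed strictly inside the admissible cross-section
(a seed *at* z = r would count as settled at t = 0) and make a 1×1 grid
release from the channel center. For the 5 µm size the bottom row sits at
z = 10 µm — this matters below.

SE(small) = captured/released, SE(big) = exited/released,
SP(small) = captured_small/(captured_small + settled_big) — the flush
phase collects whatever sits on electrodes *and* floor — and
SP(big) = exited_big/(exited_big + exited_small); empty denominators give
NaN. Parametric sweeps cache the repeating-unit field keyed by everything
it depends on (electrode dimensions, cross-section, voltages, solver
settings), so flow-rate and electrode-count axes never re-solve it.

## What the reference runs show — and where they differ from expectation

At the reference operating point (20/12.5 Vpp, 200 µL/h, l=120/d=30 µm,
n=30, drive at the 5 µm crossover) the qualitative device behavior is
fully reproduced: big particles are never captured, small ones are drawn
onto the electrodes, voltage/electrode-count/flow trends are monotone in
the expected directions, and SP(small) is degraded only by big-particle
sedimentation. Three quantitative caveats, all resolution-robust:

- **Bottom-corner sedimentation.** The 5 µm particles settle at
  2.7 µm/s; the two seeds released at (y,z) ≈ (10,10)/(90,10) µm move
  slowly enough (~2 mm/s) that they touch the floor after 1.83 s at
  x ≈ 3.0 mm < L_arr = 4.5 mm. SE(5 µm) is therefore 97.5% rather than
  100%, and SP(2.5 µm) 97.0%; at 300 µL/h, or with n ≤ 20 (shorter
  array), nothing settles and both are 100%. An ideal-device claim of
  exactly 100% at 200 µL/h holds only if the lowest release points sit
  ≥ ~14 µm above the floor — the release layout is the controlling,
  physically unconstrained choice here.
- **The blind plane.** 17 of 81 small particles released near the
  zero-lateral-DEP plane (y ≈ 55–65 µm at 20/12.5 Vpp) traverse the array
  uncaptured: SE(2.5 µm) = 79% rather than ~100%. The plane itself is a
  genuine property of any two-sided drive; how many seeds it affects
  depends on residence time and field detail.
- **Electrode-dimension trend.** Scaling (l,d) through (40,10), (80,20),
  (120,30) µm at fixed n=30 gives SE(2.5 µm) = 76.5 → 82.7 → 79.0%: not
  monotone. Longer fingers lengthen the array (more residence) but also
  space the high-gradient electrode edges further apart; in this model
  the (80,20) layout wins. The often-expected "bigger electrodes, more
  capture" holds only between the first two points.

## Known limitations

Idealized electrode boundary conditions (no double-layer screening, no
finite electrode thickness), no AC electroosmosis or electrothermal flow,
no Brownian motion (invalid below ~1 µm radius), no hydrodynamic wall
corrections or adhesion physics at capture, single-frequency sinusoidal
drive, dilute (non-interacting) suspensions only. The flush phase is an
accounting step, not a re-simulation.
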