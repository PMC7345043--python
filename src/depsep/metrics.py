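"""Release-grid seeding, separation efficiency/purity, and parametric sweeps.

Collection semantics of the two-phase operating scheme: while the sample is
processed, big particles (no DEP at the operating frequency) ride the flow
to the outlet and are collected; small particles are captured on the
electrodes.  Afterwards the voltage is switched off and the device flushed,
collecting the captured small particles - together with any big particles
that settled to the channel bottom - in a second stream.  Hence

    SE(small) = captured(small) / released(small)
    SE(big)   = exited(big)   / released(big)
    SP(small) = captured(small) / [captured(small) + settled(big)]
    SP(big)   = exited(big)   / [exited(big) + exited(small)]

all expressed in percent.  Timed-out particles (still in transit at
max_time) are counted in SE denominators and reported, never dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .dielectrics import Medium, Particle, crossover_frequency, re_cm_factor
from .dynamics import Outcome, SimulationConfig, Status, simulate_batch
from .field import build_repeating_unit, dep_force_field, solve_potential
from .flow import FlowSpec
from .geometry import DeviceGeometry

__all__ = [
    "SeedingGrid",
    "SeparationReport",
    "seed_inlet",
    "count_outcomes",
    "separation_metrics",
    "ScenarioResult",
    "run_scenario",
    "parametric_sweep",
    "SWEEP_AXES",
]

_STATUSES = (
    Status.CAPTURED_ELECTRODE,
    Status.SETTLED_BOTTOM,
    Status.EXITED,
    Status.TIMEOUT,
)


@dataclass(frozen=True)
class SeedingGrid:
    """Uniform rows x cols release grid over the inlet cross-section.

    ``margin`` is the wall offset in meters; ``None`` means one particle
    radius.  Seeds sit at the centers of equal-area cells of
    [margin, W-margin] x [margin, H-margin], so they are strictly inside the
    admissible (radius-inflated) cross-section and a 1x1 grid releases from
    the channel center.
    """

    rows: int = 9
    cols: int = 9
    margin: float | None = None

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be >= 1")


def seed_inlet(
    geometry: DeviceGeometry, grid: SeedingGrid, particle_radius: float | None = None
) -> np.ndarray:
    """Release points (W0, H0) for the inlet grid, shape (rows*cols, 2)."""
    margin = grid.margin if grid.margin is not None else particle_radius
    if margin is None:
        raise ValueError("margin unset and no particle radius supplied")
    if margin >= min(geometry.channel_width, geometry.channel_height) / 2:
        raise ValueError("margin must be below half the smallest cross-section side")
    W, H = geometry.channel_width, geometry.channel_height
    w0 = margin + (2 * np.arange(grid.cols) + 1) * (W - 2 * margin) / (2 * grid.cols)
    h0 = margin + (2 * np.arange(grid.rows) + 1) * (H - 2 * margin) / (2 * grid.rows)
    WW, HH = np.meshgrid(w0, h0, indexing="ij")
    return np.column_stack([WW.ravel(), HH.ravel()])


def count_outcomes(outcomes: list[Outcome]) -> dict:
    counts = {s.value: 0 for s in _STATUSES}
    for o in outcomes:
        counts[o.status.value] += 1
    counts["released"] = len(outcomes)
    return counts


@dataclass
class SeparationReport:
    counts_small: dict
    counts_big: dict
    se_small: float
    se_big: float
    sp_small: float
    sp_big: float

    def as_row(self) -> dict:
        row = {}
        for size, c in (("small", self.counts_small), ("big", self.counts_big)):
            for k, v in c.items():
                row[f"{size}_{k}"] = v
        row.update(
            se_small=self.se_small,
            se_big=self.se_big,
            sp_small=self.sp_small,
            sp_big=self.sp_big,
        )
        return row


def _pct(num: float, den: float) -> float:
    """Percentage with an undefined marker (NaN) for empty denominators."""
    return 100.0 * num / den if den > 0 else math.nan


def separation_metrics(outcomes_small, outcomes_big) -> SeparationReport:
    """Aggregate per-particle outcomes into SE and SP per size."""
    cs = count_outcomes(outcomes_small)
    cb = count_outcomes(outcomes_big)
    return SeparationReport(
        counts_small=cs,
        counts_big=cb,
        se_small=_pct(cs["captured_electrode"], cs["released"]),
        se_big=_pct(cb["exited"], cb["released"]),
        sp_small=_pct(
            cs["captured_electrode"], cs["captured_electrode"] + cb["settled_bottom"]
        ),
        sp_big=_pct(cb["exited"], cb["exited"] + cs["exited"]),
    )


@dataclass(frozen=True)
class Scenario:
    """A fully specified separation run: device, fluids, particles, numerics.

    ``frequency`` is either a value in Hz or the string ``"crossover_big"``,
    meaning the drive frequency is set to the big particle's DEP crossover
    (the device's intended operating point).
    """

    geometry: DeviceGeometry
    medium: Medium
    particle_small: Particle
    particle_big: Particle
    flow_rate: float  # m^3/s
    frequency: float | str = "crossover_big"
    spacing: float = 1e-6
    field_tol: float = 1e-6
    field_max_iter: int = 200_000
    relaxation: float = 1.0
    axial_bc: str = "insulated"
    time_step: float = 1e-5
    max_time: float = 60.0
    integrator_mode: str = "central_difference"
    seeding: SeedingGrid = dc_field(default_factory=SeedingGrid)

    def resolved_frequency(self) -> float:
        if self.frequency == "crossover_big":
            return crossover_frequency(self.particle_big, self.medium)
        return float(self.frequency)


@dataclass
class ScenarioResult:
    scenario: Scenario
    frequency: float
    re_fcm_small: float
    re_fcm_big: float
    report: SeparationReport
    outcomes_small: list[Outcome]
    outcomes_big: list[Outcome]
    field_iterations: int
    field_residual: float
    field_cache_hit: bool


def _field_cache_key(sc: Scenario):
    g = sc.geometry
    return (
        g.channel_width, g.channel_height, g.electrode_length, g.electrode_gap,
        g.vpp_side1, g.vpp_side2,
        sc.spacing, sc.field_tol, sc.relaxation, sc.axial_bc,
    )


def run_scenario(sc: Scenario, field_cache: dict | None = None) -> ScenarioResult:
    """Solve the field (or reuse a cached solution for the same repeating
    unit), release both sizes from the seeding grid, and aggregate SE/SP.

    The field cache key covers everything the repeating-unit solution
    depends on - electrode dimensions, channel cross-section, voltages and
    solver numerics - but not flow rate or electrode count, so flow-rate and
    electrode-count sweeps re-solve nothing.
    """
    cache_hit = False
    key = _field_cache_key(sc)
    cached = field_cache.get(key) if field_cache is not None else None
    if cached is not None:
        fld, iters, resid = cached
        cache_hit = True
    elif sc.geometry.vpp_side1 == 0 and sc.geometry.vpp_side2 == 0:
        fld, iters, resid = None, 0, 0.0
    else:
        grid = build_repeating_unit(sc.geometry, sc.spacing, sc.axial_bc)
        solve_potential(grid, tol=sc.field_tol, max_iter=sc.field_max_iter,
                        relaxation=sc.relaxation)
        fld, iters, resid = dep_force_field(grid), grid.iterations, grid.residual
        if field_cache is not None:
            field_cache[key] = (fld, iters, resid)

    freq = sc.resolved_frequency()
    fcm_s = re_cm_factor(sc.particle_small, sc.medium, freq)
    fcm_b = re_cm_factor(sc.particle_big, sc.medium, freq)
    flow = FlowSpec(sc.flow_rate, sc.geometry)
    config = SimulationConfig(
        time_step=sc.time_step,
        max_time=sc.max_time,
        operating_frequency=freq,
        integrator_mode=sc.integrator_mode,
    )
    outcomes = {}
    for name, particle, fcm in (
        ("small", sc.particle_small, fcm_s),
        ("big", sc.particle_big, fcm_b),
    ):
        seeds = seed_inlet(sc.geometry, sc.seeding, particle.radius)
        outcomes[name] = simulate_batch(
            seeds, particle, sc.medium, flow, fld, sc.geometry, config, re_fcm=fcm
        )
    report = separation_metrics(outcomes["small"], outcomes["big"])
    return ScenarioResult(
        scenario=sc,
        frequency=freq,
        re_fcm_small=fcm_s,
        re_fcm_big=fcm_b,
        report=report,
        outcomes_small=outcomes["small"],
        outcomes_big=outcomes["big"],
        field_iterations=iters,
        field_residual=resid,
        field_cache_hit=cache_hit,
    )


SWEEP_AXES = ("voltage", "electrode_dims", "flow_rate", "n_electrodes")


def _apply_axis(sc: Scenario, axis: str, value) -> Scenario:
    if axis == "voltage":
        v1, v2 = value
        return replace(sc, geometry=replace(sc.geometry, vpp_side1=v1, vpp_side2=v2))
    if axis == "electrode_dims":
        l, d = value
        return replace(
            sc, geometry=replace(sc.geometry, electrode_length=l, electrode_gap=d)
        )
    if axis == "flow_rate":
        return replace(sc, flow_rate=float(value))
    if axis == "n_electrodes":
        return replace(sc, geometry=replace(sc.geometry, electrodes_per_side=int(value)))
    raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")


def parametric_sweep(
    base: Scenario, axis: str, values, field_cache: dict | None = None
) -> pd.DataFrame:
    """Run one scenario per value of the swept axis; one report row each.

    The shared field cache means the repeating-unit Laplace problem is
    re-solved only when the swept axis changes electrode geometry or
    voltage.  A failing scenario is recorded in its row's ``error`` column
    and the sweep continues.
    """
    if field_cache is None:
        field_cache = {}
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    rows = []
    for value in values:
        row = {"axis": axis, "value": str(value)}
        if axis == "flow_rate":
            row["Q_m3_per_s"] = float(value)
        try:
            sc = _apply_axis(base, axis, value)
            res = run_scenario(sc, field_cache)
            row.update(res.report.as_row())
            row["frequency_Hz"] = res.frequency
            row["field_cache_hit"] = res.field_cache_hit
            row["field_iterations"] = res.field_iterations
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 - per-row fault isolation
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
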