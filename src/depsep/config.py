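"""YAML scenario configuration: parsing, unit handling, output writers.

Every physical quantity in a config file carries its unit as a key suffix
(``l_um``, ``Q_uL_per_h``, ``frequency_kHz``, ``Vpp1_V`` ...); plain SI
variants (``l_m``, ``Q_m3_per_s``, ``frequency_Hz``) are accepted too.
Unknown keys are rejected, and all validation problems of a file are
aggregated into a single error.  A fully resolved copy of the configuration
(defaults applied, SI everywhere with explicit micro-unit suffixes) is
echoed into every output directory for provenance, and ``dump_config`` after
``load_config`` is idempotent.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .constants import m3_per_s_to_ul_per_h
from .dielectrics import MATERIALS, DielectricMaterial, Medium, Particle
from .geometry import DeviceGeometry
from .metrics import Scenario, ScenarioResult, SeedingGrid

__all__ = ["ConfigError", "load_config", "dump_config", "save_config", "write_outputs"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""


def _get_scaled(section: dict, errors: list, prefix: str, variants: dict,
                default=None, required=False):
    """Fetch one quantity given alternative unit-suffixed keys.

    ``variants`` maps key name -> scale-to-SI.  Returns the SI value.
    """
    found = [k for k in variants if k in section]
    if len(found) > 1:
        errors.append(f"{prefix}: conflicting keys {found}")
        return default
    if not found:
        if required:
            errors.append(f"{prefix}: missing one of {sorted(variants)}")
        return default
    key = found[0]
    raw = section.pop(key)
    try:
        return _sig(float(raw) * variants[key])
    except (TypeError, ValueError):
        errors.append(f"{prefix}.{key}: not a number ({raw!r})")
        return default


def _sig(x: float) -> float:
    """Normalize to 12 significant digits so unit conversions round-trip
    (e.g. 100 um -> 1e-4 m -> 100 um exactly)."""
    return float(f"{x:.12g}")


def _material(spec, materials: dict, errors: list, where: str):
    if isinstance(spec, str):
        if spec in materials:
            return materials[spec]
        errors.append(f"{where}: unknown material {spec!r}")
        return None
    if isinstance(spec, dict):
        spec = dict(spec)
        eps = spec.pop("rel_permittivity", None)
        sig = spec.pop("bulk_conductivity_S_per_m", 0.0)
        ks = spec.pop("surface_conductance_S", 0.0)
        if spec:
            errors.append(f"{where}: unknown material keys {sorted(spec)}")
        if eps is None:
            errors.append(f"{where}: material needs rel_permittivity")
            return None
        try:
            return DielectricMaterial(float(eps), float(sig), float(ks))
        except ValueError as e:
            errors.append(f"{where}: {e}")
            return None
    errors.append(f"{where}: material must be a name or a mapping")
    return None


_LEN = {"_um": 1e-6, "_m": 1.0}


def _len_variants(base):
    return {base + suf: scale for suf, scale in _LEN.items()}


def load_config(path) -> Scenario:
    """Parse a YAML scenario file into a :class:`~depsep.metrics.Scenario`."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors: list[str] = []
    raw = {k: (dict(v) if isinstance(v, dict) else v) for k, v in raw.items()}

    materials = dict(MATERIALS)
    for name, spec in (raw.pop("materials", {}) or {}).items():
        mat = _material(spec, materials, errors, f"materials.{name}")
        if mat is not None:
            materials[name] = mat

    med_sec = raw.pop("medium", {}) or {}
    med_kw = {}
    if "rel_permittivity" in med_sec:
        med_kw["rel_permittivity"] = float(med_sec.pop("rel_permittivity"))
    for key, attr in (
        ("conductivity_S_per_m", "conductivity"),
        ("viscosity_Pa_s", "viscosity"),
        ("density_kg_per_m3", "density"),
    ):
        if key in med_sec:
            med_kw[attr] = float(med_sec.pop(key))
    if med_sec:
        errors.append(f"medium: unknown keys {sorted(med_sec)}")
    try:
        medium = Medium(**med_kw)
    except ValueError as e:
        errors.append(f"medium: {e}")
        medium = Medium()

    geo_sec = raw.pop("geometry", None)
    geometry = None
    if geo_sec is None:
        errors.append("geometry: section is required")
    else:
        W = _get_scaled(geo_sec, errors, "geometry", _len_variants("W_ch"), required=True)
        H = _get_scaled(geo_sec, errors, "geometry", _len_variants("H_ch"), required=True)
        l = _get_scaled(geo_sec, errors, "geometry", _len_variants("l"), required=True)
        d = _get_scaled(geo_sec, errors, "geometry", _len_variants("d"), required=True)
        n = geo_sec.pop("n", None)
        v1 = _get_scaled(geo_sec, errors, "geometry", {"Vpp1_V": 1.0}, default=0.0)
        v2 = _get_scaled(geo_sec, errors, "geometry", {"Vpp2_V": 1.0}, default=0.0)
        if n is None:
            errors.append("geometry: missing electrode count n")
        if geo_sec:
            errors.append(f"geometry: unknown keys {sorted(geo_sec)}")
        if not errors:
            try:
                geometry = DeviceGeometry(W, H, l, d, int(n), v1, v2)
            except (TypeError, ValueError) as e:
                errors.append(f"geometry: {e}")

    def particle(sec_name, default_radius):
        sec = parts.pop(sec_name, {}) or {}
        r = _get_scaled(sec, errors, f"particles.{sec_name}", _len_variants("radius"),
                        default=default_radius)
        mat_spec = sec.pop("material", "polystyrene")
        rho = float(sec.pop("density_kg_per_m3", 1050.0))
        if sec:
            errors.append(f"particles.{sec_name}: unknown keys {sorted(sec)}")
        mat = _material(mat_spec, materials, errors, f"particles.{sec_name}.material")
        if mat is None:
            return None
        try:
            return Particle(r, mat, rho)
        except ValueError as e:
            errors.append(f"particles.{sec_name}: {e}")
            return None

    parts = raw.pop("particles", {}) or {}
    p_small = particle("small", 2.5e-6)
    p_big = particle("big", 5.0e-6)
    if parts:
        errors.append(f"particles: unknown keys {sorted(parts)}")

    flow_sec = raw.pop("flow", {}) or {}
    q = _get_scaled(
        flow_sec, errors, "flow",
        {"Q_uL_per_h": 1e-9 / 3600.0, "Q_m3_per_s": 1.0},
        required=True,
    )
    if flow_sec:
        errors.append(f"flow: unknown keys {sorted(flow_sec)}")

    op_sec = raw.pop("operation", {}) or {}
    freq = op_sec.pop("frequency", "crossover_big")
    if freq != "crossover_big":
        errors.append(
            "operation.frequency: must be 'crossover_big' or use frequency_Hz/_kHz"
        )
        freq = "crossover_big"
    fnum = _get_scaled(op_sec, errors, "operation",
                       {"frequency_Hz": 1.0, "frequency_kHz": 1e3})
    if fnum is not None:
        freq = fnum
    if op_sec:
        errors.append(f"operation: unknown keys {sorted(op_sec)}")

    fld_sec = raw.pop("field", {}) or {}
    spacing = _get_scaled(fld_sec, errors, "field", _len_variants("spacing"), default=1e-6)
    tol = float(fld_sec.pop("tol", 1e-6))
    max_iter = int(fld_sec.pop("max_iter", 200_000))
    relaxation = float(fld_sec.pop("relaxation", 1.0))
    axial_bc = str(fld_sec.pop("axial_bc", "insulated"))
    if fld_sec:
        errors.append(f"field: unknown keys {sorted(fld_sec)}")

    dyn_sec = raw.pop("dynamics", {}) or {}
    dt = _get_scaled(dyn_sec, errors, "dynamics", {"time_step_s": 1.0}, default=1e-5)
    max_time = _get_scaled(dyn_sec, errors, "dynamics", {"max_time_s": 1.0}, default=60.0)
    integrator = str(dyn_sec.pop("integrator", "central_difference"))
    if dyn_sec:
        errors.append(f"dynamics: unknown keys {sorted(dyn_sec)}")

    seed_sec = raw.pop("seeding", {}) or {}
    rows = int(seed_sec.pop("rows", 9))
    cols = int(seed_sec.pop("cols", 9))
    margin = _get_scaled(seed_sec, errors, "seeding", _len_variants("margin"))
    if seed_sec:
        errors.append(f"seeding: unknown keys {sorted(seed_sec)}")

    if raw:
        errors.append(f"unknown top-level sections {sorted(raw)}")
    if errors or geometry is None or p_small is None or p_big is None or q is None:
        raise ConfigError(f"{path}:\n  " + "\n  ".join(errors))

    try:
        return Scenario(
            geometry=geometry,
            medium=medium,
            particle_small=p_small,
            particle_big=p_big,
            flow_rate=q,
            frequency=freq,
            spacing=spacing,
            field_tol=tol,
            field_max_iter=max_iter,
            relaxation=relaxation,
            axial_bc=axial_bc,
            time_step=dt,
            max_time=max_time,
            integrator_mode=integrator,
            seeding=SeedingGrid(rows, cols, margin),
        )
    except ValueError as e:
        raise ConfigError(f"{path}: {e}") from e


def _dump_material(mat: DielectricMaterial):
    for name, preset in MATERIALS.items():
        if mat == preset:
            return name
    return {
        "rel_permittivity": mat.rel_permittivity,
        "bulk_conductivity_S_per_m": mat.bulk_conductivity,
        "surface_conductance_S": mat.surface_conductance,
    }


def dump_config(sc: Scenario) -> dict:
    """Scenario -> plain dict in the canonical config schema."""
    g = sc.geometry
    out = {
        "geometry": {
            "W_ch_um": _sig(g.channel_width * 1e6),
            "H_ch_um": _sig(g.channel_height * 1e6),
            "l_um": _sig(g.electrode_length * 1e6),
            "d_um": _sig(g.electrode_gap * 1e6),
            "n": g.electrodes_per_side,
            "Vpp1_V": g.vpp_side1,
            "Vpp2_V": g.vpp_side2,
        },
        "medium": {
            "rel_permittivity": sc.medium.rel_permittivity,
            "conductivity_S_per_m": sc.medium.conductivity,
            "viscosity_Pa_s": sc.medium.viscosity,
            "density_kg_per_m3": sc.medium.density,
        },
        "particles": {
            name: {
                "radius_um": _sig(p.radius * 1e6),
                "material": _dump_material(p.material),
                "density_kg_per_m3": p.density,
            }
            for name, p in (("small", sc.particle_small), ("big", sc.particle_big))
        },
        "flow": {"Q_uL_per_h": _sig(m3_per_s_to_ul_per_h(sc.flow_rate))},
        "operation": (
            {"frequency": "crossover_big"}
            if sc.frequency == "crossover_big"
            else {"frequency_Hz": float(sc.frequency)}
        ),
        "field": {
            "spacing_um": _sig(sc.spacing * 1e6),
            "tol": sc.field_tol,
            "max_iter": sc.field_max_iter,
            "relaxation": sc.relaxation,
            "axial_bc": sc.axial_bc,
        },
        "dynamics": {
            "time_step_s": sc.time_step,
            "max_time_s": sc.max_time,
            "integrator": sc.integrator_mode,
        },
        "seeding": {"rows": sc.seeding.rows, "cols": sc.seeding.cols},
    }
    if sc.seeding.margin is not None:
        out["seeding"]["margin_um"] = _sig(sc.seeding.margin * 1e6)
    return out


def save_config(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(sc), fh, sort_keys=False)


def check_writable(out_dir) -> Path:
    """Fail fast (before any simulation) if the output directory is unusable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_probe"
    try:
        probe.write_text("")
    except OSError as e:
        raise OSError(f"output directory {out} is not writable: {e}") from e
    probe.unlink()
    return out


def write_outputs(
    result: ScenarioResult,
    out_dir,
    trajectories: dict | None = None,
    log_lines: list[str] | None = None,
) -> Path:
    """Write outcome records, the SE/SP report, the resolved config echo,
    and optional trajectories (CSV, one file per particle) to ``out_dir``."""
    import pandas as pd

    out = check_writable(out_dir)
    rows = []
    for size, outcomes in (("small", result.outcomes_small), ("big", result.outcomes_big)):
        for i, o in enumerate(outcomes):
            rows.append(
                {
                    "size": size,
                    "index": i,
                    "W0_um": o.release[0] * 1e6,
                    "H0_um": o.release[1] * 1e6,
                    "status": o.status.value,
                    "x_um": o.position[0] * 1e6,
                    "y_um": o.position[1] * 1e6,
                    "z_um": o.position[2] * 1e6,
                    "residence_time_s": o.time,
                }
            )
    pd.DataFrame(rows).to_csv(out / "outcomes.csv", index=False)
    pd.DataFrame([result.report.as_row()]).to_csv(out / "report.csv", index=False)
    save_config(result.scenario, out / "resolved_config.yaml")
    if trajectories:
        for (size, idx), traj in trajectories.items():
            pd.DataFrame(traj, columns=["t_s", "x_m", "y_m", "z_m"]).to_csv(
                out / f"trajectory_{size}_{idx:03d}.csv", index=False
            )
    log = log_lines or []
    log = [
        f"frequency_Hz: {result.frequency:.6g}",
        f"re_fcm_small: {result.re_fcm_small:.6g}",
        f"re_fcm_big: {result.re_fcm_big:.6g}",
        f"field_iterations: {result.field_iterations}",
        f"field_residual_V: {result.field_residual:.3e}",
        f"field_cache_hit: {result.field_cache_hit}",
    ] + log
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out
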