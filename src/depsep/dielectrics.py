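"""Frequency-dependent polarization of a dielectric microsphere in a medium.

The dielectrophoretic (DEP) force on a small homogeneous sphere is
proportional to the real part of the Clausius--Mossotti factor

    Re[f_CM] = [ (eps_e - eps_m)(eps_e + 2 eps_m) w^2 + (sig_e - sig_m)(sig_e + 2 sig_m) ]
               / [ (eps_e + 2 eps_m)^2 w^2 + (sig_e + 2 sig_m)^2 ]

with absolute permittivities eps = eps_r * eps0, angular frequency
w = 2 pi N, and the particle's *effective* conductivity

    sig_e = sig_bulk + 2 K_s / r

which folds surface conduction (surface conductance K_s, in siemens) into an
equivalent bulk value; the 2 K_s / r term makes small particles effectively
more conductive than large ones of the same material.  A particle feels
positive DEP (attraction to strong-field regions) where Re[f_CM] > 0 and
negative DEP where it is < 0; the frequency where it vanishes is the
crossover frequency

    N_cr = (1 / 2 pi) * sqrt[ (sig_e + 2 sig_m)(sig_m - sig_e)
                              / ((eps_e + 2 eps_m)(eps_e - eps_m)) ].

A size-selective separator is operated at the crossover frequency of the
*larger* particle, which then feels no DEP while the smaller (effectively
more conductive) particle still feels positive DEP and is captured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import EPS0

__all__ = [
    "DielectricMaterial",
    "Medium",
    "Particle",
    "NoCrossoverError",
    "effective_conductivity",
    "re_cm_factor",
    "crossover_frequency",
    "cm_spectrum",
    "MATERIALS",
    "POLYSTYRENE",
    "SILICA",
]


class NoCrossoverError(ValueError):
    """The particle/medium pair has no real crossover frequency (DEP never
    changes sign)."""


@dataclass(frozen=True)
class DielectricMaterial:
    """Electrical properties of a particle material.

    Parameters
    ----------
    rel_permittivity : dimensionless relative permittivity.
    bulk_conductivity : bulk conductivity, S/m.
    surface_conductance : surface conductance K_s, S.
    """

    rel_permittivity: float
    bulk_conductivity: float = 0.0
    surface_conductance: float = 0.0

    def __post_init__(self):
        if self.rel_permittivity <= 0:
            raise ValueError("rel_permittivity must be > 0")
        if self.bulk_conductivity < 0:
            raise ValueError("bulk_conductivity must be >= 0")
        if self.surface_conductance < 0:
            raise ValueError("surface_conductance must be >= 0")


@dataclass(frozen=True)
class Medium:
    """Suspending fluid: relative permittivity, conductivity (S/m),
    dynamic viscosity (Pa s), and density (kg/m^3)."""

    rel_permittivity: float = 78.5
    conductivity: float = 1e-4
    viscosity: float = 1.0e-3
    density: float = 1000.0

    def __post_init__(self):
        for name in ("rel_permittivity", "conductivity", "viscosity", "density"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Particle:
    """A spherical microparticle: radius (m), material, density (kg/m^3)."""

    radius: float
    material: DielectricMaterial
    density: float = 1050.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3

    @property
    def mass(self) -> float:
        return self.volume * self.density


#: Built-in material presets.
POLYSTYRENE = DielectricMaterial(2.55, 0.0, 2.85e-9)
SILICA = DielectricMaterial(3.8, 0.0, 0.82e-9)
MATERIALS = {"polystyrene": POLYSTYRENE, "silica": SILICA}


def effective_conductivity(particle: Particle) -> float:
    """Effective conductivity sig_e = sig_bulk + 2 K_s / r, in S/m."""
    m = particle.material
    return m.bulk_conductivity + 2.0 * m.surface_conductance / particle.radius


def re_cm_factor(particle: Particle, medium: Medium, frequency) -> float:
    """Real part of the Clausius--Mossotti factor at ``frequency`` (Hz).

    Valid for all frequencies >= 0 (the w=0 limit is the conductivity
    contrast).  Accepts scalar or array frequency.
    """
    freq = np.asarray(frequency, dtype=float)
    if np.any(freq < 0):
        raise ValueError("frequency must be >= 0")
    eps_e = particle.material.rel_permittivity * EPS0
    eps_m = medium.rel_permittivity * EPS0
    sig_e = effective_conductivity(particle)
    sig_m = medium.conductivity
    w2 = (2.0 * math.pi * freq) ** 2
    num = (eps_e - eps_m) * (eps_e + 2 * eps_m) * w2 + (sig_e - sig_m) * (sig_e + 2 * sig_m)
    den = (eps_e + 2 * eps_m) ** 2 * w2 + (sig_e + 2 * sig_m) ** 2
    out = num / den
    return float(out) if out.ndim == 0 else out


def crossover_frequency(particle: Particle, medium: Medium) -> float:
    """Closed-form DEP crossover frequency N_cr in Hz.

    Raises :class:`NoCrossoverError` when the conductivity and permittivity
    contrasts have the same sign, in which case Re[f_CM] never changes sign.
    """
    eps_e = particle.material.rel_permittivity * EPS0
    eps_m = medium.rel_permittivity * EPS0
    sig_e = effective_conductivity(particle)
    sig_m = medium.conductivity
    radicand = ((sig_e + 2 * sig_m) * (sig_m - sig_e)) / (
        (eps_e + 2 * eps_m) * (eps_e - eps_m)
    )
    if radicand <= 0:
        raise NoCrossoverError(
            "no real crossover frequency: particle never switches DEP sign "
            f"(radicand={radicand:.3e})"
        )
    return math.sqrt(radicand) / (2.0 * math.pi)


def cm_spectrum(
    particle: Particle,
    medium: Medium,
    f_min: float = 1e2,
    f_max: float = 1e9,
    n_points: int = 200,
) -> np.ndarray:
    """Re[f_CM] over a log-spaced frequency grid.

    Returns an (n_points, 2) array of (frequency Hz, Re[f_CM]) suitable for
    plotting a DEP dispersion curve.
    """
    freqs = np.logspace(math.log10(f_min), math.log10(f_max), n_points)
    return np.column_stack([freqs, re_cm_factor(particle, medium, freqs)])
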