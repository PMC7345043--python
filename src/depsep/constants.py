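"""Physical constants and unit conversions used across the package.

All internal computation is in SI units.  The vacuum permittivity is kept at
the four-digit engineering value commonly used in the dielectrophoresis
literature; crossover frequencies quoted to four significant figures are
insensitive to the remaining digits.
"""

import math

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12

#: Standard gravitational acceleration, m/s^2.
GRAVITY = 9.81

#: Peak-to-peak -> RMS conversion for a sinusoidal drive: Vrms = Vpp / (2*sqrt(2)).
VPP_TO_VRMS = 1.0 / (2.0 * math.sqrt(2.0))


def ul_per_h_to_m3_per_s(q: float) -> float:
    """Convert a volumetric flow rate from uL/h to m^3/s."""
    return q * 1e-9 / 3600.0


def m3_per_s_to_ul_per_h(q: float) -> float:
    return q * 3600.0 / 1e-9
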