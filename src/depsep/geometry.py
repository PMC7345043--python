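"""Channel and electrode-array geometry.

Coordinate convention: x is axial (from the inlet), y in [0, W_ch] is the
spanwise coordinate (the two sidewalls at y=0 and y=W_ch carry the
electrodes), z in [0, H_ch] is vertical with gravity along -z.

Each sidewall carries ``electrodes_per_side`` vertical electrodes of axial
length l separated by gaps d, alternating signal/ground, so one repeating
unit of the array (one signal + one ground electrode per side) has axial
period L_u = 2 (l + d) and the whole array spans L_arr = (n/2) L_u from the
inlet.  Electrodes span the full channel height.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DeviceGeometry"]


@dataclass(frozen=True)
class DeviceGeometry:
    channel_width: float  # W_ch, m (y extent)
    channel_height: float  # H_ch, m (z extent)
    electrode_length: float  # l, m (axial)
    electrode_gap: float  # d, m (axial)
    electrodes_per_side: int  # n, even
    vpp_side1: float = 0.0  # peak-to-peak drive of the y=0 wall, V
    vpp_side2: float = 0.0  # peak-to-peak drive of the y=W_ch wall, V

    def __post_init__(self):
        for name in ("channel_width", "channel_height", "electrode_length", "electrode_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        n = self.electrodes_per_side
        if n <= 0 or n % 2 != 0:
            raise ValueError("electrodes_per_side must be a positive even count")
        if self.vpp_side1 < 0 or self.vpp_side2 < 0:
            raise ValueError("peak-to-peak voltages must be >= 0")

    @property
    def unit_period(self) -> float:
        """Axial period of the repeating electrode unit, L_u = 2 (l + d)."""
        return 2.0 * (self.electrode_length + self.electrode_gap)

    @property
    def array_length(self) -> float:
        """Axial extent of the electrode array, L_arr = (n/2) L_u."""
        return (self.electrodes_per_side // 2) * self.unit_period
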