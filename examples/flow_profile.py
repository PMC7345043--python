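"""Laminar velocity profile of the 100 x 100 um separation channel.

Evaluates the analytical rectangular-duct series at 200 uL/h and verifies
that integrating it over the cross-section recovers the imposed volumetric
flow rate.
"""

import numpy as np
from scipy.integrate import simpson

import depsep as ds
from depsep.flow import FlowSpec, axial_velocity, mean_velocity

geo = ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30)
spec = FlowSpec(ds.ul_per_h_to_m3_per_s(200), geo)

u_mean = mean_velocity(spec)
u_max = axial_velocity(50e-6, 50e-6, spec)
print(f"mean velocity   : {u_mean * 1e3:.3f} mm/s")
print(f"center velocity : {u_max * 1e3:.3f} mm/s  (x{u_max / u_mean:.3f} the mean)")
print(f"near-wall (10,10) um : {axial_velocity(10e-6, 10e-6, spec) * 1e3:.3f} mm/s")

y = np.linspace(0, 100e-6, 201)
Y, Z = np.meshgrid(y, y, indexing="ij")
q = simpson(simpson(axial_velocity(Y, Z, spec), x=y, axis=1), x=y)
print(f"quadrature of u over the cross-section: {q * 3.6e12:.2f} uL/h (imposed: 200)")
# Particles released near a wall move several times slower than the mean,
# so they spend much longer between the electrodes than center-line ones.
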