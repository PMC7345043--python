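"""Full separation run at the reference operating point.

Releases 81 particles of each size (2.5 and 5 um) from a uniform 9x9 inlet
grid, tracks every trajectory, and reports separation efficiency (SE) and
purity (SP) per size.  Grid spacing 5 um keeps this a desk-scale run.
"""

import depsep as ds
from depsep.metrics import Scenario, run_scenario

scenario = Scenario(
    geometry=ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30, 20.0, 12.5),
    medium=ds.Medium(),
    particle_small=ds.Particle(2.5e-6, ds.POLYSTYRENE),
    particle_big=ds.Particle(5.0e-6, ds.POLYSTYRENE),
    flow_rate=ds.ul_per_h_to_m3_per_s(200),
    spacing=5e-6,
)
res = run_scenario(scenario)
rep = res.report

print(f"operating frequency: {res.frequency / 1e3:.1f} kHz "
      f"(Re[f_CM] small {res.re_fcm_small:+.3f}, big {res.re_fcm_big:+.1e})")
for size, counts in (("2.5 um", rep.counts_small), ("5.0 um", rep.counts_big)):
    print(f"{size}: {counts}")
print(f"SE(2.5 um) = {rep.se_small:.1f}%   SE(5 um) = {rep.se_big:.1f}%")
print(f"SP(2.5 um) = {rep.sp_small:.1f}%   SP(5 um) = {rep.sp_big:.1f}%")
# Captured small particles are recovered later by flushing with the field
# off, so SE(small) counts captures; SE(big) counts outlet arrivals during
# processing.  SP(small) dips below 100% only if big particles sediment
# onto the channel floor before reaching the outlet.
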