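"""Dielectric dispersion of the two particle sizes.

Computes the real part of the Clausius-Mossotti factor over frequency for
2.5 um and 5 um polystyrene microspheres in a low-conductivity aqueous
medium, and the crossover frequency of each.  The separator is driven at
the big particle's crossover: there the big particle feels no DEP while the
small one still feels positive DEP.
"""

import depsep as ds

medium = ds.Medium()  # eps_m=78.5, sigma_m=1e-4 S/m
small = ds.Particle(2.5e-6, ds.POLYSTYRENE)
big = ds.Particle(5.0e-6, ds.POLYSTYRENE)

for name, p in (("2.5 um", small), ("5.0 um", big)):
    ncr = ds.crossover_frequency(p, medium)
    print(f"{name}: sigma_eff = {ds.effective_conductivity(p):.3e} S/m, "
          f"crossover = {ncr / 1e3:.1f} kHz")

f_op = ds.crossover_frequency(big, medium)
print(f"\nAt the operating frequency {f_op / 1e3:.1f} kHz:")
print(f"  Re[f_CM](small) = {ds.re_cm_factor(small, medium, f_op):+.3f}  (positive DEP -> captured)")
print(f"  Re[f_CM](big)   = {ds.re_cm_factor(big, medium, f_op):+.2e}  (no DEP -> transits)")

table = ds.cm_spectrum(big, medium, 1e3, 1e8, 9)
print("\nfrequency_Hz  Re[f_CM] (5 um)")
for f, v in table:
    print(f"{f:12.3e}  {v:+.3f}")
# The sign flips from + to - across the crossover: below it surface
# conduction dominates (pDEP), above it the permittivity contrast (nDEP).
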