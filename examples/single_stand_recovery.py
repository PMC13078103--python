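"""Grow one replanted stand with fixed vs temperature-responsive wood density.

Simulates 150 years of post-disturbance regrowth at a warm site under a
repeating 30-year climate, once with the fixed 186 kgC/m^3 density and once
with the dynamic logistic response, and prints how stature, stocking and
stem density diverge.
"""

import numpy as np

from ringdemog.demography import SimulatorConfig, canopy_closure_year, simulate_stand
from ringdemog.synth import DEFAULT_RANGE_RESPONSE, gen_climate, gen_site_gradient

site = gen_site_gradient().hottest
climate = gen_climate(site, 150, seed=7)
t_jas = climate.jas_series().to_numpy()

static = simulate_stand(t_jas, SimulatorConfig(mode="static"))
dynamic = simulate_stand(t_jas, SimulatorConfig(mode="dynamic", response=DEFAULT_RANGE_RESPONSE))

print(f"site {site.site_id}: JAS mean {site.jas_mean:.1f} C (warm end of the gradient)")
print(f"{'year':>4} {'H_std':>7} {'H_dyn':>7} {'trees_std':>9} {'trees_dyn':>9} {'SWD_dyn':>8}")
for y in (10, 30, 60, 100, 150):
    i = y - 1
    print(
        f"{y:4d} {static['height_m'][i]:7.2f} {dynamic['height_m'][i]:7.2f} "
        f"{static['trees_ha'][i]:9.1f} {dynamic['trees_ha'][i]:9.1f} "
        f"{dynamic['swd_kgC_m3'][i]:8.1f}"
    )
print()
print("closure year  static :", canopy_closure_year(static["canopy_fraction_pre"]))
print("closure year  dynamic:", canopy_closure_year(dynamic["canopy_fraction_pre"]))
rw = dynamic["ring_width_m"][9:100]
rd = dynamic["ring_density_kgC_m3"][9:100]
print(f"ring width vs density correlation (years 10-100): {np.corrcoef(rw, rd)[0, 1]:.2f}")
print()
print("At a warm site the dynamic mode builds denser wood than the 186")
print("kgC/m^3 baseline, so trees end up shorter, the canopy closes later,")
print("and after closure more (smaller) trees survive per hectare.  Warm")
print("years make dense and therefore narrow rings: the correlation above")
print("is negative.")
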