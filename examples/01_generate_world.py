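"""Generate a synthetic world and inspect its base-year calibration.

The generator builds a FAOSTAT-like country-level calibration for a
focus root crop traded alongside two larger staple markets: one big
rest-of-world exporter bloc, one large target-eligible producer, and a
heavy tail of small producers.  Base-year market clearing is exact by
construction, and the same seed reproduces the same world bit for bit.
"""

import numpy as np

from cropforesight import GeneratorConfig, generate_world, validate_world

world = generate_world(GeneratorConfig(seed=2019))
print(f"regions:     {world.region_ids}")
print(f"commodities: {world.commodity_ids} (focus: "
      f"{world.commodity_ids[world.focus_index]})")
print(f"horizon:     {world.years[0]}..{world.years[-1]} ({world.n_years} years)")

cal = world.calibration
f = world.focus_index
prod = cal.supply_base[:, f]
net = cal.supply_base[:, f] - cal.demand_base[:, f]
print("\nfocus-crop base year (kt):")
print(f"{'region':8s} {'production':>12s} {'share':>7s} {'net trade':>11s}")
for i, rid in enumerate(world.region_ids):
    print(f"{rid:8s} {prod[i]:12.0f} {prod[i] / prod.sum():7.1%} {net[i]:11.0f}")

print(f"\nworld price (US$/t): {cal.price_base[f]:.1f}")
print(f"supply elasticities:  {np.round(cal.supply_elasticity()[:, f], 3)}")
print(f"validation problems:  {validate_world(world) or 'none'}")
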