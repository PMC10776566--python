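"""Simulate passive larval drift between two spawning banks and print the
connectivity matrix and dispersal-distance statistics.

A uniform 0.12 m/s eastward current carries larvae from an upstream bank
toward a downstream one; particles drift for up to 10 days at hourly steps.
"""

import numpy as np

from seaconnect.dispersal import connectivity_matrix, dispersal_stats, run_simulation
from seaconnect.fixtures import FixtureConfig, make_sites, make_velocity_field

cfg = FixtureConfig(seed=1, grid_extent=(-2.0, 2.0, -2.0, 2.0), grid_step=0.25, n_days=14)
field = make_velocity_field(cfg, "uniform", {"u": 0.12, "v": 0.0})
sites = make_sites(
    cfg,
    [("Upstream", -1.0, 0.0, 9.0, (2, 5)), ("Downstream", -0.4, 0.0, 9.0, (2, 5))],
    field=field,
    settlement_buffer_km=5.0,
)

trajs = run_simulation(field, sites, years=[2008], release_per_day=1, max_days=10, min_age_hours=48.0)
cm = connectivity_matrix(trajs, sites)
stats = dispersal_stats(trajs)

print(f"released {len(trajs)} particles from {len(sites)} sites")
print("\nconnectivity matrix P[i][j] = fraction released at i settling at j:")
print(cm.to_dataframe().round(3))
print("\npooled dispersal distances (km):")
for k, v in stats["pooled"].items():
    print(f"  {k:>5}: {v:.2f}" if isinstance(v, float) else f"  {k:>5}: {v}")
print(
    "\nEach matrix row is a source site; the diagonal is local retention. "
    "The 0.12 m/s current moves larvae ~10.4 km/day, so the downstream bank "
    "(~67 km away) is reached in about a week."
)
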