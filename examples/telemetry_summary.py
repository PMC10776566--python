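"""Summarise adult movements from a tagged fish's detection track: distances
travelled and transitions between two coastal zones.
"""

import numpy as np
from shapely.geometry import box

from seaconnect.fixtures import FixtureConfig, make_track
from seaconnect.telemetry import annual_distance_km, track_distances, zone_transitions

cfg = FixtureConfig(seed=5)
waypoints = [(-7.9, 37.0), (-8.9, 37.0), (-9.3, 38.4), (-9.0, 38.7), (-8.9, 37.0), (-7.9, 37.0)]
times = np.array(["2019-01-05", "2019-03-01", "2019-05-10", "2019-06-20", "2019-09-01", "2019-11-15"],
                 dtype="datetime64[ns]")
track = make_track(cfg, waypoints, times, fish_id="meagre01")

d = track_distances(track)
print(f"fish {track.fish_id}: {len(track)} positions over {(times[-1] - times[0]).astype('timedelta64[D]')}")
print(f"cumulative path length: {d['cumulative_km']:.0f} km")
print(f"maximum displacement:   {d['max_displacement_km']:.0f} km")
print(f"best 365-day distance:  {annual_distance_km(track):.0f} km")

zones = {"south_coast": box(-9.0, 36.5, -7.3, 37.3), "west_coast": box(-9.8, 37.8, -8.6, 39.2)}
res = zone_transitions(track, zones)
print(f"\nzone sequence: {res['labels']}")
for ev in res["events"]:
    print(f"  {str(ev['time'])[:10]}: {ev['from']} -> {ev['to']}")
print("\nGreat-circle legs on a spherical Earth; transitions are consecutive records in different zones.")
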