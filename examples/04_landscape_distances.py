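"""Resistance surfaces and the three landscape distances between points.

Converts a landcover raster into the empirical (EMP) resistance surface,
then compares straight-line distance, least-cost-path distance (one optimal
corridor) and random-walk commute distance (all routes at once) between
sampling points.
"""

import numpy as np

from uhedge.connectivity import (
    build_transition_graph,
    commute_distance,
    euclidean_distance,
    lcp_distance,
    passage_map,
)
from uhedge.resistance import build_resistance_surface, load_hypotheses
from uhedge.synthetic_data import default_landscape_spec, generate_landscape, sample_locations

lc = generate_landscape(default_landscape_spec(32, 32), seed=7)
hyps = load_hypotheses()
surface = build_resistance_surface(lc, hyps["EMP"])
print(f"surface {surface.shape}, {int(surface.barrier.sum())} barrier cells "
      "(buildings and waterbodies are non-traversable)")

points = sample_locations(surface, 5, seed=8)[["id", "x", "y"]]

euc = euclidean_distance(points)
g_lcp = build_transition_graph(surface)  # no epsilon repair for LCP
lcp = lcp_distance(g_lcp, points)
g_com = build_transition_graph(surface, epsilon=1e-4)  # repair for random walk
com = commute_distance(g_com, points)

print("\npair      euclid(m)   lcp(cost*m)   commute(steps)")
ids = list(points["id"])
for i in range(len(ids)):
    for j in range(i + 1, len(ids)):
        print(f"{ids[i]}-{ids[j]:<6s} {euc.values[i, j]:>8.0f} {lcp.values[i, j]:>12.0f} "
              f"{com.values[i, j]:>14.0f}")

pm = passage_map(g_com, points)
print(f"\npassage map: max expected net passages per cell = {pm.values.max():.2f}")
print("high-passage cells are the pinch points every random walk between the")
print("points must funnel through - candidate movement corridors.")
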