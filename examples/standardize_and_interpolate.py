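"""Bring raw indicator surfaces onto the common 0-10 vulnerability scale.

Builds a small elevation-like raster and a handful of monitoring stations,
then shows the three standardization routes: range standardization for a
positive indicator, for a negative indicator, and inverse-distance-weighted
interpolation of station values onto the grid.
"""

import numpy as np

from ecovuln import Grid, StationSet, idw_interpolate, standardize
from ecovuln.indicators import assign_categories

rng = np.random.default_rng(0)

# a 20 x 20 raster of some raw measurement, 30 m cells
raw = Grid(values=rng.normal(800, 150, (20, 20)), cell_size=30.0,
           origin=(0.0, 600.0))

pos = standardize(raw, "positive", name="pressure")
neg = standardize(raw, "negative", name="capacity")
print(f"raw range      : {raw.values.min():8.1f} .. {raw.values.max():8.1f}")
print(f"positive scaled: {pos.grid.values.min():8.2f} .. {pos.grid.values.max():8.2f}")
print(f"negative scaled: {neg.grid.values.min():8.2f} .. {neg.grid.values.max():8.2f}")
print("positive + negative at any cell:",
      round(pos.grid.values[3, 3] + neg.grid.values[3, 3], 6))
# the two polarities are mirror images: they always sum to 10, and a larger
# standardized value always means a more vulnerable cell

landuse = Grid(values=rng.integers(1, 6, (20, 20)).astype(float))
scored = assign_categories(landuse, {1: 2.0, 2: 4.0, 3: 6.0, 4: 8.0, 5: 2.0},
                           name="land_use")
print("land-use scores present:", sorted(set(scored.grid.values.ravel())))

# five stations; interpolate their values to every cell
stations = StationSet(points=np.column_stack([
    rng.uniform(0, 600, 5), rng.uniform(0, 600, 5), rng.normal(15, 3, 5)]))
surface = idw_interpolate(stations, raw, power=2.0, k_neighbors=None)
print(f"station values : {np.round(stations.values, 2)}")
print(f"interpolated   : {surface.values.min():.2f} .. {surface.values.max():.2f}")
# IDW output is always bounded by the station minimum and maximum
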