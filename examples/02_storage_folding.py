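"""Storage folding of the blob-ELLR weight matrix.

Builds the per-slice-plane weight matrix at symmetry levels 0-3 on a small
geometry and verifies every folded level against the dense brute-force matrix,
then forecasts the memory of a production-size slice plane analytically.
"""

import numpy as np

import blobtomo as bt

geom = bt.make_geometry([-60.0, -45.0, -30.0, -15.0, 15.0, 30.0, 45.0, 60.0], 48)
grid = bt.PixelGrid(32, 32)
dense = bt.dense_oracle(geom, grid)

print(f"slice plane: {grid.n_x}x{grid.n_z} pixels, {geom.n_views} views, "
      f"{geom.n_rays} rays -> W is {geom.n_values}x{grid.n_pixels}")
print(f"{'level':>5} {'stored':>8} {'ratio':>8}  max |folded - dense|")
for level in range(4):
    ellr = bt.build(geom, grid, symmetry_level=level)
    stats = ellr.storage_stats()
    diff = np.abs(ellr.materialize() - dense).max()
    print(f"{level:>5} {stats.stored_entries:>8} {stats.ratio_vs_unsym:>8.4f}  {diff:.2e}")
print("level 1 keeps 1/4 (one offset per view instead of four window entries),")
print("level 2 halves it (pixel point-reflection), level 3 halves again")
print("(paired +/- tilt views): 1/16 of the unfolded arrays, same matrix.")

stats = bt.storage_forecast(n_views=119, n_pixels=2048 * 430, symmetry_level=0)
print(f"\nunfolded arrays for a 2048x430 plane, 119 views: "
      f"{stats.nbytes / 1e9:.2f} GB (4+4 bytes/entry)")
folded = bt.storage_forecast(n_views=119, n_pixels=2048 * 430, symmetry_level=3)
print(f"fully folded: {folded.nbytes / 1e9:.3f} GB "
      f"({100 * folded.ratio_vs_unsym:.2f}% of baseline)")
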