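"""Build a travel segment table from raw trip records.

Generates a small synthetic reservation set, then applies the
preprocessing chain: seasonal window at both endpoints, low-frequency
pair drop, 15 km grid aggregation, and 15% return-segment augmentation.
"""

from campnet import (
    GridSpec,
    SeasonModel,
    generate_landscape,
    generate_trips,
    preprocess,
)

landscape = generate_landscape(n_centers=40, n_campgrounds=25, extent=(-10, 38, 10, 50), seed=1)
trips = generate_trips(landscape, n_trips=5000, seed=1)
grid = GridSpec.from_extent(-10, 38, 10, 50, cell_size=15.0)

table = preprocess(trips, grid, season=SeasonModel(), min_trips=4, return_fraction=0.15)

print(f"raw trips:            {len(trips)}")
print(f"segments kept:        {len(table.entries)}")
print(f"network cells:        {table.n}")
print(f"total segment weight: {table.total_weight():.1f}")
# Each segment (i, j) carries m_ij, the seasonal trip frequency between two
# 15 km map cells; return segments add 15% of each forward weight in the
# opposite direction, modelling unburned firewood carried home.
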