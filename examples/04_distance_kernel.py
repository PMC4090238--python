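"""Distance calibration of the synthetic trip generator.

Generates 100,000 trips with the default lognormal kernel and reports
the share of short (<= 100 km) and long (> 500 km) one-way trips.
"""

import numpy as np

from campnet import DEFAULT_KERNEL, generate_landscape, generate_trips, trip_distances_km

print(f"kernel: lognormal(mu={DEFAULT_KERNEL.mu:.3f}, sigma={DEFAULT_KERNEL.sigma:.3f})")
landscape = generate_landscape(seed=0)
trips = generate_trips(landscape, 100_000, seed=0)
d = trip_distances_km(trips)
print(f"trips <= 100 km: {100 * np.mean(d <= 100):.1f}%   (target ~50%)")
print(f"trips  > 500 km: {100 * np.mean(d > 500):.1f}%   (target ~10%)")
print(f"longest trip:    {d.max():.0f} km")
# The kernel parameters are solved from the two quantile constraints
# P(D <= 100 km) = 0.5 and P(D <= 500 km) = 0.9; the generator's
# importance-corrected campground choice reproduces them on any landscape.
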