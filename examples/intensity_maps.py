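"""Kernel-smoothed intensity maps of colony density and disease reoccurrence.

Builds the two point-pattern surfaces that describe a surveyed site: where
colonies are dense, and where disease kept coming back (each colony weighted
by its number of diseased survey months).  Prints the surface integrals,
which equal the (weighted) colony counts by construction of the edge
correction.
"""

import numpy as np

from whitepox import (
    ScenarioConfig,
    generate_panel,
    kernel_intensity,
    reoccurrence_weights,
)

panel, _ = generate_panel(ScenarioConfig(), seed=11)
xy = panel.coordinates
window = (0.0, 220.0, 0.0, 560.0)

density = kernel_intensity(xy, window, bandwidth=40.0)
weights = reoccurrence_weights(panel.presence)
disease = kernel_intensity(xy, window, bandwidth=40.0, weights=weights)

print(f"colony density surface integral:  {density.integral():.1f} (n = {len(xy)})")
print(
    f"reoccurrence surface integral:    {disease.integral():.1f} "
    f"(total diseased colony-months = {weights.sum():.0f})"
)
peak = np.unravel_index(np.argmax(disease.values), disease.values.shape)
print(
    f"disease hotspot near easting {disease.grid_x[peak[1]]:.0f} m, "
    f"northing {disease.grid_y[peak[0]]:.0f} m "
    f"({disease.values[peak]*1e4:.2f} weighted points per hectare)"
)
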