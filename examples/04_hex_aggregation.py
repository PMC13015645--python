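"""Aggregate village PM2.5 and proxies onto a 5 km hexagonal grid.

Villages are joined to the hexagon containing their centroid, summarised
by the mean, and assigned bivariate display classes: WRND breakpoints
(10, 20), EM breakpoints (2, 4 km), EH terciles and PM2.5 quintiles.
"""

import roadproxy as rp

landscape = rp.generate_landscape(seed=1, n_villages=12)
params = rp.ExposureModelParams(seed=1)
pm = rp.sample_village_exposure(landscape, params, n_samples=25)

table = rp.proxy_table(landscape).merge(pm, on="village_id")
table = table.rename(columns={"wrnd_kmkm2": "wrnd", "em_km": "em", "eh_km": "eh"})
table["x"] = [v.centroid.x for v in landscape.villages]
table["y"] = [v.centroid.y for v in landscape.villages]

hexes = rp.make_hex_grid(landscape.extent, width=5000.0)
aggs = rp.assign_classes(rp.aggregate_to_hex(hexes, table))
print(rp.hex_table(aggs).to_string(index=False))
# Each row is one occupied hexagon: n_villages members, mean PM2.5 and
# proxies, and the class codes used for bivariate mapping.
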