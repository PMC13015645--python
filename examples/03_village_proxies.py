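"""Compute the three road-traffic proxies for every village.

WRND is the population-weighted mean of per-cell road density on a 100 m
fishnet aligned to the population raster; EM and EH are straight-line
distances from the village centroid to the nearest main road / highway.
"""

import roadproxy as rp

landscape = rp.generate_landscape(seed=1, n_villages=6)
table = rp.proxy_table(landscape)
print(table.to_string(index=False))
# wrnd_kmkm2: road km per km2, averaged over the village's populated
# cells; 0 means no road crosses the village boundary. em_km / eh_km:
# centroid distance to the nearest main road / highway in km.
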