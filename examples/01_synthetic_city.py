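"""Generate a synthetic gridded city and write its layers as GeoJSON.

The city emulates the data a municipal accessibility study needs: roads
with speed classes, deliberately disconnected per-block sidewalks, bus
corridors with stops, a train line with stations, census units (DAs)
with populations and deprivation covariates, and clinics concentrated
towards the core.
"""

from spar_access import CityConfig, generate_city
from spar_access.geojson_io import write_bundle

city = generate_city(CityConfig(seed=42))
paths = write_bundle(city, "scratch_city")

print(f"blocks            : {city.config.blocks_per_side}^2 "
      f"({city.config.block_m:.0f} m each)")
print(f"road segments     : {len(city.roads)}")
print(f"sidewalk segments : {len(city.sidewalks)} (disconnected per block)")
print(f"bus routes/stops  : {len(city.bus_routes)}/{len(city.bus_stops)}")
print(f"train stations    : {len(city.stations)}")
print(f"dissemination areas: {len(city.das)} "
      f"(populations {min(p.population for p in city.das)}-"
      f"{max(p.population for p in city.das)})")
print(f"clinics           : {len(city.clinics)} "
      f"({sum(c.providers for c in city.clinics)} providers)")
print(f"layers written to : scratch_city/ ({len(paths)} GeoJSON files)")
# Every quantity is reproducible bit-for-bit from (config, seed).
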