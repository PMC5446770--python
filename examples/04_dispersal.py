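"""Winter dispersal between bays and pre-breeding excursions.

Detects the mid-winter switch between the two coastal wintering bays
(an occupied-region change persisting >= 24 h) and any post-arrival
excursion >= 100 km from the breeding colony.
"""

from relicttrack import (DiscRegion, PolygonRegion, SimConfig,
                         detect_prebreeding_dispersal, detect_winter_dispersal,
                         filter_track, load_regions, simulate_annual_track)

regions = load_regions()
colony = next(r for r in regions if isinstance(r, DiscRegion))
bays = [r for r in regions if isinstance(r, PolygonRegion)]

track, truth = simulate_annual_track(SimConfig(seed=5), winter_regions=bays)
kept = filter_track(track).kept

print("winter dispersal events (>= 24 h persistence):")
for ev in detect_winter_dispersal(kept, bays,
                                  start=truth.autumn_arrival,
                                  end=truth.spring_departure):
    print(f"  {ev.from_region} -> {ev.to_region} on {ev.date.date}")
print("truth:", [(a, b, t.date().isoformat())
                 for a, b, t in truth.winter_events])

events = detect_prebreeding_dispersal(kept, colony.center,
                                      min_km=100.0,
                                      after=truth.spring_arrival)
print()
if events:
    for ev in events:
        print(f"pre-breeding excursion: peak {ev.excursion_km:.0f} km from "
              f"the colony, away {ev.duration_days:.1f} d "
              f"(open-ended: {ev.open_ended})")
else:
    print("no pre-breeding excursion this year")
if truth.prebreeding:
    print(f"truth: {truth.prebreeding['excursion_km']:.0f} km, "
          f"{truth.prebreeding['duration_days']:.1f} d")
print()
print("The 24-h persistence rule stops duty-cycle flicker at a bay")
print("boundary from being read as dispersal; excursion distance is the")
print("maximum great-circle displacement from the colony.")
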