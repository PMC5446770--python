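"""Phenology statistics on the packaged reference journey table.

Loads the 20 autumn + 13 spring Relict Gull journeys that ship with the
package and runs the full statistics battery: distance summaries,
segment t-tests, between-individual ANOVA and Lessells-Boag
repeatability, and wintering-residence durations.
"""

from relicttrack.pipeline import fixture_statistics

s = fixture_statistics()

print(f"autumn journeys: {s['n_autumn_journeys']}, "
      f"spring journeys: {s['n_spring_journeys']}")
print(f"autumn distance:  {s['autumn_mean_total_km']:.0f} km mean "
      f"(sd {s['autumn_sd_total_km']:.0f})")
print(f"spring distance:  {s['spring_mean_total_km']:.0f} km mean")
print(f"autumn stopovers: {s['autumn_mean_n_stopovers']:.1f} mean")
print()
print("first/last vs middle segments of multi-stopover journeys:")
print(f"  {s['first_last_mean_km']:.0f} km vs {s['middle_mean_km']:.0f} km, "
      f"t = {s['t_first_last_vs_middle']:.2f}, "
      f"df = {s['df_first_last_vs_middle']}")
print("spring vs autumn segment lengths:")
print(f"  t = {s['t_spring_vs_autumn_segments']:.3f}, "
      f"df = {s['df_spring_vs_autumn_segments']}")
print()
print("individual as ANOVA factor (all 9 birds, df 8,11):")
print(f"  autumn departure date  F = {s['F_autumn_departure_all']:.2f}")
print(f"  autumn duration        F = {s['F_autumn_duration_all']:.2f}")
print("repeatability, birds with >= 2 round trips (df 3,10):")
print(f"  winter arrival date    F = {s['F_winter_arrival_repeat']:.2f}, "
      f"r = {s['r_winter_arrival_repeat']:.2f}")
print(f"  autumn duration        F = {s['F_autumn_duration_repeat']:.2f}, "
      f"r = {s['r_autumn_duration_repeat']:.2f}")
print()
print(f"wintering residence: mean {s['wintering_mean_days']:.0f} d, "
      f"minimum {s['wintering_min_days']} d "
      f"over {s['n_wintering_seasons']} seasons")
print()
print("A large F for autumn timing means individuals differ consistently")
print("from each other between years; r is the fraction of variance")
print("attributable to the individual (high for winter arrival, so each")
print("bird arrives on 'its own' date year after year).")
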