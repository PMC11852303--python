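"""Classify the 31 established non-native Florida fishes as fast or slow
spreaders from the packaged inputs (years since first record, occupied
area, lower lethal temperature).

Each species' occupied area is divided by its thermal potential range to
a percentage, then by years since first record; at or above 0.16 %/yr is
a fast spreader. The printed table lists the five fastest and five
slowest normalized spreaders.
"""

import spreadquant as sq

records = sq.load_florida_species()
zones = sq.load_florida_zones()
table = sq.build_species_table(records, zones, cutoff=0.16)

counts = table["category"].value_counts()
print(f"{len(table)} species: {counts['fast']} fast, {counts['slow']} slow\n")

cols = ["species", "spread_rate", "potential_range_km2", "pct_range_per_yr", "category"]
ranked = table.sort_values("pct_raw", ascending=False)
print("fastest five (% of potential range colonized per year):")
print(ranked.head(5)[cols].to_string(index=False))
print("\nslowest five:")
print(ranked.tail(5)[cols].to_string(index=False))
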