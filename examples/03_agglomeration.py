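"""Agglomeration degrees: geographic and demographic fairness in one table.

HRAD (health-resource agglomeration degree) compares a unit's share of a
resource with its share of land area; PAD does the same for population.
HRAD = 1 means geographically fair; HRAD/PAD = 1 means the resource follows
the population.
"""

from equipanel import (
    AgglomerationRow, GeneratorConfig, build_agglomeration_table,
    classify_agglomeration, generate_panel,
)

panel = generate_panel(GeneratorConfig(seed=42))
table5 = build_agglomeration_table(panel, 2018)

regions = table5[table5["unit"].str.endswith("region")]
print(regions[["unit", "pad", "hrad_beds", "ratio_beds"]].to_string(index=False))

print("\nfairness labels (beds):")
for _, row in regions.iterrows():
    agg = AgglomerationRow.build(row["unit"], row["hrad_beds"], row["pad"])
    geo, demo = classify_agglomeration(agg)
    print(f"  {row['unit']:<16} geographic: {geo.label:<17} demographic: {demo.label}")
# ratio_beds is beds per capita in the unit relative to the national level:
# above 1 the unit holds more beds per person than the country as a whole.
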