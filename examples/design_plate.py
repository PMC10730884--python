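"""Design the 384-well destination plate and emit the nanoliter transfer list.

The plate is split into three 128-well reaction zones (Ugi A1-F8,
Ugi-formaldehyde F9-K16, Ugi-tetrazole K17-P24); each zone receives a seeded
sparse-matrix sample of its product space.  Dosing follows the campaign
stoichiometry: 1 eq = 62.5 nmol per component, 2.4 eq for the azide.
"""

from d2bscreen import (
    DEFAULT_ZONES,
    SimConfig,
    build_transfer_list,
    design_plate,
    enumerate_space,
    gen_building_blocks,
    zone_wells,
)

blocks = gen_building_blocks(SimConfig(seed=0))
products = enumerate_space(blocks)

for scheme, (start, end) in DEFAULT_ZONES.items():
    print(f"{scheme.value:7s} zone {start}-{end}: {len(zone_wells(start, end))} wells")

design = design_plate(products, seed=0)
print(f"\nassigned wells: {len(design.assignments)}")

table = build_transfer_list(design.assignments, {b.id: b.role for b in blocks})
print("\nfirst well's transfers (volume in nL, stock in mol/L):")
print(table.head(4).to_string(index=False))
# Each 1-eq component delivers 62.5 nmol (125 nL x 0.5 M, or 250 nL x
# 0.25 M for the isocyanide); the azide row in UT4CR wells shows 150 nmol,
# i.e. 2.4 equivalents relative to the 62.5 nmol base.
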