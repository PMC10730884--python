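"""Enumerate the virtual Ugi-type library from a seeded building-block set.

Generates the default 87-member building-block set (28 amines, 28 oxo
components, 28 carboxylic acids plus isocyanide, formaldehyde and azide),
applies the three multicomponent-reaction transforms, and prints the library
size and one example product with its exact-mass bookkeeping.
"""

from d2bscreen import SimConfig, enumerate_space, gen_building_blocks, product_formula_string

blocks = gen_building_blocks(SimConfig(seed=0))
print(f"starting materials: {len(blocks)}")

products = enumerate_space(blocks)
per_scheme = {}
for p in products:
    per_scheme[p.scheme.value] = per_scheme.get(p.scheme.value, 0) + 1
print(f"virtual products: {len(products)}  (by scheme: {per_scheme})")

example = products[0]
print(f"\nexample product {example.product_id}")
print(f"  parents:   {'+'.join(example.parents)}")
print(f"  formula:   {product_formula_string(example)}")
print(f"  mono mass: {example.mono_mass:.4f} Da")
# The product formula is the sum of the parent formulas minus one water
# (plus HN3 delivered by the azide source for the tetrazole scheme), so the
# mono mass printed above equals the parent-mass sum minus 18.0106 Da.
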