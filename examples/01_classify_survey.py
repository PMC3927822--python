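"""Classify the packaged 366-genome survey into co-occurrence groups.

Each genome is binned by GluRS copy number and GlnRS/gatCAB presence into
one of five groups written <copies|glnS|gatCAB>; single-copy groups then map
directly onto GluRS functional types (ND, D(-), D(+)).
"""

from glxrs import genomes

rows = genomes.table1_inventory()
invs = genomes.build_inventory(rows)
table = genomes.tabulate_groups(invs)

print(table)
print(f"\ngenomes total: {table.values.sum()}")
print(f"gamma-proteobacteria in 1|+|- (GlnRS essential, no gatCAB): "
      f"{table.loc['gamma', '1|+|-']}")
print(f"alpha-proteobacteria with a GluRS2 copy: "
      f"{table.loc['alpha', ['2|-|+', '2|+|+']].sum()}")

group = genomes.classify_genome(invs[0])
types = genomes.assign_functional_types(group)
print(f"\nexample: genome {invs[0].genome_id} -> group {group.render()} -> {types}")
# The group alone fixes the functional annotation of single-copy GluRS:
# absent GlnRS means the lone GluRS must also charge tRNA-Gln (ND-GluRS).
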