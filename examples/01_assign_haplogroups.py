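"""Assign Y-SNP haplogroups against the bundled marker tree.

Builds three genotypes by hand — a deep Q-M3 paragroup chromosome, a
chromosome derived only at M242 (star paragroup), and a European R1b
chromosome — and prints the label each receives. Untyped markers are treated
as unknown, so hierarchical typing (most of the tree never typed) is fine.
"""
from ylineage import SNPGenotype, assign_haplogroup, default_tree, lineage_group

tree = default_tree()

genotypes = {
    "deep Q-M3 paragroup": SNPGenotype({
        "M242": "derived", "M3": "derived",
        "M19": "ancestral", "M194": "ancestral", "L663": "ancestral",
        "SA01": "ancestral", "L766": "ancestral",
    }),
    "derived at M242 only": SNPGenotype({"M242": "derived", "MEH2": "ancestral"}),
    "European R1b": SNPGenotype({"M343": "derived", "M242": "ancestral"}),
}

for desc, g in genotypes.items():
    call = assign_haplogroup(g, tree)
    print(f"{desc:25s} -> {call.label:45s} group: {lineage_group(call)}")

# The paragroup label "Q-M3 (x...)" lists the typed downstream markers that
# came back ancestral; "Q*-M242" means every typed downstream marker of M242
# was ancestral. The group is the continental-origin pool used for the
# regional admixture comparison (Inuit / European / Other).
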