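"""Structural equivalence on a schematic 12-peptide study.

Builds the small built-in peptide-protein-gene graph, groups peptides
with identical protein neighborhoods into SEPEPs, and prints each group.
"""
from sepepkit.datasets import toy_tripartite_graph
from sepepkit.sepeps import identify_sepeps

graph = toy_tripartite_graph()
sepeps = identify_sepeps(graph)

print(f"{len(graph.peptides())} peptides, {len(graph.proteins())} proteins, "
      f"{len(graph.genes())} genes -> {len(sepeps)} SEPEPs\n")
for sepep in sepeps:
    kind = "multi-gene" if len(sepep.gene_set) > 1 else next(iter(sepep.gene_set))
    print(f"  proteins {{{sepep.protein_key}}} [{kind}]: "
          f"{', '.join(sepep.member_peptides)}")

# Each line is one quantification unit: peptides listed together are
# indistinguishable by protein membership and will be quantified jointly.
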