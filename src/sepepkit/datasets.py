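"""Small built-in example data.

Everything here is synthetic/schematic, constructed in code; nothing is
loaded from external files.
"""
from __future__ import annotations

from .sepeps import TripartiteGraph

#: Protein -> host gene edges of the schematic worked example.
TOY_PROTEIN_TO_GENE = {
    "Pro1.1": "Gene1",
    "Pro1.2": "Gene1",
    "Pro2.1": "Gene2",
    "Pro2.2": "Gene2",
    "Pro3.1": "Gene3",
}

#: Peptide -> protein edges: 12 identified peptides across three genes,
#: including one multi-gene peptide (Pep12).
TOY_PEPTIDE_TO_PROTEINS = {
    "Pep1": ["Pro1.1"],
    "Pep2": ["Pro1.1"],
    "Pep3": ["Pro1.1", "Pro1.2"],
    "Pep4": ["Pro1.2"],
    "Pep5": ["Pro2.1"],
    "Pep6": ["Pro2.1"],
    "Pep7": ["Pro2.1", "Pro2.2"],
    "Pep8": ["Pro2.2"],
    "Pep9": ["Pro2.2"],
    "Pep10": ["Pro3.1"],
    "Pep11": ["Pro3.1"],
    "Pep12": ["Pro1.1", "Pro3.1"],
}


def toy_tripartite_graph() -> TripartiteGraph:
    """Schematic 12-peptide, 5-protein, 3-gene worked example.

    A synthetic minimal study illustrating structural equivalence: the
    twelve peptides fall into eight distinct protein neighborhoods,
    hence eight SEPEPs, one of them multi-gene.
    """
    return TripartiteGraph.from_edges(TOY_PEPTIDE_TO_PROTEINS, TOY_PROTEIN_TO_GENE)
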