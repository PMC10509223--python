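# sepepkit

Isoform-aware quantification for shotgun proteomics via **structurally
equivalent peptide groups (SEPEPs)** in a peptide–protein–gene tripartite
graph.

## The problem

In bottom-up proteomics most peptides are *degenerate*: their sequence
occurs in several protein isoforms of a gene, or in several genes of a
family. The dominant parsimony-based workflow collapses proteins into
minimal protein groups and assigns shared peptides to the group with the
most evidence. That prevents over-reporting, but it suppresses isoform
information: isoforms without unique peptides vanish, shared peptides
may be credited to the wrong isoform, and the reported representative
can flip between studies.

`sepepkit` takes the opposite route. Identified peptides, all proteins
containing them, and the proteins' host genes form a tripartite graph
G = (Pep ∪ Pro ∪ Gene, E). Peptides with *identical* protein
neighborhoods — N(p₁) = N(p₂) ⊆ Pro — are structurally equivalent and
are grouped into one **SEPEP**, the unit of identification, FDR control
and quantification. Every confidently identified peptide contributes,
and all isoform-distinguishing signal present in the data is preserved.

Each SEPEP is classified by its connection pattern:

| class | meaning |
|-------|---------|
| C1 | single-isoform gene |
| C2 | fully discriminative (one isoform of a multi-isoform gene) |
| C3 | partially discriminative (a proper subset of isoforms) |
| C4 | non-discriminative (all isoforms of the gene) |
| C5 | multi-gene |

SEPEP-level error control is target–decoy: reversed-sequence decoys
compete in the same graph, a SEPEP is a decoy hit iff its whole protein
neighborhood is decoy, the ranking statistic is the best member-peptide
identification score, FDR(r) = #decoys / max(1, #targets) among the top
r, and q-values are the monotonized running minimum. SEPEPs with
q > 0.01 are excluded. Quantification rolls member peptides up per
sample — sum of PSM counts (label-free) or median of log2 reporter
ratios (isobaric) — then median-centers ratio data with factors from
the gene-level matrix and drops features with more than 50% missing
values. Downstream, two-sided t tests or Pearson correlations with
Benjamini–Hochberg adjustment compare SEPEP- against gene-level results;
SEPEPs significant without matching gene-level significance flag
candidate isoform-specific regulation.

A fully seeded synthetic-study generator (isoform-rich proteomes built
from tryptic segments with exon-skip deletions, mutually exclusive
exon exchanges, alternative N-terminal exons, and paralog gene pairs;
peptide evidence with additive linear-scale mixing across isoforms,
detection noise and decoy contamination; planted isoform effects with
recorded ground truth) makes everything testable offline.

## Worked example

```python
from sepepkit import analyze_study, differential_test, discordance_report, discordance_summary
from sepepkit.simulate import SimulationConfig, recovery_metrics, simulate_study

config = SimulationConfig(seed=0)            # 200 genes, 20 planted isoform effects
db, evidence, truth = simulate_study(config)
result = analyze_study(db, evidence)         # decoys, graph, SEPEPs, FDR, rollup

sepep_res = differential_test(result.sepep_matrix, truth.group_labels)
gene_res  = differential_test(result.gene_matrix,  truth.group_labels)
report = discordance_report(sepep_res, gene_res, result.sepep_to_gene)
print(discordance_summary(report))
print(recovery_metrics(report, truth))
```

prints

```
     category  n_sepeps  n_genes
   concordant       695      199
   sepep_only        18       17
opposite_sign         0        0
{'sensitivity': 0.8, 'fdp': 0.06, ...}
```

meaning: of the quantifiable single-gene SEPEPs, 18 (from 17 genes) are
significantly different between the two groups while their host gene is
not — isoform-level events a gene-level analysis would have missed.
Sixteen of the twenty planted genes are among them (sensitivity 0.80)
and one reported gene carries no planted effect (false-discovery
proportion 0.06). The scripts in `examples/` walk through the other
capabilities (the schematic tripartite graph, proteome-wide peptide
classification, the full file-based pipeline) and print what each
number means.

There is also a thin CLI:

```bash
sepepkit simulate --out study/ --seed 5
sepepkit build --fasta study/proteome.fasta --gene-map study/gene_map.tsv \
    --evidence study/evidence.tsv --out results/
sepepkit stats --sepep-matrix results/sepep_matrix.tsv --gene-matrix results/gene_matrix.tsv \
    --mapping results/mapping_table.tsv --samples study/samples.tsv --groups group --out stats/
```

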