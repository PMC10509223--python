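"""Detecting planted isoform-specific regulation.

Simulates a two-group study with 20 regulated minor isoforms among 200
genes, tests every quantifiable SEPEP and gene (two-sided Welch t,
Benjamini-Hochberg), and reports SEPEPs significant without matching
gene-level significance -- the signature that gene-level analysis alone
would have missed the event.
"""
from sepepkit import analyze_study, differential_test, discordance_report, discordance_summary
from sepepkit.simulate import SimulationConfig, recovery_metrics, simulate_study

config = SimulationConfig(seed=0)  # 200 genes, 20 planted effects, n=20
db, evidence, truth = simulate_study(config)
result = analyze_study(db, evidence)

sepep_res = differential_test(result.sepep_matrix, truth.group_labels)
gene_res = differential_test(result.gene_matrix, truth.group_labels)
report = discordance_report(sepep_res, gene_res, result.sepep_to_gene)

print(discordance_summary(report).to_string(index=False))
metrics = recovery_metrics(report, truth)
print(f"\nplanted genes recovered : {metrics['sensitivity']:.2f}"
      f"  (of {int(metrics['n_planted'])})")
print(f"false-discovery proportion: {metrics['fdp']:.2f}")

# 'sepep_only' rows are isoform-level events invisible at the gene level;
# sensitivity is the fraction of planted genes carrying such a flag.
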