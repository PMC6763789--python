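"""Within-dataset classification with greedy AUC feature selection.

10 repetitions of stratified 5-fold cross-validation; inside each training
partition a 3-way rotation separates feature retrieval (classifier fitting)
from feature selection (greedy accept/reject by AUC), giving 150 optimised
classifiers evaluated on untouched test folds.  Subpathways selected more
often than the median count form the high-frequency (HF) set — the stable
biomarkers.
"""

import midrw as m

config = m.SimulationConfig(seed=42)
pathways, gene_expr, mirna_expr, labels, targets, truth = m.simulate_bundle(config)
gdpn = m.build_gdpn(pathways)
bundle = m.DataBundle(gene_expr, mirna_expr, labels, targets)

report = m.evaluate_within(bundle, gdpn, reps=10, folds=5, seed=7)
print(f"classifiers:    {len(report.records)}")
print(f"mean AUC:       {report.mean_auc:.4f} +/- {report.sd_auc:.4f}")
print(f"mean accuracy:  {report.mean_accuracy:.4f}")
print(f"HF subpathways: {sorted(report.hf_set)}")
print(f"implanted:      {sorted(truth.informative_mirnas)}")

# Mean AUC near 1 on this cohort reflects the implanted 1.5-sd signal; the
# HF set should recover most of the implanted miRNAs, showing that greedy
# selection repeatedly lands on the true features rather than noise.
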