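"""Infer miRNA-mediated subpathway activities.

The pipeline: filter zero-heavy features, score every gene and miRNA with a
case-vs-control t-test, seed the restart walk with |t| scores to get each
gene's topology score, define one subpathway per differential miRNA from
its inversely regulated differential targets inside the network, and
aggregate topology-weighted standardised expression into one activity value
per subpathway and sample.
"""

import midrw as m

config = m.SimulationConfig(seed=42)
pathways, gene_expr, mirna_expr, labels, targets, truth = m.simulate_bundle(config)
gdpn = m.build_gdpn(pathways)

model = m.fit_activity_model(gene_expr, mirna_expr, labels, targets, gdpn)
activity = model.transform(gene_expr, gene_expr.sample_ids)

print(f"subpathways defined: {len(activity.subpathway_ids)}")
first = model.defs[0]
print(
    f"example: {first.mirna_id} (t = {first.mirna_t:+.2f}) integrates "
    f"{first.n_members} inverse targets, e.g. {first.member_genes[:3]}"
)

ranked = m.rank_candidates(activity, labels, top_k=10)
print("top 10 candidates by activity t-test:", ranked)
implanted = sorted(truth.informative_mirnas)
print("implanted signal miRNAs:             ", implanted)
# The implanted miRNAs should dominate the top of the ranking: their
# activity rows aggregate genes that genuinely separate the classes.
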