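# midrw

Topology-aware inference of **miRNA-mediated subpathway activities** for
two-group (case/control) expression cohorts, with AUC-driven greedy feature
selection and nested cross-validation evaluation.

## The problem

Single-gene and single-miRNA expression biomarkers reproduce poorly across
cohorts and platforms.  A more stable signal lives at the level of
*subpathways*: a regulatory miRNA together with the pathway genes it
represses.  `midrw` scores each such subpathway per sample by combining

* how differential the miRNA and its target genes are,
* how topologically important those genes are in a global directed pathway
  network (GDPN), and
* the genes' standardised expression,

and then asks which subpathway activities classify case vs control best,
and how reproducibly.

## The method

1. **Filtering and differential statistics.** Features whose zero-fraction
   is ≥ 20% are removed; every gene and miRNA gets a pooled-variance
   two-tailed Student t-score (positive = higher in cases).
2. **GDPN.** Per-pathway directed gene graphs are merged; every gene–gene
   edge is reversed (a gene is important when it *influences* many genes —
   the mirror of PageRank); a virtual node is bidirectionally linked to
   every gene so the row-normalised transition matrix *M* is stochastic.
3. **Directed random walk with restart.** With seed p₀ ∝ |t| over GDPN
   genes (0 on the virtual node),

       p_{t+1} = (1 − r) Mᵀ p_t + r p₀,     r = 0.7,

   iterated to the stationary p_∞ (L1 tolerance 1e-10).  p_∞(g) is gene
   g's topology score.
4. **Subpathway activity.** For each differential miRNA miR_j with
   differential, GDPN-resident, *inversely* regulated targets g₁…g_nj
   (up-miRNA with down-genes or vice versa),

       a(miR_j) = Σᵢ p_∞(gᵢ) · sgn(t(miR_j)·t(gᵢ)) · z(gᵢ) / √(Σᵢ p_∞(gᵢ)²)

   where z is the per-gene standardised expression row and sgn is the
   inverted sign function (+1 for negative products, i.e. inverse pairs).
5. **Evaluation.** Candidate subpathways are ranked by activity t-test,
   truncated to the top 20, and selected greedily (keep a candidate only if
   the feature-selection-subset AUC strictly increases).  Within-dataset:
   10 × stratified 5-fold × 3 inner rotations = 150 classifiers;
   cross-dataset: 10 × 5 selection rotations = 50 classifiers scored on an
   independent cohort.  Reproducibility power
   C_score(N) = (1/N) Σ |t_train|/|t_valid| over rank-paired top-N
   activities quantifies feature stability; hypergeometric overlap tests
   and a random-deletion harness probe robustness.

Mean/median/first-principal-component pathway activities over the same
member genes are included as classical baselines, and a synthetic-data
module generates complete input bundles (pathways as neighbourhoods of a
scale-free interactome, matched gene/miRNA cohorts with implanted
inverse-regulated signal) so the whole pipeline runs without downloads.

## Worked example

```python
import midrw as m

config = m.SimulationConfig(seed=42)           # 50+50 samples, 5 implanted miRNAs
pathways, ge, me, lab, tg, truth = m.simulate_bundle(config)
gdpn = m.build_gdpn(pathways)
report = m.evaluate_within(m.DataBundle(ge, me, lab, tg), gdpn, reps=10, folds=5, seed=7)
print(f"mean AUC:       {report.mean_auc:.4f} +/- {report.sd_auc:.4f}")
print(f"mean accuracy:  {report.mean_accuracy:.4f}")
print(f"HF subpathways: {sorted(report.hf_set)}")
```

prints (see `examples/03_within_dataset_evaluation.py`):

```
mean AUC:       0.9982 +/- 0.0061
mean accuracy:  0.9840
HF subpathways: ['miR-0004', 'miR-0010', 'miR-0015', 'miR-0041']
```

The 150 held-out-fold classifiers average an AUC of 0.998 on this cohort —
the implanted 1.5-sd inverse-regulation signal is essentially always
recovered — and the high-frequency (HF) set, the subpathways selected more
often than the median count, contains four of the five implanted miRNAs
(`truth.informative_mirnas` lists them).  The `examples/` directory walks
through network construction, activity inference, cross-dataset
generalisation, reproducibility power and the deletion harness; the same
steps are scriptable via the `midrw` CLI (`simulate`, `build-gdpn`,
`activity`, `evaluate-within`, `evaluate-cross`, `cscore`).

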