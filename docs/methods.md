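# Methods

## Model overview

`midrw` treats a case/control expression study as four linked inputs: a
gene matrix, a matched miRNA matrix, binary phenotype labels, and two
pieces of prior knowledge — a set of directed pathway graphs over genes and
a miRNA→gene target map.  Its output is a matrix of *miRNA-mediated
subpathway activities* (one row per qualifying miRNA, one column per
sample) and, on top of it, classification and reproducibility analyses.

The chain is: zero-fraction filtering → per-feature differential t-scores →
global directed pathway network (GDPN) → restart random walk → subpathway
definition → activity aggregation → greedy AUC feature selection inside
nested cross-validation.

## Differential statistics

The two-sample statistic is the classical pooled-variance Student t
(two-tailed), sign convention *case minus control*.  The sign convention is
arbitrary but must be uniform, because subpathway membership depends only
on the *relative* signs of miRNA and gene t-scores; computing every t-score
in one module enforces that.  Features with zero pooled variance are
degenerate: equal means give t = 0, p = 1; unequal means are flagged and
excluded from the differential set rather than given an unbounded
statistic.  The differential call is p < α with a single α (default 0.05)
applied to genes and miRNAs alike; no multiple-testing correction is
applied, matching the method's design as a feature-construction step rather
than an inference endpoint.

## GDPN construction

Pathway graphs are merged as unweighted directed edge unions (duplicate
edges collapse, keeping per-pathway provenance; self-loops are dropped
because the walk is defined on loop-free transitions).  All gene–gene edges
are then **reversed**: in PageRank a page is important when many pages
point to it, whereas a gene is important when it influences many genes, so
influence must flow against the regulatory arrows.  A reserved virtual node
(`__VIRTUAL__`, banned as a gene ID at read time) is linked to and from
every gene; this closes the network so every row of the transition matrix
has at least one out-edge and the walk cannot leak mass.  Virtual links are
symmetric, so closing before or after reversal is equivalent; we close
after.  Rows of the adjacency matrix are divided by their sums, giving a
uniform step over out-neighbours.

Degree QC fits ordinary least squares to log₁₀(degree) vs log₁₀(frequency)
over gene–gene edges only (the virtual closure is an algorithmic device,
not biology), excluding empty histogram bins; fewer than three distinct
positive degrees returns NaN.  On generated networks the R² values fall in
roughly 0.8–0.9 for in/out/total degree — the same scale-free regime
reported for curated pathway collections.

## Restart walk

p_{t+1} = (1 − r)·Mᵀ·p_t + r·p₀ with restart probability r = 0.7 and seed
p₀ ∝ |t| over GDPN genes present in the differential table (0 for the
virtual node and absent genes), L1-normalised: the walk is a probability
propagation, and only L1 normalisation makes mass conservation hold
exactly.  Convergence is declared at L1 step difference ≤ 1e-10; the map is
an L1 contraction with factor (1 − r), so ~20 iterations suffice at the
default r and max_iter = 10 000 is effectively unreachable (hitting it
flags the result unconverged rather than raising).  By default the seed
uses *all* genes in the differential table regardless of their p-value
(`differential_only` restricts to significant genes); seeding with all
t-scores keeps weakly-informative topology in play and the choice is
exposed as a flag.

## Subpathway definition and activity

A subpathway exists for each differential miRNA with at least one target
gene that is (i) differential, (ii) a GDPN node and (iii) of opposite
t-score sign ("inverse regulation": miRNAs repress their targets, so only
up-miRNA/down-gene and down-miRNA/up-gene pairs are biologically coherent;
same-sign pairs are never integrated).  Inverse correlation is operation-
alised through t-score signs, not through an explicit expression
correlation test.

Activity:  a(miR_j) = Σᵢ p_∞(gᵢ)·sgn(t(miR_j)·t(gᵢ))·z(gᵢ) / √(Σᵢ p_∞(gᵢ)²),
with sgn the inverted sign function (+1 for negative products).  Under the
inverse membership rule every sgn term is +1, and a regression test pins
that equivalence.  The denominator makes activities invariant to uniform
rescaling of topology scores.  z-scores use the **population** standard
deviation (÷ n); any consistent convention merely rescales each gene
uniformly, so this is fixed and documented rather than configurable.
Constant genes are flagged and standardised to zero.  All moments (and
p_∞, and the subpathway definitions themselves) are fit on training
samples only; held-out samples are transformed with frozen parameters.

Baselines over the same member genes: per-sample mean, median, and the
first principal component (fit on training samples; its sign is fixed to
correlate positively with the member-mean profile, since PCA sign is
arbitrary but AUC-relevant; a single-gene set degenerates to that gene's
row).

## Evaluation protocols

Candidates are subpathways ranked by activity t-test p ascending (ties:
|t| descending, then ID), truncated to the top 20.  Greedy forward
selection walks the candidate order: the first candidate is always kept;
a later candidate is kept only if the feature-selection-subset AUC
*strictly* increases.  AUC is the Mann–Whitney estimator (ties 1/2),
identical to trapezoidal ROC integration.  The classifier contract is any
object with `fit`/`predict_proba`; the default is L2-penalised logistic
regression (C = 1), and the protocols are classifier-agnostic.

*Within-dataset*: per repetition, a stratified 5-fold split; per fold the
training partition is refit end-to-end and split into 3 equal stratified
subsets; each rotates once as the Feature Selection subset (candidates are
ranked on the complementary Feature Retrieve subset, where the classifiers
are also fit).  10 × 5 × 3 = 150 classifier records, each scored on the
untouched test fold.  Splits are stratified by class — plain random splits
on small cohorts produce one-class subsets — with `stratify=False`
restoring plain randomness.  If a training partition yields *no* definable
subpathway (routine under label permutation), the protocol records
chance-level classifiers (constant scores, AUC exactly 0.5) for that fold
instead of aborting: the honest answer when no biomarker exists.

*Cross-dataset*: feature spaces are intersected between cohorts first; all
statistics come from the training cohort; its samples are split into 5
stratified subsets with each in turn the Feature Selection subset, repeated
10 times → 50 records scored on the independent cohort.

Selection frequencies are pooled over all runs; the high-frequency (HF)
set is counts strictly greater than the median count (middle-order
statistic, mean of the two middles for even n).

## Reproducibility power

C_score(N) = (1/N) Σᵢ |t_train(i)| / |t_valid(i)| over activity t-scores,
both sides sorted by |t| and paired by rank.  The default sorts
descending — the reproducibility of the *most discriminative* top-N
features is the quantity of interest — with `descending=False` for the
literal smallest-first ordering.  Zero validation |t| pairs are skipped
with a warning.  The within-dataset schedule is 5 folds × 100 repetitions
= 500 train/validation experiments (reducible for testing); each refits
the activity model on the training side only.  Note that with a 4:1
train:validation split, C_score concentrates near √(n_train/n_valid) ≈ 2
rather than 1, because |t| scales with √n at a fixed effect size.

## Overlap significance and deletion harness

Overlap between two feature sets is tested with the upper-tail
hypergeometric probability P(X ≥ observed), taking the universe size as an
explicit argument — the appropriate universe (shared differential miRNAs,
all shared miRNAs, or the full target map) is study-specific and the
function makes no choice for the caller.  The deletion harness removes a
given fraction of target pairs (or of GDPN-resident target genes plus
miRNAs) uniformly at random and re-runs the within-dataset protocol; the
evaluation seed is held fixed across fractions, so fraction 0 reproduces
the baseline bit-for-bit and the curve isolates the effect of deletion.
A deletion that empties the subpathway set flags the row instead of
failing.

## Synthetic data

The generator emulates the *structure* of the real inputs at desk scale.
A single preferential-attachment interactome (500 genes, m = 3) is grown
and each pathway is the induced subgraph of a snowball-sampled connected
neighbourhood (50 pathways × 30 genes by default), so pathways overlap,
share hubs, and their merged union keeps a heavy-tailed degree
distribution — merging *independent* per-pathway graphs instead washes the
tail out, which is why pathways are views of one interactome.  Edge
orientations are fixed once globally.

Cohorts: 50 cases + 50 controls; background expression N(0, 1); 5
informative miRNAs shifted ±1.5 sd in cases with each of their 8 (disjoint)
targets shifted oppositely; 15 additional weak carriers at 0.5 sd keep the
pool of differential miRNAs above twenty, mirroring the dataset-inclusion
filter used for real cohorts (with only 5 strong implants, candidate
ranking would be vacuous).  A background zero rate of 2% plus an 8% subset
of zero-heavy features (50% zeros) gives the zero-fraction filter realistic
work; signal carriers are exempt so the implanted effect is exactly the
nominal one.  Two RNG streams — *design* (`signal_seed`: carriers, targets,
signs) and *noise* (`seed`: values, zeroing) — let cross-dataset
experiments pair cohorts that share a signal but not noise.

What the synthetic cohorts do **not** emulate: count-distributed RNA-seq
noise (values are Gaussian, optionally exponentiated via `log_normal`),
batch effects, correlated co-expression beyond the implanted shifts,
subtype heterogeneity, and realistic target-map density (hundreds of
targets per miRNA).  Passing tests therefore demonstrate correctness of
the machinery and recoverability of a clean inverse-regulation signal, not
performance on real tumour cohorts.

## Numerical choices and problem sizes

Tolerances: walk convergence 1e-10 (L1); transition row sums asserted to
1e-12; activity vectorisation agrees with a scalar-loop oracle to 1e-12;
walk vs dense linear solve to 1e-8.  Ties in candidate ranking break by
|t| then ID so runs are exactly reproducible; all protocols are pure
functions of (inputs, seed), with sub-seeds drawn from one
`numpy.random.default_rng` stream.  The test suite and the acceptance
script run the full 150/50/500-experiment schedules on the default
synthetic cohort (100 samples, ~440-gene network), which completes in
tens of seconds; the same code paths scale to cohort sizes typical of
public tumour datasets, where the walk's sparse power iteration (~20
iterations) remains the cheap step.

## Known limitations

* Inverse regulation is judged by t-sign opposition, not expression
  correlation; miRNAs whose repression is real but sub-threshold in either
  matrix are invisible.
* The hypergeometric overlap test leaves the universe choice to the
  caller; no default can reproduce any particular published p-value.
* The within-dataset chance-classifier fallback (no definable subpathway)
  records AUC 0.5 rather than abstaining, which slightly biases permuted-
  null means toward 0.5 — intended behaviour for calibration, but worth
  knowing when comparing against protocols that drop such folds.
* C_score compares |t| spectra, not feature identity: two splits can agree
  in C_score while ranking different miRNAs.
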