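"""Feature ranking, greedy AUC selection, evaluation protocols and the
reproducibility-power statistic.

Two protocols are implemented:

* **within-dataset** — 10 repetitions of stratified 5-fold cross-validation.
  Inside each training partition a further stratified 3-way split rotates a
  *Feature Selection* subset against a 2/3 *Feature Retrieve* subset, giving
  10 × 5 × 3 = 150 optimised classifiers whose held-out-fold AUC/accuracy
  are averaged.
* **cross-dataset** — one cohort trains, an independent cohort tests.  The
  training cohort is split into 5 stratified subsets; each in turn is the
  Feature Selection subset (the rest retrieve), repeated 10 times for
  10 × 5 = 50 classifiers evaluated on the independent cohort.

Every training-derived quantity (zero filters, t-scores, walk seed,
z-moments, subpathway definitions) is recomputed from the training
partition only, so held-out samples never leak into feature construction.

Reproducibility power compares the discriminative strength of the top-N
subpathway activities between a training and a validation split:

    C_score(N) = (1/N) Σ_i |t_train(i)| / |t_valid(i)|

with both lists rank-paired by |t|.  A method whose best features keep
their discriminative power out-of-sample scores near (or above) 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .activity import ActivityMatrix, NoSubpathwaysError, fit_activity_model
from .gdpn import GDPN, remove_genes
from .io import ExpressionMatrix, PhenotypeLabels, TargetMap, match_samples  # noqa: F401
from .preprocess import DifferentialTable, t_scores

logger = logging.getLogger(__name__)

#: Fixed ridge-penalised logistic regression; the protocols are
#: classifier-agnostic, so any object with fit/predict_proba plugs in.
def default_classifier():
    return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)


ClassifierFactory = Callable[[], object]


@dataclass
class DataBundle:
    """The four sample-matched inputs of one cohort."""

    gene_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    labels: PhenotypeLabels
    targets: TargetMap

    def matched(self) -> "DataBundle":
        g, m, lab = match_samples(self.gene_expr, self.mirna_expr, self.labels)
        return DataBundle(g, m, lab, self.targets)

    @property
    def sample_ids(self) -> list[str]:
        return self.gene_expr.sample_ids


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Mann–Whitney AUC of ``scores`` against binary labels (1 = case).

    Equals the probability that a random case outscores a random control,
    with ties counting 1/2; identical to the area under the empirical ROC
    curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required to compute an AUC")
    ranks = stats.rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def accuracy(scores: Sequence[float], y: Sequence[int], threshold: float = 0.5) -> float:
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    return float((pred == np.asarray(y, dtype=int)).mean())


def rank_candidates(
    activity: ActivityMatrix,
    labels: PhenotypeLabels,
    sample_ids: list[str] | None = None,
    top_k: int = 20,
) -> list[str]:
    """Rank subpathways by two-tailed t-test p ascending; truncate to top_k.

    Ties are broken by |t| descending, then ID lexicographically.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    samples = activity.sample_ids if sample_ids is None else list(sample_ids)
    values = activity.values[samples]
    diff = t_scores(ExpressionMatrix(values, "mirna"), labels.subset(samples))
    table = diff.table.copy()
    table["abs_t"] = table["t"].abs().fillna(0.0)
    table["p"] = table["p"].fillna(1.0)
    ranked = list(
        table.assign(_id=table.index)
        .sort_values(by=["p", "abs_t", "_id"], ascending=[True, False, True], kind="mergesort")
        .index
    )
    if len(ranked) < top_k:
        logger.warning("only %d candidates available (top_k=%d)", len(ranked), top_k)
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# Greedy forward selection
# ---------------------------------------------------------------------------


@dataclass
class GreedyResult:
    candidate_order: list[str]
    selected: list[str]
    selection_auc: list[float]  # selection-set AUC at each accepted step
    final_auc_on_test: float = float("nan")


def _fit_score(
    make_classifier: ClassifierFactory,
    X_fit: np.ndarray,
    y_fit: np.ndarray,
    X_eval: np.ndarray,
) -> np.ndarray:
    clf = make_classifier()
    clf.fit(X_fit, y_fit)
    return clf.predict_proba(X_eval)[:, 1]


def greedy_select(
    candidates: list[str],
    act_retrieve: ActivityMatrix,
    y_retrieve: np.ndarray,
    act_select: ActivityMatrix,
    y_select: np.ndarray,
    make_classifier: ClassifierFactory = default_classifier,
) -> GreedyResult:
    """Forward pass in candidate order, keeping a candidate only if the
    Feature-Selection-subset AUC strictly increases.

    The first candidate is always kept (it defines the incumbent).  A
    classifier that fails to fit on some step skips that candidate with a
    warning.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    selected: list[str] = []
    sel_auc: list[float] = []
    best = -np.inf
    for cand in candidates:
        trial = selected + [cand]
        try:
            scores = _fit_score(
                make_classifier,
                act_retrieve.as_features(trial),
                y_retrieve,
                act_select.as_features(trial),
            )
        except Exception as exc:  # fit failure: skip candidate
            logger.warning("classifier failed on candidate %s: %s", cand, exc)
            continue
        a = auc(scores, y_select)
        if not selected or a > best:
            selected = trial
            best = a
            sel_auc.append(a)
    return GreedyResult(list(candidates), selected, sel_auc)


# ---------------------------------------------------------------------------
# Protocol reports
# ---------------------------------------------------------------------------


@dataclass
class ClassifierRecord:
    rep: int
    fold: int
    rotation: int
    auc: float
    accuracy: float
    selected: tuple[str, ...]


@dataclass
class EvaluationReport:
    records: list[ClassifierRecord]
    frequency: dict[str, int]  # selection counts over candidates ever ranked

    @property
    def mean_auc(self) -> float:
        return float(np.mean([r.auc for r in self.records]))

    @property
    def sd_auc(self) -> float:
        return float(np.std([r.auc for r in self.records], ddof=1))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.records]))

    @property
    def hf_set(self) -> set[str]:
        return hf_subpathways(self.frequency)

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_accuracy": self.mean_accuracy,
            "n_classifiers": len(self.records),
            "hf_subpathways": sorted(self.hf_set),
            "frequency": dict(sorted(self.frequency.items())),
            "records": [
                {
                    "rep": r.rep,
                    "fold": r.fold,
                    "rotation": r.rotation,
                    "auc": r.auc,
                    "accuracy": r.accuracy,
                    "selected": list(r.selected),
                }
                for r in self.records
            ],
        }

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.rep, r.fold, r.rotation, r.auc, r.accuracy, ";".join(r.selected))
                for r in self.records
            ],
            columns=["rep", "fold", "rotation", "auc", "accuracy", "selected"],
        )


def hf_subpathways(frequency: dict[str, int]) -> set[str]:
    """High-frequency calling: counts strictly greater than the median count."""
    if not frequency:
        raise ValueError("empty frequency table")
    med = float(np.median(list(frequency.values())))
    return {k for k, v in frequency.items() if v > med}


def _stratified_partition(
    samples: list[str],
    y: np.ndarray,
    n_parts: int,
    rng: np.random.Generator,
    stratify: bool = True,
    max_attempts: int = 100,
) -> list[list[str]]:
    """Split samples into ``n_parts`` near-equal subsets, each with both
    classes; re-draw (new derived seed) up to ``max_attempts`` times."""
    samples = list(samples)
    for _ in range(max_attempts):
        seed = int(rng.integers(2**31))
        if stratify:
            skf = StratifiedKFold(n_splits=n_parts, shuffle=True, random_state=seed)
            parts = [
                [samples[i] for i in test_idx]
                for _, test_idx in skf.split(np.zeros(len(samples)), y)
            ]
        else:
            order = np.random.default_rng(seed).permutation(len(samples))
            parts = [
                [samples[i] for i in order[j::n_parts]] for j in range(n_parts)
            ]
        ok = all(
            0 < sum(y[samples.index(s)] for s in part) < len(part) for part in parts
        )
        if ok:
            return parts
    raise ValueError(
        f"could not produce {n_parts} subsets containing both classes "
        f"after {max_attempts} attempts"
    )


def evaluate_within(
    bundle: DataBundle,
    gdpn: GDPN,
    reps: int = 10,
    folds: int = 5,
    inner_subsets: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    restart_prob: float = 0.7,
    top_k: int = 20,
    zero_threshold: float = 0.2,
    stratify: bool = True,
    make_classifier: ClassifierFactory = default_classifier,
) -> EvaluationReport:
    """Within-dataset protocol: reps × folds × inner_subsets classifiers.

    Per repetition the cohort is split into stratified ``folds`` folds; per
    fold the training partition is refit end-to-end (filters, t-scores,
    walk, z-moments, subpathway definitions) and split into
    ``inner_subsets`` equal stratified subsets, each rotating once as the
    Feature Selection subset.  Each optimised classifier is evaluated on
    the untouched test fold.
    """
    bundle = bundle.matched()
    samples = bundle.sample_ids
    y_all = bundle.labels.binary(samples)
    rng = np.random.default_rng(seed)

    records: list[ClassifierRecord] = []
    frequency: dict[str, int] = {}

    for rep in range(reps):
        fold_parts = _stratified_partition(samples, y_all, folds, rng, stratify)
        for fold, test_samples in enumerate(fold_parts):
            train_samples = [s for s in samples if s not in set(test_samples)]
            try:
                model = fit_activity_model(
                    bundle.gene_expr,
                    bundle.mirna_expr,
                    bundle.labels,
                    bundle.targets,
                    gdpn,
                    fit_samples=train_samples,
                    alpha=alpha,
                    restart_prob=restart_prob,
                    zero_threshold=zero_threshold,
                )
            except NoSubpathwaysError:
                # no biomarker definable on this training partition: the
                # honest classifier is an uninformative one (chance AUC)
                logger.warning(
                    "rep %d fold %d: no subpathway definable; recording "
                    "chance-level classifiers",
                    rep,
                    fold,
                )
                y_test = bundle.labels.binary(test_samples)
                flat = np.full(len(test_samples), 0.5)
                for rotation in range(inner_subsets):
                    records.append(
                        ClassifierRecord(
                            rep,
                            fold,
                            rotation,
                            auc(flat, y_test),
                            accuracy(flat, y_test),
                            tuple(),
                        )
                    )
                continue
            act_train = model.transform(bundle.gene_expr, train_samples)
            act_test = model.transform(bundle.gene_expr, test_samples)
            y_train = bundle.labels.binary(train_samples)
            y_test = bundle.labels.binary(test_samples)

            inner = _stratified_partition(
                train_samples, y_train, inner_subsets, rng, stratify
            )
            for rotation in range(inner_subsets):
                select_samples = inner[rotation]
                retrieve_samples = [
                    s for s in train_samples if s not in set(select_samples)
                ]
                candidates = rank_candidates(
                    act_train, bundle.labels, retrieve_samples, top_k
                )
                for c in candidates:
                    frequency.setdefault(c, 0)
                act_ret = _subset_activity(act_train, retrieve_samples)
                act_sel = _subset_activity(act_train, select_samples)
                result = greedy_select(
                    candidates,
                    act_ret,
                    bundle.labels.binary(retrieve_samples),
                    act_sel,
                    bundle.labels.binary(select_samples),
                    make_classifier,
                )
                scores = _fit_score(
                    make_classifier,
                    act_ret.as_features(result.selected),
                    bundle.labels.binary(retrieve_samples),
                    act_test.as_features(result.selected),
                )
                result.final_auc_on_test = auc(scores, y_test)
                records.append(
                    ClassifierRecord(
                        rep,
                        fold,
                        rotation,
                        result.final_auc_on_test,
                        accuracy(scores, y_test),
                        tuple(result.selected),
                    )
                )
                for s in result.selected:
                    frequency[s] = frequency.get(s, 0) + 1
    return EvaluationReport(records, frequency)


def _subset_activity(act: ActivityMatrix, samples: list[str]) -> ActivityMatrix:
    return ActivityMatrix(act.values[list(samples)], act.z_params, act.members)


def _intersect_bundles(
    train: DataBundle, test: DataBundle
) -> tuple[DataBundle, DataBundle]:
    """Restrict both cohorts to their shared gene and miRNA feature spaces."""
    genes = [g for g in train.gene_expr.feature_ids if g in set(test.gene_expr.feature_ids)]
    mirnas = [m for m in train.mirna_expr.feature_ids if m in set(test.mirna_expr.feature_ids)]
    if not genes or not mirnas:
        raise ValueError("train and test cohorts share no gene or miRNA features")

    def cut(b: DataBundle) -> DataBundle:
        return DataBundle(
            b.gene_expr.subset_features(genes),
            b.mirna_expr.subset_features(mirnas),
            b.labels,
            b.targets,
        )

    return cut(train), cut(test)


def evaluate_cross(
    train: DataBundle,
    test: DataBundle,
    gdpn: GDPN,
    reps: int = 10,
    selection_subsets: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
    restart_prob: float = 0.7,
    top_k: int = 20,
    zero_threshold: float = 0.2,
    stratify: bool = True,
    make_classifier: ClassifierFactory = default_classifier,
) -> EvaluationReport:
    """Cross-dataset protocol: reps × selection_subsets classifiers.

    The training cohort supplies every statistic (differential sets, target
    filtering, walk, z-moments); the independent test cohort is only ever
    scored.  Feature spaces are intersected between cohorts first.
    """
    train = train.matched()
    test = test.matched()
    train, test = _intersect_bundles(train, test)
    rng = np.random.default_rng(seed)

    model = fit_activity_model(
        train.gene_expr,
        train.mirna_expr,
        train.labels,
        train.targets,
        gdpn,
        alpha=alpha,
        restart_prob=restart_prob,
        zero_threshold=zero_threshold,
    )
    train_samples = train.sample_ids
    act_train = model.transform(train.gene_expr, train_samples)
    # test-cohort genes may miss some training genes after filtering: the
    # shared-feature intersection above guarantees presence.
    act_test = model.transform(test.gene_expr, test.sample_ids)
    y_train = train.labels.binary(train_samples)
    y_test = test.labels.binary(test.sample_ids)

    records: list[ClassifierRecord] = []
    frequency: dict[str, int] = {}
    for rep in range(reps):
        parts = _stratified_partition(
            train_samples, y_train, selection_subsets, rng, stratify
        )
        for rotation in range(selection_subsets):
            select_samples = parts[rotation]
            retrieve_samples = [
                s for s in train_samples if s not in set(select_samples)
            ]
            candidates = rank_candidates(
                act_train, train.labels, retrieve_samples, top_k
            )
            for c in candidates:
                frequency.setdefault(c, 0)
            act_ret = _subset_activity(act_train, retrieve_samples)
            act_sel = _subset_activity(act_train, select_samples)
            result = greedy_select(
                candidates,
                act_ret,
                train.labels.binary(retrieve_samples),
                act_sel,
                train.labels.binary(select_samples),
                make_classifier,
            )
            scores = _fit_score(
                make_classifier,
                act_ret.as_features(result.selected),
                train.labels.binary(retrieve_samples),
                act_test.as_features(result.selected),
            )
            result.final_auc_on_test = auc(scores, y_test)
            records.append(
                ClassifierRecord(
                    rep,
                    0,
                    rotation,
                    result.final_auc_on_test,
                    accuracy(scores, y_test),
                    tuple(result.selected),
                )
            )
            for s in result.selected:
                frequency[s] = frequency.get(s, 0) + 1
    return EvaluationReport(records, frequency)


# ---------------------------------------------------------------------------
# Reproducibility power
# ---------------------------------------------------------------------------


@dataclass
class ReproducibilityReport:
    n_values: list[int]
    c_scores: dict[int, float]  # mean C_score per N
    n_experiments: int
    reps: int
    folds: int


def c_score(
    train_diff: DifferentialTable,
    valid_diff: DifferentialTable,
    n_top: int,
    descending: bool = True,
) -> float:
    """Mean rank-paired |t| ratio of the top-N subpathway activities.

    Both tables are sorted independently by |t| (most discriminative first
    by default; ``descending=False`` gives the literal smallest-first
    ordering) and paired by rank.  Zero validation |t| values are skipped
    with a warning and N adjusted.
    """
    t_train = np.sort(np.abs(train_diff.table["t"].dropna().to_numpy()))
    t_valid = np.sort(np.abs(valid_diff.table["t"].dropna().to_numpy()))
    if descending:
        t_train, t_valid = t_train[::-1], t_valid[::-1]
    if len(t_train) < n_top or len(t_valid) < n_top:
        raise ValueError(
            f"both tables must cover at least N={n_top} subpathways "
            f"(have {len(t_train)} and {len(t_valid)})"
        )
    t_train = t_train[:n_top]
    t_valid = t_valid[:n_top]
    keep = t_valid != 0
    if not keep.all():
        logger.warning(
            "skipping %d rank pair(s) with zero validation |t|", int((~keep).sum())
        )
    if not keep.any():
        raise ValueError("every validation |t| in the top N is zero")
    return float(np.mean(t_train[keep] / t_valid[keep]))


def reproducibility_within(
    bundle: DataBundle,
    gdpn: GDPN,
    reps: int = 100,
    folds: int = 5,
    n_values: Sequence[int] = (10, 20, 30, 40),
    seed: int = 0,
    alpha: float = 0.05,
    restart_prob: float = 0.7,
    zero_threshold: float = 0.2,
    stratify: bool = True,
    descending: bool = True,
) -> ReproducibilityReport:
    """Mean C_score per N over reps × folds train/validation splits.

    Each experiment holds one fold out as validation, refits the activity
    model on the remainder, and compares the |t| spectra of the activity
    rows between the two sample sets.  N values exceeding the number of
    subpathways in some experiment are skipped for that experiment.
    """
    bundle = bundle.matched()
    samples = bundle.sample_ids
    y_all = bundle.labels.binary(samples)
    rng = np.random.default_rng(seed)

    sums = {n: 0.0 for n in n_values}
    counts = {n: 0 for n in n_values}
    n_experiments = 0
    for _rep in range(reps):
        parts = _stratified_partition(samples, y_all, folds, rng, stratify)
        for valid_samples in parts:
            train_samples = [s for s in samples if s not in set(valid_samples)]
            model = fit_activity_model(
                bundle.gene_expr,
                bundle.mirna_expr,
                bundle.labels,
                bundle.targets,
                gdpn,
                fit_samples=train_samples,
                alpha=alpha,
                restart_prob=restart_prob,
                zero_threshold=zero_threshold,
            )
            act_train = model.transform(bundle.gene_expr, train_samples)
            act_valid = model.transform(bundle.gene_expr, valid_samples)
            diff_train = t_scores(
                ExpressionMatrix(act_train.values, "mirna"),
                bundle.labels.subset(train_samples),
            )
            diff_valid = t_scores(
                ExpressionMatrix(act_valid.values, "mirna"),
                bundle.labels.subset(valid_samples),
            )
            n_experiments += 1
            for n in n_values:
                try:
                    sums[n] += c_score(diff_train, diff_valid, n, descending)
                    counts[n] += 1
                except ValueError:
                    continue
    c_scores = {
        n: (sums[n] / counts[n] if counts[n] else float("nan")) for n in n_values
    }
    return ReproducibilityReport(
        list(n_values), c_scores, n_experiments, reps, folds
    )


# ---------------------------------------------------------------------------
# Overlap significance and robustness-by-deletion
# ---------------------------------------------------------------------------


def overlap_significance(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> float:
    """Upper-tail hypergeometric P(X ≥ observed overlap).

    Tests whether two feature sets drawn from a universe of
    ``universe_size`` items overlap more than chance.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(a & b)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def deletion_robustness(
    bundle: DataBundle,
    gdpn: GDPN,
    kind: str,
    fractions: Sequence[float],
    seed: int = 0,
    eval_seed: int = 0,
    **eval_kwargs,
) -> pd.DataFrame:
    """Mean AUC/accuracy after random deletion of targets or network genes.

    ``kind='targets'`` deletes the given fraction of miRNA→gene pairs;
    ``kind='network'`` deletes that fraction of GDPN-resident target genes
    (removed from the network) and of miRNAs (removed from the miRNA
    matrix).  The evaluation itself always runs with ``eval_seed``, so a
    fraction of 0 reproduces the undeleted baseline bit-for-bit.  A deletion
    that empties the subpathway set flags that row instead of failing.
    """
    if kind not in ("targets", "network"):
        raise ValueError("kind must be 'targets' or 'network'")
    if any(not 0 <= f < 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    rows = []
    for i, frac in enumerate(fractions):
        rng = np.random.default_rng([seed, i])
        b, g = _apply_deletion(bundle, gdpn, kind, float(frac), rng)
        try:
            report = evaluate_within(b, g, seed=eval_seed, **eval_kwargs)
            rows.append((frac, report.mean_auc, report.mean_accuracy, False))
        except ValueError as exc:
            logger.warning("fraction %.2f: %s", frac, exc)
            rows.append((frac, float("nan"), float("nan"), True))
    return pd.DataFrame(rows, columns=["fraction", "mean_auc", "mean_accuracy", "flagged"])


def _apply_deletion(
    bundle: DataBundle,
    gdpn: GDPN,
    kind: str,
    frac: float,
    rng: np.random.Generator,
) -> tuple[DataBundle, GDPN]:
    if frac == 0:
        return bundle, gdpn
    if kind == "targets":
        pairs = sorted(bundle.targets.pairs)
        n_del = int(round(frac * len(pairs)))
        drop = set(
            map(tuple, [pairs[i] for i in rng.choice(len(pairs), n_del, replace=False)])
        )
        new_targets = TargetMap(frozenset(p for p in pairs if p not in drop))
        return (
            DataBundle(bundle.gene_expr, bundle.mirna_expr, bundle.labels, new_targets),
            gdpn,
        )
    # network: drop target genes from the GDPN and miRNAs from the matrix
    target_genes = sorted({g for _, g in bundle.targets.pairs if g in gdpn})
    n_del_g = int(round(frac * len(target_genes)))
    drop_genes = set(
        target_genes[i] for i in rng.choice(len(target_genes), n_del_g, replace=False)
    )
    mirnas = sorted(bundle.mirna_expr.feature_ids)
    n_del_m = int(round(frac * len(mirnas)))
    drop_mirnas = set(
        mirnas[i] for i in rng.choice(len(mirnas), n_del_m, replace=False)
    )
    keep_mirnas = [m for m in bundle.mirna_expr.feature_ids if m not in drop_mirnas]
    new_bundle = DataBundle(
        bundle.gene_expr,
        bundle.mirna_expr.subset_features(keep_mirnas),
        bundle.labels,
        bundle.targets,
    )
    return new_bundle, remove_genes(gdpn, drop_genes)
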