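"""miRNA-mediated subpathway activity inference.

A miRNA-mediated subpathway is a differentially expressed miRNA together
with its differentially expressed target genes that sit in the GDPN and are
regulated in the *opposite* direction (miRNAs repress their targets, so only
inverse pairs are biologically meaningful here: up-miRNA with down-genes and
vice versa).

The activity of subpathway miR_j over the n_j member genes g_1..g_nj is

    a(miR_j) = Σ_i p_∞(g_i) · sgn(t(miR_j)·t(g_i)) · z(g_i)
               / sqrt(Σ_i p_∞(g_i)²)

where p_∞ is the topology score from the restart walk, z(g_i) the
standardised expression row of gene g_i, and sgn the *inverted* sign
function (+1 for negative arguments, −1 for positive).  Under the
inverse-regulation membership rule the miRNA–gene t-score product is always
negative, so every sgn term contributes +1; the inverted sgn simply encodes
that an inversely regulated target counts positively toward the miRNA's
influence.  The denominator makes the activity invariant to uniform
rescaling of the topology scores.

Mean, median and first-principal-component aggregation over the same member
genes are provided as the classical pathway-activity baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gdpn import GDPN
from .io import ExpressionMatrix, PhenotypeLabels, TargetMap
from .preprocess import DifferentialTable, filter_zero_fraction, t_scores
from .walk import TopologyScores, random_walk, seed_vector

logger = logging.getLogger(__name__)


class NoSubpathwaysError(ValueError):
    """No miRNA-mediated subpathway is definable from the given inputs."""


@dataclass
class SubpathwayDefinition:
    """One differential miRNA with its qualifying (inverse) target genes."""

    mirna_id: str
    member_genes: list[str]
    mirna_t: float
    gene_ts: list[float]

    def __post_init__(self) -> None:
        if len(self.member_genes) < 1:
            raise ValueError("subpathway needs at least one member gene")
        if len(self.member_genes) != len(self.gene_ts):
            raise ValueError("member_genes and gene_ts length mismatch")
        for t in self.gene_ts:
            if np.sign(t) == np.sign(self.mirna_t):
                raise ValueError(
                    f"{self.mirna_id}: member gene with same-sign t-score"
                )

    @property
    def n_members(self) -> int:
        return len(self.member_genes)


@dataclass
class ActivityMatrix:
    """Subpathway × sample activity values plus the standardisation used."""

    values: pd.DataFrame  # subpathway IDs × sample IDs
    z_params: pd.DataFrame  # per-gene mean / sd / constant flag
    members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def subpathway_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def as_features(self, ids: list[str] | None = None) -> np.ndarray:
        """Samples × subpathways feature array for a classifier."""
        sub = self.values if ids is None else self.values.loc[ids]
        return sub.to_numpy().T


def define_subpathways(
    targets: TargetMap,
    gene_diff: DifferentialTable,
    mirna_diff: DifferentialTable,
    gdpn: GDPN,
) -> list[SubpathwayDefinition]:
    """One definition per differential miRNA with ≥1 qualifying target.

    A target gene qualifies when it is (i) differential, (ii) a GDPN node,
    and (iii) of opposite t-score sign to the miRNA.  miRNAs with no
    qualifying target are omitted; an empty result raises
    :class:`NoSubpathwaysError`.
    """
    gene_table = gene_diff.table
    diff_genes = set(gene_table.index[gene_table["is_differential"]])
    defs: list[SubpathwayDefinition] = []
    for mirna in sorted(mirna_diff.differential_ids()):
        t_mir = mirna_diff.t_of(mirna)
        if t_mir == 0 or not np.isfinite(t_mir):
            continue
        members, ts = [], []
        for g in sorted(targets.targets_of(mirna)):
            if g not in diff_genes or g not in gdpn:
                continue
            t_g = gene_diff.t_of(g)
            if t_g == 0 or np.sign(t_g) == np.sign(t_mir):
                continue
            members.append(g)
            ts.append(t_g)
        if members:
            defs.append(SubpathwayDefinition(mirna, members, t_mir, ts))
    if not defs:
        raise NoSubpathwaysError("no miRNA-mediated subpathways definable")
    return defs


def z_normalize(
    matrix: ExpressionMatrix, fit_samples: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene standardisation with moments from ``fit_samples`` only.

    Returns ``(z, params)`` where ``z`` covers *all* samples of ``matrix``
    transformed with the fit-sample mean and population (÷n) standard
    deviation, and ``params`` records those moments.  Constant genes are
    flagged and their z rows set to 0.
    """
    fit = matrix.data if fit_samples is None else matrix.data[list(fit_samples)]
    mean = fit.mean(axis=1)
    sd = fit.std(axis=1, ddof=0)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = matrix.data.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    params = pd.DataFrame({"mean": mean, "sd": sd, "constant": constant})
    return z, params


def _inverted_sgn(x: float) -> int:
    """+1 for negative numbers, −1 for positive, 0 for exact zero."""
    if x < 0:
        return 1
    if x > 0:
        return -1
    return 0


def subpathway_activity(
    defn: SubpathwayDefinition, topo: TopologyScores, z: pd.DataFrame
) -> pd.Series:
    """Activity row of one subpathway across the samples of ``z``.

    Members whose miRNA–gene t product is exactly zero are excluded (an
    exact-zero t never passes the differential filter, so this only matters
    for adversarial inputs).
    """
    weights, rows = [], []
    for g, t_g in zip(defn.member_genes, defn.gene_ts):
        s = _inverted_sgn(defn.mirna_t * t_g)
        if s == 0:
            continue
        weights.append(topo.score_of(g))
        rows.append(s * z.loc[g].to_numpy())
    w = np.asarray(weights)
    denom = np.sqrt((w**2).sum())
    if denom == 0:
        raise ValueError(
            f"{defn.mirna_id}: all member topology scores are zero"
        )
    numer = (w[:, None] * np.vstack(rows)).sum(axis=0)
    return pd.Series(numer / denom, index=z.columns, name=defn.mirna_id)


def activity_matrix(
    defs: list[SubpathwayDefinition],
    topo: TopologyScores,
    z: pd.DataFrame,
    z_params: pd.DataFrame,
) -> ActivityMatrix:
    rows = [subpathway_activity(d, topo, z) for d in defs]
    values = pd.DataFrame(rows)
    return ActivityMatrix(
        values=values,
        z_params=z_params,
        members={d.mirna_id: list(d.member_genes) for d in defs},
    )


def baseline_activity(
    method: str,
    gene_set: list[str],
    z: pd.DataFrame,
    fit_samples: list[str] | None = None,
) -> pd.Series:
    """Classical pathway-activity aggregates over the same member genes.

    ``mean`` and ``median`` aggregate member z rows per sample; ``pca1``
    scores samples on the first principal component of the member submatrix,
    with the component fit on ``fit_samples`` and its sign fixed to correlate
    positively with the member-mean profile (PCA sign is arbitrary but
    AUC-relevant).
    """
    if not gene_set:
        raise ValueError("empty gene set")
    sub = z.loc[list(gene_set)]
    if method == "mean":
        return sub.mean(axis=0)
    if method == "median":
        return sub.median(axis=0)
    if method == "pca1":
        if len(gene_set) == 1:
            return sub.iloc[0]
        fit = sub if fit_samples is None else sub[list(fit_samples)]
        X = fit.to_numpy().T  # samples × genes
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        component = vt[0]
        scores_all = (sub.to_numpy().T - X.mean(axis=0)) @ component
        fit_scores = (X - X.mean(axis=0)) @ component
        fit_mean = fit.to_numpy().mean(axis=0)
        if np.corrcoef(fit_scores, fit_mean)[0, 1] < 0:
            scores_all = -scores_all
        return pd.Series(scores_all, index=sub.columns)
    raise ValueError(f"unknown baseline method {method!r}")


# ---------------------------------------------------------------------------
# End-to-end fitted model (training-data-only statistics)
# ---------------------------------------------------------------------------


@dataclass
class ActivityModel:
    """Everything derived from the training samples, frozen for transform.

    Fitting runs the full inference chain on the fit samples only: zero
    filtering, differential t-scores for genes and miRNAs, walk seed,
    restart walk, subpathway definitions and z-moments.  ``transform``
    then scores arbitrary samples with those frozen quantities, so held-out
    samples never influence any statistic.
    """

    gene_diff: DifferentialTable
    mirna_diff: DifferentialTable
    defs: list[SubpathwayDefinition]
    topo: TopologyScores
    z_params: pd.DataFrame
    gene_ids: list[str]

    def transform(self, gene_expr: ExpressionMatrix, sample_ids: list[str]) -> ActivityMatrix:
        sub = gene_expr.subset_features(self.gene_ids).subset_samples(sample_ids)
        mean = self.z_params["mean"]
        sd = self.z_params["sd"].mask(self.z_params["constant"], 1.0)
        z = sub.data.sub(mean, axis=0).div(sd, axis=0)
        z.loc[self.z_params.index[self.z_params["constant"]]] = 0.0
        return activity_matrix(self.defs, self.topo, z, self.z_params)


def fit_activity_model(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    labels: PhenotypeLabels,
    targets: TargetMap,
    gdpn: GDPN,
    fit_samples: list[str] | None = None,
    alpha: float = 0.05,
    restart_prob: float = 0.7,
    zero_threshold: float = 0.2,
    seed_differential_only: bool = False,
) -> ActivityModel:
    """Fit the whole inference chain on ``fit_samples``."""
    if fit_samples is None:
        fit_samples = gene_expr.sample_ids
    genes_fit = filter_zero_fraction(gene_expr.subset_samples(fit_samples), zero_threshold)
    mirnas_fit = filter_zero_fraction(mirna_expr.subset_samples(fit_samples), zero_threshold)
    lab_fit = labels.subset(fit_samples)

    gene_diff = t_scores(genes_fit, lab_fit, alpha)
    mirna_diff = t_scores(mirnas_fit, lab_fit, alpha)

    p0 = seed_vector(gene_diff, gdpn, differential_only=seed_differential_only)
    topo = random_walk(gdpn, p0, restart_prob=restart_prob)

    defs = define_subpathways(targets, gene_diff, mirna_diff, gdpn)
    _, z_params = z_normalize(genes_fit)
    return ActivityModel(
        gene_diff=gene_diff,
        mirna_diff=mirna_diff,
        defs=defs,
        topo=topo,
        z_params=z_params,
        gene_ids=list(genes_fit.feature_ids),
    )
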