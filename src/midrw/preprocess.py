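"""Expression filtering and two-sample differential statistics.

The differential statistic throughout is the classical pooled-variance
(Student) two-tailed t-test between case and control samples.  The sign
convention is fixed: positive t means higher mean expression in the case
class.  Any consistent convention would do — the downstream sign rule for
miRNA/gene integration depends only on *relative* signs — but it must be
applied uniformly, which this module enforces by being the single place
t-scores are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, PhenotypeLabels


@dataclass
class DifferentialTable:
    """Per-feature t-score, p-value and differential call.

    ``table`` columns:

    t
        Signed pooled-variance Student t (case minus control); NaN when the
        statistic is degenerate (zero pooled variance, unequal means).
    p
        Two-tailed p-value in [0, 1].
    is_differential
        ``p < alpha`` and not degenerate.
    degenerate
        Zero pooled variance with unequal means — the statistic is
        unbounded, the feature is excluded from the differential set.
    """

    table: pd.DataFrame
    alpha: float

    def __post_init__(self) -> None:
        required = {"t", "p", "is_differential", "degenerate"}
        if not required <= set(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def t_of(self, feature_id: str) -> float:
        return float(self.table.at[feature_id, "t"])

    def differential_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_differential"]])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def filter_zero_fraction(
    matrix: ExpressionMatrix, threshold: float = 0.2
) -> ExpressionMatrix:
    """Drop features whose fraction of exactly-zero values is ≥ ``threshold``.

    Low-expressed features dominated by zeros carry mostly measurement noise;
    removing them is the first reliability filter applied to both gene and
    miRNA matrices.  The sample set is unchanged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    zero_frac = (matrix.values == 0).mean(axis=1)
    keep = zero_frac < threshold
    if not keep.any():
        raise ValueError("zero-fraction filter removed every feature")
    return ExpressionMatrix(matrix.data.loc[keep], matrix.feature_kind)


def t_scores(
    matrix: ExpressionMatrix, labels: PhenotypeLabels, alpha: float = 0.05
) -> DifferentialTable:
    """Two-tailed pooled-variance Student t per feature, case vs control.

    Degenerate features (zero pooled variance): equal means give t = 0,
    p = 1; unequal means are flagged and excluded from the differential set.
    """
    y = labels.binary(matrix.sample_ids)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 < 2 or n0 < 2:
        raise ValueError("need at least 2 samples per class for a t-test")
    X = matrix.values
    case = X[:, y == 1]
    ctrl = X[:, y == 0]
    m1 = case.mean(axis=1)
    m0 = ctrl.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v0 = ctrl.var(axis=1, ddof=1)
    df = n1 + n0 - 2
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / denom
    zero_var = sp2 == 0
    equal_means = m1 == m0
    degenerate = zero_var & ~equal_means
    t = np.where(zero_var & equal_means, 0.0, t)
    t = np.where(degenerate, np.nan, t)
    p = np.where(np.isnan(t), np.nan, 2.0 * stats.t.sf(np.abs(np.nan_to_num(t)), df))
    p = np.where(zero_var & equal_means, 1.0, p)

    table = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "is_differential": ~degenerate & (np.nan_to_num(p, nan=1.0) < alpha),
            "degenerate": degenerate,
        },
        index=matrix.data.index,
    )
    return DifferentialTable(table, alpha)
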