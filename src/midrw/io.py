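"""Flat-file input/output and the core in-memory containers.

All external files are tab-separated UTF-8 text with a header row; lines
starting with ``#`` are comments and are skipped.  Every downstream module
consumes only the in-memory types defined here:

* :class:`ExpressionMatrix` — features (genes or miRNAs) × samples,
* :class:`PhenotypeLabels` — a binary case/control assignment,
* :class:`TargetMap` — miRNA → target-gene pairs,
* :class:`PathwayGraphSet` — per-pathway directed gene graphs.

Duplicate feature rows in an expression file are collapsed by averaging at
read time (and never again later), matching the convention used for
platform-level probe duplicates in public tumour expression matrices.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved identifier for the closure node of the global directed pathway
#: network.  It is banned as a feature or gene identifier in every reader.
VIRTUAL_NODE = "__VIRTUAL__"

CASE = "case"
CONTROL = "control"
_VALID_LABELS = {CASE, CONTROL}


class ParseError(ValueError):
    """Raised when an input file violates the expected TSV dialect."""


def _check_no_virtual(ids: Iterable[str], what: str) -> None:
    if VIRTUAL_NODE in set(ids):
        raise ParseError(
            f"identifier {VIRTUAL_NODE!r} is reserved for the network closure "
            f"node and may not appear as a {what}"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A named features × named samples real-valued matrix.

    Parameters
    ----------
    data
        DataFrame with feature IDs as index and sample IDs as columns.
    feature_kind
        Either ``"gene"`` or ``"mirna"``.
    """

    data: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in ("gene", "mirna"):
            raise ValueError(f"unknown feature_kind {self.feature_kind!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate feature ID {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        _check_no_virtual(self.data.index, "feature ID")
        self.data = self.data.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a view restricted to ``sample_ids`` in the given order."""
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.feature_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise KeyError(f"unknown feature IDs: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.feature_kind)


@dataclass
class PhenotypeLabels:
    """Binary phenotype assignment over named samples."""

    labels: pd.Series  # index: sample IDs, values: "case"/"control"

    def __post_init__(self) -> None:
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate sample IDs in labels")
        bad = set(self.labels.unique()) - _VALID_LABELS
        if bad:
            raise ValueError(f"unknown label token(s): {sorted(bad)}")
        present = set(self.labels.unique())
        if present != _VALID_LABELS:
            raise ValueError("both phenotypes required (case and control)")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def subset(self, sample_ids: Sequence[str]) -> "PhenotypeLabels":
        return PhenotypeLabels(self.labels.loc[list(sample_ids)])

    def binary(self, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        """0/1 vector (case = 1) in the order of ``sample_ids``."""
        lab = self.labels if sample_ids is None else self.labels.loc[list(sample_ids)]
        return (lab == CASE).to_numpy(dtype=int)

    def case_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CASE])

    def control_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == CONTROL])


@dataclass(frozen=True)
class TargetMap:
    """Set of (mirna_id, gene_id) regulation pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError("target pair with empty identifier")

    def __len__(self) -> int:
        return len(self.pairs)

    def mirnas(self) -> set[str]:
        return {m for m, _ in self.pairs}

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for m, g in self.pairs if m == mirna_id}

    def subset_mirnas(self, mirna_ids: Iterable[str]) -> "TargetMap":
        keep = set(mirna_ids)
        return TargetMap(frozenset(p for p in self.pairs if p[0] in keep))


@dataclass(frozen=True)
class Pathway:
    pathway_id: str
    edges: tuple[tuple[str, str], ...]
    pathway_class: str  # "metabolic" | "nonmetabolic"

    def __post_init__(self) -> None:
        if self.pathway_class not in ("metabolic", "nonmetabolic"):
            raise ValueError(f"unknown pathway class {self.pathway_class!r}")
        for u, v in self.edges:
            if not u or not v:
                raise ValueError(f"pathway {self.pathway_id}: empty gene ID in edge")

    def genes(self) -> set[str]:
        return {g for e in self.edges for g in e}


@dataclass
class PathwayGraphSet:
    """Collection of directed, already-converted pathway graphs."""

    pathways: list[Pathway]

    def __post_init__(self) -> None:
        ids = [p.pathway_id for p in self.pathways]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate pathway IDs")
        for p in self.pathways:
            _check_no_virtual(p.genes(), "gene ID")

    def __len__(self) -> int:
        return len(self.pathways)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pathways:
            out |= p.genes()
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)


def read_expression(path: str | Path, feature_kind: str) -> ExpressionMatrix:
    """Read a features × samples expression TSV.

    The header row holds sample IDs; the first column holds feature IDs.
    Duplicate feature rows are collapsed by their mean.  A non-numeric cell
    raises :class:`ParseError` naming the offending row and column.
    """
    # pandas mangles duplicate header names, so check the raw header first
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            header = line.rstrip("\n").split("\t")
            break
        else:
            raise ParseError(f"{path}: empty file")
    sample_ids = header[1:]
    if len(sample_ids) != len(set(sample_ids)):
        dups = pd.Index(sample_ids)
        dup = dups[dups.duplicated()][0]
        raise ParseError(f"{path}: duplicate sample ID {dup!r}")
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected feature column plus >=1 sample column")
    feature_col = raw.columns[0]
    sample_ids = list(raw.columns[1:])
    features = raw[feature_col].astype(str)
    numeric = raw[sample_ids].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy().nonzero()
    if bad[0].size:
        i, j = int(bad[0][0]), int(bad[1][0])
        raise ParseError(
            f"{path}: non-numeric value {raw[sample_ids].iat[i, j]!r} for "
            f"feature {features.iat[i]!r}, sample {sample_ids[j]!r}"
        )
    numeric.index = features
    if numeric.index.duplicated().any():
        n_dup = int(numeric.index.duplicated().sum())
        logger.info("%s: averaging %d duplicated feature row(s)", path, n_dup)
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric, feature_kind)


def read_labels(path: str | Path) -> PhenotypeLabels:
    """Read a two-column ``sample<TAB>label`` TSV (labels: case/control)."""
    raw = _read_tsv(path)
    if raw.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly 2 columns (sample, label)")
    samples = raw.iloc[:, 0].astype(str)
    labels = raw.iloc[:, 1].astype(str)
    bad = sorted(set(labels) - _VALID_LABELS)
    if bad:
        raise ParseError(f"{path}: unknown label token(s) {bad}")
    series = pd.Series(labels.to_numpy(), index=pd.Index(samples, name="sample"))
    return PhenotypeLabels(series)


def read_targets(path: str | Path) -> TargetMap:
    """Read a two-column ``mirna<TAB>gene`` TSV; duplicate pairs collapse."""
    raw = _read_tsv(path)
    if raw.shape[1] != 2:
        raise ParseError(f"{path}: expected exactly 2 columns (mirna, gene)")
    pairs = frozenset(
        (str(m), str(g)) for m, g in zip(raw.iloc[:, 0], raw.iloc[:, 1])
    )
    return TargetMap(pairs)


def read_pathways(path: str | Path) -> PathwayGraphSet:
    """Read a four-column ``pathway_id<TAB>source<TAB>target<TAB>class`` TSV."""
    raw = _read_tsv(path)
    if raw.shape[1] != 4:
        raise ParseError(
            f"{path}: expected 4 columns (pathway_id, source, target, class)"
        )
    pathways: list[Pathway] = []
    for pid, block in raw.groupby(raw.columns[0], sort=False):
        classes = set(block.iloc[:, 3].astype(str))
        if len(classes) > 1:
            raise ParseError(f"{path}: pathway {pid!r} has conflicting classes")
        edges = tuple(
            (str(u), str(v)) for u, v in zip(block.iloc[:, 1], block.iloc[:, 2])
        )
        pathways.append(Pathway(str(pid), edges, classes.pop()))
    return PathwayGraphSet(pathways)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label=matrix.feature_kind)


def write_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    labels.labels.rename("label").to_csv(path, sep="\t", index_label="sample")


def write_targets(targets: TargetMap, path: str | Path) -> None:
    df = pd.DataFrame(sorted(targets.pairs), columns=["mirna", "gene"])
    df.to_csv(path, sep="\t", index=False)


def write_pathways(pathways: PathwayGraphSet, path: str | Path) -> None:
    rows = [
        (p.pathway_id, u, v, p.pathway_class)
        for p in pathways.pathways
        for u, v in p.edges
    ]
    pd.DataFrame(rows, columns=["pathway_id", "source", "target", "class"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def match_samples(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    labels: PhenotypeLabels,
) -> tuple[ExpressionMatrix, ExpressionMatrix, PhenotypeLabels]:
    """Restrict all three inputs to their common samples.

    Order is taken from the gene matrix; unmatched samples are dropped with a
    logged count.
    """
    common = [
        s
        for s in gene_expr.sample_ids
        if s in set(mirna_expr.sample_ids) and s in set(labels.sample_ids)
    ]
    if not common:
        raise ValueError("no samples shared between gene/miRNA matrices and labels")
    dropped = (
        len(set(gene_expr.sample_ids) | set(mirna_expr.sample_ids) | set(labels.sample_ids))
        - len(common)
    )
    if dropped:
        logger.info("dropping %d unmatched sample ID(s)", dropped)
    return (
        gene_expr.subset_samples(common),
        mirna_expr.subset_samples(common),
        labels.subset(common),
    )
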