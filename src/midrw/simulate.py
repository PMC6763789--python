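"""Synthetic pathway graphs, target maps and expression cohorts.

The generator emulates the structure of the real inputs: a set of directed
pathway graphs with overlapping gene membership and heavy-tailed degrees
(preferential attachment, so the merged network is approximately
scale-free), a miRNA→gene target map drawn over the pathway genes, and a
matched two-group gene/miRNA expression cohort.

Signal is implanted as inverse regulation: each of the k informative miRNAs
is shifted by ±effect_size standard deviations in the case class, and each
of its (disjointly assigned) target genes is shifted by the same amount in
the opposite direction — exactly the up-miRNA/down-target pattern the
activity inference is built to detect.  Background values are Gaussian;
a small fraction of features is made zero-heavy so the zero-fraction filter
has realistic work to do.

Everything is deterministic under the config seeds: a *design* stream
(``signal_seed``) fixes which miRNAs carry signal, their targets and shift
signs, and a *noise* stream (``seed``) draws the measurements, so two
cohorts sharing a design but not a noise seed emulate independent cohorts
of the same disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    Pathway,
    PathwayGraphSet,
    PhenotypeLabels,
    TargetMap,
    write_expression,
    write_json,
    write_labels,
    write_pathways,
    write_targets,
)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults describe a modest two-group tumour/normal cohort: 50 cases and
    50 controls, a few hundred pathway genes across 20 overlapping pathways,
    60 assayed miRNAs of which k = 5 carry an implanted inverse-regulation
    signal of 1.5 background standard deviations.
    """

    n_pathways: int = 50
    genes_per_pathway: int = 30
    gene_pool_size: int = 500
    pa_edges: int = 3  # preferential-attachment edges per interactome node
    n_mirnas: int = 60
    targets_per_mirna: int = 8
    n_case: int = 50
    n_control: int = 50
    n_informative_mirnas: int = 5
    effect_size: float = 1.5  # in units of noise_sd
    n_weak_mirnas: int = 15  # weakly differential miRNAs filling the pool
    weak_effect_size: float = 0.5
    noise_sd: float = 1.0
    zero_inflation: float = 0.02  # per-cell zero probability, background
    high_zero_fraction: float = 0.08  # fraction of features made zero-heavy
    high_zero_rate: float = 0.5
    log_normal: bool = False
    seed: int = 0
    #: Seed of the signal design (which miRNAs carry signal, their targets
    #: and shift signs).  Defaults to ``seed``; two cohorts sharing a
    #: signal_seed but differing in seed emulate independent measurements of
    #: the same disease process.
    signal_seed: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_pathways",
            "genes_per_pathway",
            "gene_pool_size",
            "pa_edges",
            "n_mirnas",
            "targets_per_mirna",
            "n_case",
            "n_control",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.n_informative_mirnas + self.n_weak_mirnas > self.n_mirnas:
            raise ValueError(
                "informative plus weak miRNAs cannot exceed n_mirnas"
            )


@dataclass
class TruthRecord:
    """Ground truth of the implanted signal."""

    informative_mirnas: dict[str, int]  # miRNA -> case shift sign (+1/-1)
    shifted_targets: dict[str, list[str]]  # miRNA -> genes shifted oppositely
    weak_mirnas: dict[str, int]  # weak-effect miRNAs -> shift sign

    def to_dict(self) -> dict:
        return {
            "informative_mirnas": self.informative_mirnas,
            "shifted_targets": self.shifted_targets,
            "weak_mirnas": self.weak_mirnas,
        }


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _mirna_id(i: int) -> str:
    return f"miR-{i:04d}"


def simulate_pathways(config: SimulationConfig) -> PathwayGraphSet:
    """Directed pathway graphs as local views of one global interactome.

    A single preferential-attachment interactome is grown over the gene
    pool and each edge given one fixed random orientation.  Every pathway
    is then the induced subgraph of a connected neighbourhood sampled by a
    snowball walk from a random start, so pathways overlap, share hub
    genes, and their merged union keeps the heavy-tailed degree
    distribution of the interactome.  The first half of the pathways is
    labelled metabolic, the rest nonmetabolic; the label is carried
    through but does not alter construction (conversion from raw pathway
    sources happens upstream of this tool).
    """
    rng = np.random.default_rng(config.seed)
    n_pool = config.gene_pool_size
    m_edges = min(config.pa_edges, n_pool - 1)
    interactome = nx.barabasi_albert_graph(
        n_pool, m_edges, seed=int(rng.integers(2**31))
    )
    orientation: dict[tuple[int, int], tuple[int, int]] = {}
    for u, v in interactome.edges():
        orientation[(u, v)] = (u, v) if rng.random() < 0.5 else (v, u)

    pathways = []
    size = min(config.genes_per_pathway, n_pool)
    for p in range(config.n_pathways):
        nodes = _snowball_sample(interactome, size, rng)
        edges = []
        for u, v in interactome.subgraph(nodes).edges():
            a, b = orientation[(u, v) if (u, v) in orientation else (v, u)]
            edges.append((_gene_id(a), _gene_id(b)))
        if not edges:  # degenerate sample: connect the nodes in a chain
            ordered = sorted(nodes)
            edges = [
                (_gene_id(a), _gene_id(b)) for a, b in zip(ordered, ordered[1:])
            ]
        cls = "metabolic" if p < config.n_pathways // 2 else "nonmetabolic"
        pathways.append(Pathway(f"path{p:03d}", tuple(edges), cls))
    return PathwayGraphSet(pathways)


def _snowball_sample(
    graph: nx.Graph, size: int, rng: np.random.Generator
) -> set[int]:
    """Connected neighbourhood of ``size`` nodes (random restarts if stuck)."""
    n = graph.number_of_nodes()
    nodes = {int(rng.integers(n))}
    frontier = list(nodes)
    while len(nodes) < size:
        if not frontier:
            fresh = int(rng.integers(n))
            if fresh in nodes:
                continue
            nodes.add(fresh)
            frontier.append(fresh)
            continue
        idx = int(rng.integers(len(frontier)))
        cur = frontier[idx]
        nbrs = [x for x in graph.neighbors(cur) if x not in nodes]
        if not nbrs:
            frontier.pop(idx)
            continue
        take = min(len(nbrs), int(rng.integers(1, 4)), size - len(nodes))
        for x in list(rng.choice(nbrs, size=take, replace=False)):
            nodes.add(int(x))
            frontier.append(int(x))
    return nodes


def simulate_cohort(
    config: SimulationConfig, pathways: PathwayGraphSet
) -> tuple[ExpressionMatrix, ExpressionMatrix, PhenotypeLabels, TargetMap, TruthRecord]:
    """Matched gene/miRNA cohort with implanted inverse-regulated signal."""
    signal_seed = config.signal_seed if config.signal_seed is not None else config.seed
    design = np.random.default_rng([signal_seed, 2])
    rng = np.random.default_rng([config.seed, 1])
    genes = sorted(pathways.all_genes())
    mirnas = [_mirna_id(i) for i in range(config.n_mirnas)]
    n = config.n_case + config.n_control
    samples = [f"S{i:04d}" for i in range(n)]
    case_mask = np.zeros(n, dtype=bool)
    case_mask[: config.n_case] = True

    # target map: signal-carrying miRNAs get disjoint target sets so
    # implanted shifts never collide; background miRNAs draw freely
    carriers = [
        str(x)
        for x in design.choice(
            mirnas,
            size=config.n_informative_mirnas + config.n_weak_mirnas,
            replace=False,
        )
    ]
    informative = carriers[: config.n_informative_mirnas]
    pairs: set[tuple[str, str]] = set()
    available = list(genes)
    design.shuffle(available)
    shifted_targets: dict[str, list[str]] = {}
    cursor = 0
    for m in carriers:
        take = min(config.targets_per_mirna, len(available) - cursor)
        chosen = available[cursor : cursor + take]
        cursor += take
        shifted_targets[m] = sorted(chosen)
        pairs.update((m, g) for g in chosen)
    for m in mirnas:
        if m in shifted_targets:
            continue
        chosen = design.choice(genes, size=min(config.targets_per_mirna, len(genes)), replace=False)
        pairs.update((m, str(g)) for g in chosen)

    gene_vals = rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    mirna_vals = rng.normal(0.0, config.noise_sd, size=(len(mirnas), n))
    gene_index = {g: i for i, g in enumerate(genes)}
    mirna_index = {m: i for i, m in enumerate(mirnas)}

    signs: dict[str, int] = {}
    weak_signs: dict[str, int] = {}
    for m in carriers:
        effect = config.effect_size if m in set(informative) else config.weak_effect_size
        shift = effect * config.noise_sd
        s = 1 if design.random() < 0.5 else -1
        (signs if m in set(informative) else weak_signs)[m] = s
        mirna_vals[mirna_index[m], case_mask] += s * shift
        for g in shifted_targets[m]:
            gene_vals[gene_index[g], case_mask] -= s * shift

    protected = set(carriers) | {g for gs in shifted_targets.values() for g in gs}
    _zero_inflate(gene_vals, genes, protected, config, rng)
    _zero_inflate(mirna_vals, mirnas, protected, config, rng)
    if config.log_normal:
        gene_vals = np.where(gene_vals == 0, 0.0, np.exp(gene_vals))
        mirna_vals = np.where(mirna_vals == 0, 0.0, np.exp(mirna_vals))

    gene_expr = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=genes, columns=samples), "gene"
    )
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=mirnas, columns=samples), "mirna"
    )
    labels = PhenotypeLabels(
        pd.Series(np.where(case_mask, "case", "control"), index=samples)
    )
    truth = TruthRecord(signs, shifted_targets, weak_signs)
    return gene_expr, mirna_expr, labels, TargetMap(frozenset(pairs)), truth


def _zero_inflate(
    values: np.ndarray,
    feature_ids: list[str],
    protected: set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    """Zero out cells in place: background rate everywhere, a high rate for
    a random subset of unprotected features (signal carriers are exempt so
    the implanted effect is untouched)."""
    n_feat, _ = values.shape
    high = rng.random(n_feat) < config.high_zero_fraction
    for i, f in enumerate(feature_ids):
        if f in protected:
            continue
        rate = config.high_zero_rate if high[i] else config.zero_inflation
        if rate > 0:
            mask = rng.random(values.shape[1]) < rate
            values[i, mask] = 0.0


def simulate_bundle(config: SimulationConfig):
    """Convenience: pathways plus cohort in one call.

    Returns ``(pathways, gene_expr, mirna_expr, labels, targets, truth)``.
    """
    pathways = simulate_pathways(config)
    gene_expr, mirna_expr, labels, targets, truth = simulate_cohort(config, pathways)
    return pathways, gene_expr, mirna_expr, labels, targets, truth


def write_bundle(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Write the five input files plus the truth record to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathways, gene_expr, mirna_expr, labels, targets, truth = simulate_bundle(config)
    paths = {
        "gene_expression": str(outdir / "gene_expression.tsv"),
        "mirna_expression": str(outdir / "mirna_expression.tsv"),
        "labels": str(outdir / "labels.tsv"),
        "targets": str(outdir / "targets.tsv"),
        "pathways": str(outdir / "pathways.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_expression(gene_expr, paths["gene_expression"])
    write_expression(mirna_expr, paths["mirna_expression"])
    write_labels(labels, paths["labels"])
    write_targets(targets, paths["targets"])
    write_pathways(pathways, paths["pathways"])
    write_json(truth.to_dict(), paths["truth"])
    return paths
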