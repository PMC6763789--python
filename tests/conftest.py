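"""Shared fixtures: small synthetic cohorts and networks.

Everything is generated programmatically under fixed seeds; session scope
keeps the heavier cohort/network fixtures to one construction each.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import midrw as m


@pytest.fixture(scope="session")
def default_config() -> m.SimulationConfig:
    return m.SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Default-condition synthetic cohort: (pathways, bundle, gdpn, truth)."""
    pathways, ge, me, lab, tg, truth = m.simulate_bundle(default_config)
    gdpn = m.build_gdpn(pathways)
    return pathways, m.DataBundle(ge, me, lab, tg), gdpn, truth


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast protocol bookkeeping tests."""
    cfg = m.SimulationConfig(
        n_pathways=8,
        genes_per_pathway=12,
        gene_pool_size=80,
        n_mirnas=30,
        targets_per_mirna=5,
        n_case=30,
        n_control=30,
        n_weak_mirnas=8,
        seed=7,
    )
    pathways, ge, me, lab, tg, truth = m.simulate_bundle(cfg)
    gdpn = m.build_gdpn(pathways)
    return cfg, m.DataBundle(ge, me, lab, tg), gdpn, truth


@pytest.fixture()
def tiny_gdpn():
    """Three genes A->B->C closed into a GDPN (edges reversed)."""
    ps = m.PathwayGraphSet(
        [
            __import__("midrw.io", fromlist=["Pathway"]).Pathway(
                "p1", (("A", "B"), ("B", "C")), "nonmetabolic"
            )
        ]
    )
    return m.build_gdpn(ps)


def random_gdpn(rng: np.random.Generator, n_genes: int = 19, p_edge: float = 0.15):
    """Random directed gene graph closed into a GDPN (helper, not fixture)."""
    from midrw.io import Pathway, PathwayGraphSet

    genes = [f"g{i}" for i in range(n_genes)]
    edges = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(n_genes)
        if i != j and rng.random() < p_edge
    ]
    if not edges:
        edges = [(genes[0], genes[1])]
    return m.build_gdpn(PathwayGraphSet([Pathway("p", tuple(edges), "metabolic")]))


def random_seed_vector(rng: np.random.Generator, gdpn) -> np.ndarray:
    p0 = np.zeros(gdpn.n_nodes)
    p0[: gdpn.n_nodes - 1] = rng.random(gdpn.n_nodes - 1)
    return p0 / p0.sum()


def closed_form_stationary(gdpn, p0: np.ndarray, r: float) -> np.ndarray:
    """Independent oracle: solve p = (1-r) M^T p + r p0 as a dense system."""
    MT = gdpn.transition.toarray().T
    n = MT.shape[0]
    return r * np.linalg.solve(np.eye(n) - (1 - r) * MT, p0)


@pytest.fixture()
def expr3():
    """3-gene, 4-sample matrix with known group means."""
    data = pd.DataFrame(
        {
            "s1": [4.0, 1.0, 5.0],
            "s2": [5.0, 2.0, 5.0],
            "s3": [1.0, 2.0, 5.0],
            "s4": [2.0, 1.0, 5.0],
        },
        index=["gA", "gB", "gC"],
    )
    return m.ExpressionMatrix(data, "gene")


@pytest.fixture()
def labels4():
    return m.PhenotypeLabels(
        pd.Series(["case", "case", "control", "control"], index=["s1", "s2", "s3", "s4"])
    )
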