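"""Directed random walk with restart over the GDPN.

The walker starts from a seed distribution p0 built from absolute
differential t-scores and at each step either follows a uniform out-edge of
the transition matrix M (probability 1 − r) or restarts at p0
(probability r):

    p_{t+1} = (1 − r) Mᵀ p_t + r p0

Because M is row-stochastic the total probability mass is conserved, and the
map is an L1 contraction with factor (1 − r), so the stationary vector p_∞
exists, is unique, and is reached geometrically fast (about 20 iterations at
r = 0.7 for a 1e-10 tolerance).  p_∞ is the node topology score: genes that
are both differentially expressed (large seed) and topologically upstream of
many differential genes (mass flows into them along reversed edges) score
highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gdpn import GDPN
from .preprocess import DifferentialTable

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


@dataclass
class TopologyScores:
    """Seed and stationary distributions over the GDPN node order."""

    node_ids: list[str]
    p0: np.ndarray
    p_inf: np.ndarray
    restart_prob: float
    iterations: int
    converged: bool

    def score_of(self, node_id: str) -> float:
        return float(self.p_inf[self._index[node_id]])

    @property
    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_index_cache", None)
        if idx is None:
            idx = {n: i for i, n in enumerate(self.node_ids)}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"p0": self.p0, "p_inf": self.p_inf}, index=self.node_ids
        ).to_csv(path, sep="\t", index_label="node")


def seed_vector(
    diff: DifferentialTable, gdpn: GDPN, differential_only: bool = False
) -> np.ndarray:
    """|t|-score seed distribution over GDPN nodes, L1-normalised.

    Genes absent from the differential table, degenerate features and the
    virtual node seed at 0.  With ``differential_only`` the seed is further
    restricted to features passing the differential call.
    """
    p0 = np.zeros(gdpn.n_nodes)
    table = diff.table
    if differential_only:
        table = table[table["is_differential"]]
    usable = table[~table["degenerate"] & np.isfinite(table["t"])]
    for gene, t in usable["t"].items():
        if gene in gdpn:
            p0[gdpn.index_of(gene)] = abs(t)
    total = p0.sum()
    if total == 0:
        raise ValueError("no seeded genes in GDPN")
    return p0 / total


def random_walk(
    gdpn: GDPN,
    p0: np.ndarray,
    restart_prob: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> TopologyScores:
    """Power-iterate the restart walk to its stationary distribution.

    Convergence is declared when the L1 step difference drops to ``tol``.
    Hitting ``max_iter`` first returns an unconverged result with a warning
    rather than raising.
    """
    if not 0 < restart_prob <= 1:
        raise ValueError("restart_prob must lie in (0, 1]")
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (gdpn.n_nodes,):
        raise ValueError("seed vector length does not match GDPN")
    if (p0 < 0).any() or not np.isclose(p0.sum(), 1.0, atol=1e-12):
        raise ValueError("seed must be a probability vector")

    MT = gdpn.transition.T.tocsr()
    p = p0.copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        p_next = (1.0 - restart_prob) * (MT @ p) + restart_prob * p0
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta <= tol:
            converged = True
            break
    if not converged:
        logger.warning("random walk did not converge in %d iterations", max_iter)
    return TopologyScores(
        node_ids=list(gdpn.node_ids),
        p0=p0,
        p_inf=p,
        restart_prob=restart_prob,
        iterations=iterations,
        converged=converged,
    )
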