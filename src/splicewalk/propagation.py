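"""Random walk with restart on a merged multilayer network.

The K evidence layers are collapsed into a single symmetric adjacency by
averaging edge weights over the fixed layer count K (an edge absent from a
layer contributes 0, so an edge supported by one of three layers carries a
third of its weight). The walk then iterates

    p(t+1) = (1 - alpha) * B @ p(t) + alpha * p_s

with a column-stochastic transition matrix B (columns of the adjacency
normalized to 1; isolated nodes become self-absorbing) and a seed
distribution p_s, until the L1 change falls below tolerance. Because the
update is an alpha-contraction in L1, convergence is geometric at rate
(1 - alpha).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .network import LNC_SIDE, MultiGraph

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.5
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 10_000


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class AdjacencyMatrix:
    """Symmetric nonnegative merged adjacency with its node ordering."""

    A: sp.csr_matrix
    node_order: list[str]

    @property
    def n(self) -> int:
        return len(self.node_order)

    def index_of(self) -> dict[str, int]:
        return {nid: i for i, nid in enumerate(self.node_order)}


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix B over the same node ordering."""

    B: sp.csr_matrix
    node_order: list[str]

    @property
    def n(self) -> int:
        return len(self.node_order)


@dataclass
class SeedVector:
    p_s: np.ndarray
    seed_ids: list[str]
    node_order: list[str]


@dataclass
class ScoreVector:
    p: np.ndarray
    node_order: list[str]
    iterations_used: int
    converged: bool

    def as_series(self) -> pd.Series:
        return pd.Series(self.p, index=self.node_order, name="score")


def merge_layers(mg: MultiGraph, node_order: Sequence[str] | None = None) -> AdjacencyMatrix:
    """Average the per-layer edge weights into one adjacency.

    The denominator is the total layer count K, not the number of layers
    containing a given edge, so single-layer evidence is down-weighted
    relative to multi-layer support.
    """
    if mg.n_layers < 1:
        raise ValueError("at least one layer is required")
    order = list(node_order) if node_order is not None else [n.id for n in mg.nodes]
    if set(order) != {n.id for n in mg.nodes}:
        raise ValueError("node_order must be a permutation of the graph's node ids")
    idx = {nid: i for i, nid in enumerate(order)}
    K = mg.n_layers
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for layer in mg.layers:
        for (u, v), w in layer.edges.items():
            i, j = idx[u], idx[v]
            rows += [i, j]
            cols += [j, i]
            vals += [w / K, w / K]
    n = len(order)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    A.sum_duplicates()
    return AdjacencyMatrix(A=A, node_order=order)


def transition_matrix(adj: AdjacencyMatrix) -> TransitionMatrix:
    """Column-normalize the adjacency; isolated columns become self-absorbing."""
    A = adj.A.tocsc(copy=True)
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    dangling = col_sums == 0
    scale = np.ones_like(col_sums)
    nz = ~dangling
    scale[nz] = 1.0 / col_sums[nz]
    B = A @ sp.diags(scale)
    if dangling.any():
        d_idx = np.flatnonzero(dangling)
        B = B + sp.coo_matrix(
            (np.ones(d_idx.size), (d_idx, d_idx)), shape=B.shape
        )
    return TransitionMatrix(B=B.tocsr(), node_order=adj.node_order)


def make_seed_vector(
    seed_ids: Iterable[str],
    node_order: Sequence[str],
    normalize: bool = True,
) -> SeedVector:
    """Place restart mass on the seed nodes.

    With ``normalize=True`` (default) each seed receives 1/|seeds| so p_s is a
    probability distribution; ``normalize=False`` gives each seed entry 1,
    which rescales all scores by |seeds| without changing the ranking.
    """
    seeds = list(dict.fromkeys(seed_ids))
    if not seeds:
        raise ValueError("seed set is empty")
    idx = {nid: i for i, nid in enumerate(node_order)}
    unknown = [s for s in seeds if s not in idx]
    if unknown:
        raise ValueError(f"seed ids not in node universe: {unknown}")
    p_s = np.zeros(len(node_order))
    mass = 1.0 / len(seeds) if normalize else 1.0
    for s in seeds:
        p_s[idx[s]] = mass
    return SeedVector(p_s=p_s, seed_ids=seeds, node_order=list(node_order))


def rwr(
    B: TransitionMatrix,
    p_s: SeedVector,
    alpha: float = DEFAULT_ALPHA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    callback: Callable[[int, np.ndarray], None] | None = None,
) -> ScoreVector:
    """Iterate the restart recursion from p(0) = p_s to its fixed point."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if B.node_order != p_s.node_order:
        raise ValueError("transition matrix and seed vector node orders differ")
    mat = B.B
    p = p_s.p_s.copy()
    restart = alpha * p_s.p_s
    if callback is not None:
        callback(0, p)
    for t in range(1, max_iter + 1):
        p_next = (1.0 - alpha) * (mat @ p) + restart
        delta = np.abs(p_next - p).sum()
        p = p_next
        if callback is not None:
            callback(t, p)
        if delta < tol:
            logger.info("rwr converged in %d iterations (L1 change %.3e)", t, delta)
            return ScoreVector(p=p, node_order=B.node_order, iterations_used=t, converged=True)
    warnings.warn(
        f"rwr did not converge in {max_iter} iterations (last L1 change {delta:.3e})",
        ConvergenceWarning,
        stacklevel=2,
    )
    return ScoreVector(p=p, node_order=B.node_order, iterations_used=max_iter, converged=False)


def closed_form_rwr(
    B: TransitionMatrix, p_s: SeedVector, alpha: float = DEFAULT_ALPHA
) -> ScoreVector:
    """Solve the fixed point directly: p = alpha * (I - (1-alpha) B)^-1 p_s.

    Dense linear solve; intended as an analytic cross-check of :func:`rwr`
    on small graphs, not as the production path.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if B.node_order != p_s.node_order:
        raise ValueError("transition matrix and seed vector node orders differ")
    n = B.n
    M = np.eye(n) - (1.0 - alpha) * B.B.toarray()
    p = alpha * np.linalg.solve(M, p_s.p_s)
    return ScoreVector(p=p, node_order=B.node_order, iterations_used=0, converged=True)


def rank_candidates(
    scores: ScoreVector,
    node_class_of: dict[str, str],
    candidate_classes: frozenset[str] | set[str] = LNC_SIDE,
    exclude_seeds: bool = False,
    seed_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Restrict scores to candidate node classes and rank them.

    Sorted by score descending; ties break lexicographically by node id and
    ranks are consecutive from 1 (deterministic output).
    """
    excluded = set(seed_ids) if exclude_seeds else set()
    rows = [
        (nid, float(s), node_class_of[nid])
        for nid, s in zip(scores.node_order, scores.p)
        if node_class_of.get(nid) in candidate_classes and nid not in excluded
    ]
    if not rows:
        raise ValueError("no candidate nodes remain after filtering")
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(
        {
            "id": [r[0] for r in rows],
            "rank": np.arange(1, len(rows) + 1),
            "score": [r[1] for r in rows],
            "node_class": [r[2] for r in rows],
        }
    )


class RandomWalkRanker(BaseEstimator):
    """Seed-driven node prioritization on a merged multilayer network.

    A scikit-learn style estimator: ``fit(multigraph, seed_ids)`` merges the
    layers, builds the column-stochastic transition matrix, and propagates
    restart probability from the seeds to a stationary score per node;
    ``rank()`` then returns candidate nodes ordered by score.

    Parameters
    ----------
    alpha : float, default 0.5
        Restart probability; higher values keep probability nearer the seeds.
    tol : float, default 1e-10
        L1 convergence tolerance of the iteration.
    max_iter : int, default 10000
        Iteration cap; non-convergence raises a warning, not an error.
    normalize_seeds : bool, default True
        Distribute unit mass uniformly over the seeds (probability semantics).
        If False, each seed entry is 1 (scores rescale; ranking unchanged).

    Attributes
    ----------
    node_order_ : list of node ids fixing the index <-> id map
    adjacency_ : AdjacencyMatrix of the merged layers
    transition_ : TransitionMatrix
    seed_vector_ : SeedVector
    scores_ : ScoreVector with stationary probabilities
    n_iter_ : iterations used
    converged_ : bool
    """

    def __init__(
        self,
        alpha: float = DEFAULT_ALPHA,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        normalize_seeds: bool = True,
    ):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.normalize_seeds = normalize_seeds

    def fit(self, multigraph: MultiGraph, seed_ids: Iterable[str]) -> "RandomWalkRanker":
        self.adjacency_ = merge_layers(multigraph)
        self.node_order_ = self.adjacency_.node_order
        self.transition_ = transition_matrix(self.adjacency_)
        self.seed_vector_ = make_seed_vector(
            seed_ids, self.node_order_, normalize=self.normalize_seeds
        )
        self.scores_ = rwr(
            self.transition_,
            self.seed_vector_,
            alpha=self.alpha,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.n_iter_ = self.scores_.iterations_used
        self.converged_ = self.scores_.converged
        self._node_class_of = multigraph.node_class_of()
        return self

    def scores(self) -> pd.Series:
        self._check_fitted()
        return self.scores_.as_series()

    def rank(
        self,
        candidate_classes: frozenset[str] | set[str] = LNC_SIDE,
        exclude_seeds: bool = False,
    ) -> pd.DataFrame:
        self._check_fitted()
        return rank_candidates(
            self.scores_,
            self._node_class_of,
            candidate_classes=candidate_classes,
            exclude_seeds=exclude_seeds,
            seed_ids=self.seed_vector_.seed_ids,
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "scores_"):
            raise RuntimeError("RandomWalkRanker is not fitted; call fit() first")
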