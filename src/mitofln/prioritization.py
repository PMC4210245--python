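"""Stage 3: network propagation of disease seed genes over the FLN.

Genes underlying the same or related diseases tend to be functionally
linked, so candidates are ranked by how strongly signal placed on known
disease genes ("seeds") propagates to them through the weighted
network.  Four rankers are provided:

* AAR  — average adjacency to randomly resampled seed subsets;
* PRP  — PageRank with priors: random walk restarting at the seeds
         with back-probability beta;
* KSM  — K-step Markov: cumulative visit probability over exactly K
         walk steps from the seeds;
* HKDR — heat kernel diffusion: iterative approximation of
         exp(-alpha * L^T) applied to the seed indicator, with
         L = I - W the random-walk Laplacian.

All propagation uses the transpose of the row-stochastic transition
matrix W = D^-1 A, so probability mass flows from the seeds outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge; carries the final residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"no convergence after {max_iter} iterations (L1 residual {residual:.3g})"
        )
        self.residual = residual


@dataclass
class TransitionModel:
    """Row-stochastic random-walk operator of a weighted graph.

    ``W[i, j]`` is the probability of stepping from node i to node j,
    proportional to the edge weight.  Rows of zero-degree nodes are
    all-zero and those nodes are flagged; the Laplacian-like operator
    L = I - W is applied on demand.
    """

    nodes: List[str]
    adjacency: sp.csr_matrix
    transition: sp.csr_matrix
    degrees: np.ndarray
    index: Dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "TransitionModel":
        nodes = sorted(g.nodes)
        A = nx.to_scipy_sparse_array(g, nodelist=nodes, weight="weight", format="csr")
        deg = np.asarray(A.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
        W = sp.diags(inv) @ A
        return cls(nodes=nodes, adjacency=sp.csr_matrix(A),
                   transition=sp.csr_matrix(W), degrees=deg,
                   index={n: i for i, n in enumerate(nodes)})

    @property
    def zero_degree(self) -> List[str]:
        return [n for n, d in zip(self.nodes, self.degrees) if d == 0]

    def seed_vector(self, seeds: Sequence[str]) -> np.ndarray:
        """Uniform probability vector on the seeds: 1/|R| per seed."""
        seeds = sorted(set(seeds))
        if not seeds:
            raise ValueError("seed set is empty")
        missing = [s for s in seeds if s not in self.index]
        if missing:
            raise ValueError(f"seeds not in network: {missing}")
        p = np.zeros(len(self.nodes))
        p[[self.index[s] for s in seeds]] = 1.0 / len(seeds)
        return p


@dataclass
class RankingResult:
    """Per-gene prioritization scores for one seed set and algorithm."""

    algorithm: str
    params: Dict
    scores: pd.Series
    seeds: frozenset

    def ranked(self, exclude_seeds: bool = True, bands: int | None = None
               ) -> pd.DataFrame:
        return rank(self.scores, self.seeds if exclude_seeds else frozenset(),
                    bands=bands)


def _result(name: str, params: Dict, tm: TransitionModel, scores: np.ndarray,
            seeds: Iterable[str]) -> RankingResult:
    if not np.isfinite(scores).all():
        raise ValueError(f"{name} produced non-finite scores")
    return RankingResult(
        algorithm=name, params=dict(params),
        scores=pd.Series(scores, index=tm.nodes, name=name),
        seeds=frozenset(seeds),
    )


def aar(g: nx.Graph, seeds: Sequence[str], m: int | None = None,
        iterations: int = 100, seed: int = 0) -> RankingResult:
    """Average adjacency ranking by resampled seed subsets.

    Each iteration samples ``m`` seeds without replacement; every gene
    outside the sampled subset accrues the sum of its edge weights to
    the sampled seeds.  The final score divides each gene's accumulated
    sum by the number of iterations in which it was outside the subset
    (0 if never scoreable).  ``m = |seeds|`` is the deterministic limit.
    """
    tm = TransitionModel.from_graph(g)
    seeds = sorted(set(seeds))
    tm.seed_vector(seeds)  # validates membership/non-emptiness
    if m is None:
        m = len(seeds)
    if not 1 <= m <= len(seeds):
        raise ValueError(f"m={m} outside [1, {len(seeds)}]")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    seed_idx = np.array([tm.index[s] for s in seeds])
    A = tm.adjacency
    acc = np.zeros(len(tm.nodes))
    n_i = np.zeros(len(tm.nodes))
    for _ in range(iterations):
        chosen = seed_idx if m == len(seeds) else rng.choice(seed_idx, size=m,
                                                             replace=False)
        contrib = np.asarray(A[:, chosen].sum(axis=1)).ravel()
        eligible = np.ones(len(tm.nodes), dtype=bool)
        eligible[chosen] = False
        acc[eligible] += contrib[eligible]
        n_i += eligible
    scores = np.divide(acc, n_i, out=np.zeros_like(acc), where=n_i > 0)
    return _result("AAR", {"m": m, "iterations": iterations, "seed": seed},
                   tm, scores, seeds)


def prp(g: nx.Graph, seeds: Sequence[str], beta: float = 0.3,
        tol: float = 1e-10, max_iter: int = 10000) -> RankingResult:
    """PageRank with priors: stationary distribution of a restarting walk.

    Solves pi = beta * p + (1 - beta) * W^T pi by power iteration,
    where p is uniform on the seeds; scores sum to 1.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    tm = TransitionModel.from_graph(g)
    p = tm.seed_vector(seeds)
    WT = tm.transition.T.tocsr()
    pi = p.copy()
    for _ in range(max_iter):
        new = beta * p + (1.0 - beta) * (WT @ pi)
        total = new.sum()
        if total > 0:  # guard against mass lost at zero-degree nodes
            new = new / total
        residual = float(np.abs(new - pi).sum())
        pi = new
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)
    return _result("PRP", {"beta": beta, "tol": tol}, tm, pi, seeds)


def ksm(g: nx.Graph, seeds: Sequence[str], K: int = 4) -> RankingResult:
    """K-step Markov importance: sum of walk occupancy over K steps.

    score = sum_{k=1..K} (W^T)^k p_R with p_R uniform on the seeds; the
    t-th entry is the relative time the walk spends at node t within
    the first K steps.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    tm = TransitionModel.from_graph(g)
    x = tm.seed_vector(seeds)
    WT = tm.transition.T.tocsr()
    total = np.zeros_like(x)
    for _ in range(K):
        x = WT @ x
        total += x
    return _result("KSM", {"K": K}, tm, total, seeds)


def hkdr(g: nx.Graph, seeds: Sequence[str], alpha: float = 1.0,
         n_iter: int = 3) -> RankingResult:
    """Heat kernel diffusion ranking of the seed signal.

    Computes p = (I - (alpha/N) L^T)^N p_0 with L = I - W and p_0
    uniform on the seeds — the N-step discrete approximation of
    exp(-alpha L^T) p_0.  ``n_iter`` (N) sets the approximation order;
    larger N approaches the continuous heat kernel.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    tm = TransitionModel.from_graph(g)
    p = tm.seed_vector(seeds)
    WT = tm.transition.T.tocsr()
    step = alpha / n_iter
    for _ in range(n_iter):
        # (I - step * L^T) p = p - step * (p - W^T p)
        p = p - step * (p - WT @ p)
    return _result("HKDR", {"alpha": alpha, "n_iter": n_iter}, tm, p, seeds)


ALGORITHMS = {"aar": aar, "prp": prp, "ksm": ksm, "hkdr": hkdr}


def rank(scores: pd.Series, exclude: Iterable[str] = (),
         bands: int | None = None) -> pd.DataFrame:
    """Order candidates by descending score, excluding the seeds.

    Ties break by ascending gene identifier so rankings are fully
    deterministic.  With ``bands``, genes are additionally labelled by
    score quantile into that many confidence levels (1 = top).
    """
    exclude = set(exclude)
    sub = scores[~scores.index.isin(exclude)]
    order = sorted(sub.index, key=lambda gene: (-sub[gene], gene))
    out = pd.DataFrame({
        "rank": np.arange(1, len(order) + 1),
        "gene": order,
        "score": [float(sub[g]) for g in order],
    })
    if bands is not None and len(out):
        # quantile bands over scores; band 1 holds the highest scores
        qs = np.quantile(out["score"], np.linspace(0, 1, bands + 1))
        lab = bands - np.clip(np.searchsorted(qs[1:-1], out["score"],
                                              side="left"), 0, bands - 1)
        out["band"] = lab
    return out
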