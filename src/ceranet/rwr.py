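"""Random walk with restart (RWR) on the ceRNA network.

A walker starts on the disease seed genes (initial probability 1/n on
each of the n seed mRNAs) and at every step either moves to a uniformly
chosen neighbor (probability 1 - r) or restarts at the seeds
(probability r):

    P(t+1) = (1 - r) W P(t) + r P0

with W the column-normalized adjacency matrix.  Iteration stops when
the L1 difference between successive vectors falls below ``tol``; the
fixed point P(inf) scores every node's proximity to the seed set, and
lncRNAs are ranked by it.

Statistical significance is assessed by a permutation null: the seed
set is re-drawn uniformly (without replacement) from the network's mRNA
nodes N times, the walk is re-run, and each lncRNA's empirical p-value
is M/N where M counts permutations whose score strictly exceeds the
real one.  The strict inequality means a lncRNA whose score is never
exceeded gets p = 0; an optional ``(M+1)/(N+1)`` pseudocount mode avoids
exact zeros when a never-zero estimator is preferred.

Isolated nodes would lose walker mass (their adjacency column is all
zero), so they are pruned before the walk by default.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = ["RandomWalkRestart", "rwr_propagate", "permutation_test", "rank_lncrnas"]


def _column_normalized_adjacency(
    network: nx.Graph, nodes: Sequence[str]
) -> np.ndarray:
    A = nx.to_numpy_array(network, nodelist=nodes, dtype=float)
    colsum = A.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = np.where(colsum > 0, A / colsum, 0.0)
    return W


def _propagate(
    W: np.ndarray,
    P0: np.ndarray,
    restart_prob: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, float]:
    """Iterate the RWR update on one or many start vectors (columns)."""
    Pt = P0.copy()
    for it in range(1, max_iter + 1):
        Pnext = (1.0 - restart_prob) * (W @ Pt) + restart_prob * P0
        residual = float(np.abs(Pnext - Pt).sum(axis=0).max())
        Pt = Pnext
        if residual < tol:
            return Pt, it, residual
    raise RuntimeError(
        f"RWR did not converge within {max_iter} iterations "
        f"(last L1 residual {residual:.3e}, tol {tol:.1e})"
    )


class RandomWalkRestart(BaseEstimator):
    """Seeded network propagation with a seed-shuffling permutation null.

    Parameters
    ----------
    restart_prob : float
        Restart probability r in (0, 1].
    tol : float
        L1 convergence cutoff on successive probability vectors.
    max_iter : int
        Safety bound on iterations.
    n_permutations : int
        Number of random seed sets for the empirical null; 0 disables
        the permutation test.
    perm_seed : int or None
        RNG seed for the permutation draws (determinism contract).
    pseudocount : bool
        Report (M+1)/(N+1) instead of M/N.
    degree_matched : bool
        Draw permuted seeds degree-matched to the real seeds (each real
        seed replaced by an mRNA of nearest degree) instead of uniformly;
        uniform draws bias the null toward low-degree seeds.
    prune_isolated : bool
        Drop degree-0 nodes before the walk (their adjacency column is
        all zero and would leak walker mass).

    Attributes
    ----------
    scores_ : pandas.Series
        Stationary probability P(inf) per node, summing to 1.
    pvalues_ : pandas.Series
        Permutation p-value per lncRNA (empty if n_permutations = 0).
    ranking_ : pandas.DataFrame
        lncRNAs sorted by score (descending, lexicographic tie-break)
        with p-values and significance flags.
    n_iter_ : int
        Iterations used by the real-seed walk.
    """

    def __init__(
        self,
        restart_prob: float = 0.5,
        tol: float = 1e-10,
        max_iter: int = 10_000,
        n_permutations: int = 10_000,
        perm_seed: int | None = None,
        alpha: float = 0.01,
        pseudocount: bool = False,
        degree_matched: bool = False,
        prune_isolated: bool = True,
    ):
        self.restart_prob = restart_prob
        self.tol = tol
        self.max_iter = max_iter
        self.n_permutations = n_permutations
        self.perm_seed = perm_seed
        self.alpha = alpha
        self.pseudocount = pseudocount
        self.degree_matched = degree_matched
        self.prune_isolated = prune_isolated

    def fit(self, network: nx.Graph, seeds: Iterable[str]) -> "RandomWalkRestart":
        if not 0 < self.restart_prob <= 1:
            raise ValueError(f"restart_prob must be in (0, 1], got {self.restart_prob}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")
        seeds = list(dict.fromkeys(seeds))
        if not seeds:
            raise ValueError("seed list is empty")
        graph = network
        if self.prune_isolated:
            isolated = list(nx.isolates(graph))
            if isolated:
                logger.info("pruning %d isolated nodes before the walk", len(isolated))
                graph = graph.copy()
                graph.remove_nodes_from(isolated)
        nodes = sorted(graph.nodes())
        index = {n: i for i, n in enumerate(nodes)}
        missing = [s for s in seeds if s not in index]
        if missing:
            # seed genes are chosen from an external disease database and
            # are only usable if they made it into the network
            seeds = [s for s in seeds if s in index]
            if not seeds:
                raise ValueError(f"no seed gene found in the network; missing: {missing}")
            logger.warning(
                "dropping %d seed genes absent from the network: %s", len(missing), missing
            )

        W = _column_normalized_adjacency(graph, nodes)
        n = len(nodes)
        P0 = np.zeros(n)
        P0[[index[s] for s in seeds]] = 1.0 / len(seeds)

        Pinf, n_iter, _ = _propagate(
            W, P0[:, None], self.restart_prob, self.tol, self.max_iter
        )
        scores = pd.Series(Pinf[:, 0], index=pd.Index(nodes, name="node"), name="score")

        lnc_nodes = [n_ for n_ in nodes if graph.nodes[n_].get("node_class") == "lncRNA"]
        mrna_nodes = [n_ for n_ in nodes if graph.nodes[n_].get("node_class") == "mRNA"]

        pvals = pd.Series(dtype=float)
        if self.n_permutations > 0 and lnc_nodes:
            if len(seeds) > len(mrna_nodes):
                raise ValueError(
                    f"cannot draw {len(seeds)} permuted seeds from "
                    f"{len(mrna_nodes)} mRNA nodes"
                )
            rng = np.random.default_rng(self.perm_seed)
            mrna_idx = np.array([index[m] for m in mrna_nodes])
            degrees = np.array([graph.degree(m) for m in mrna_nodes])
            P0_perm = np.zeros((n, self.n_permutations))
            for j in range(self.n_permutations):
                if self.degree_matched:
                    chosen = self._degree_matched_draw(
                        rng, mrna_idx, degrees, [graph.degree(s) for s in seeds]
                    )
                else:
                    chosen = rng.choice(mrna_idx, size=len(seeds), replace=False)
                P0_perm[chosen, j] = 1.0 / len(seeds)
            Pperm, _, _ = _propagate(
                W, P0_perm, self.restart_prob, self.tol, self.max_iter
            )
            lnc_i = np.array([index[l] for l in lnc_nodes])
            real = scores.to_numpy()[lnc_i][:, None]
            M = (Pperm[lnc_i, :] > real).sum(axis=1)
            if self.pseudocount:
                p = (M + 1) / (self.n_permutations + 1)
            else:
                p = M / self.n_permutations
            pvals = pd.Series(p, index=pd.Index(lnc_nodes, name="lncrna_id"), name="p_value")

        self.nodes_ = nodes
        self.scores_ = scores
        self.pvalues_ = pvals
        self.n_iter_ = n_iter
        self.seeds_ = seeds
        self.ranking_ = rank_lncrnas(scores, pvals, lnc_nodes, alpha=self.alpha)
        return self

    @staticmethod
    def _degree_matched_draw(rng, mrna_idx, degrees, seed_degrees):
        chosen: list[int] = []
        taken = np.zeros(len(mrna_idx), dtype=bool)
        for sd in seed_degrees:
            gap = np.abs(degrees - sd).astype(float)
            gap[taken] = np.inf
            # sample uniformly among the closest-degree candidates
            best = np.flatnonzero(gap == gap.min())
            pick = int(rng.choice(best))
            taken[pick] = True
            chosen.append(int(mrna_idx[pick]))
        return np.array(chosen)


def rank_lncrnas(
    scores: pd.Series,
    pvalues: pd.Series,
    lncrna_ids: Sequence[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Order lncRNAs by stationary score (descending, ties lexicographic)."""
    rows = []
    for lnc in lncrna_ids:
        p = float(pvalues.get(lnc, np.nan)) if len(pvalues) else np.nan
        rows.append(
            {
                "lncrna_id": lnc,
                "score": float(scores[lnc]),
                "p_value": p,
                "significant": bool(p < alpha) if not np.isnan(p) else False,
            }
        )
    df = pd.DataFrame(rows, columns=["lncrna_id", "score", "p_value", "significant"])
    if len(df):
        df = df.sort_values(
            ["score", "lncrna_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def permutation_test(
    network: nx.Graph,
    seeds: Iterable[str],
    n_permutations: int = 10_000,
    perm_seed: int | None = None,
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Empirical p = M/N per lncRNA from seed-shuffled walks.

    The ratio is undefined without permutations, so ``n_permutations``
    must be positive here (use :func:`rwr_propagate` for scores alone).
    """
    if n_permutations <= 0:
        raise ValueError("n_permutations must be positive: p = M/N is undefined at N = 0")
    est = RandomWalkRestart(
        restart_prob=restart_prob,
        tol=tol,
        n_permutations=n_permutations,
        perm_seed=perm_seed,
        alpha=alpha,
    ).fit(network, seeds)
    return est.ranking_


def rwr_propagate(
    network: nx.Graph,
    seeds: Iterable[str],
    restart_prob: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.Series:
    """Stationary RWR score vector for one seed set (no permutation null)."""
    est = RandomWalkRestart(
        restart_prob=restart_prob, tol=tol, max_iter=max_iter, n_permutations=0
    ).fit(network, seeds)
    return est.scores_
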