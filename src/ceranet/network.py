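"""Competing-pair selection by the hypergeometric shared-miRNA test.

A lncRNA and an mRNA are candidate competing endogenous RNAs (ceRNAs)
when they share miRNA partners far above chance.  With a miRNA universe
of size ``T``, an mRNA bound by ``t`` miRNAs, a lncRNA bound by ``N``
miRNAs and ``r`` shared partners, the evidence is the upper tail of the
hypergeometric distribution,

    P(X >= r),  X ~ Hypergeometric(T, t, N),

i.e. one minus the probability of fewer than ``r`` shared partners if
the lncRNA drew its ``N`` partners uniformly from the universe.  Pairs
with P below ``alpha`` (default 0.01, uncorrected) form the edges of the
bipartite lncRNA-mRNA ceRNA network.

The universe ``T`` ("all human miRNAs") is ambiguous in practice and
changes every p-value, so it is configurable: ``interaction-union``
(default) counts the miRNAs present in the filtered interaction tables,
making T, t, N and r internally consistent; ``de-only`` restricts to
differentially expressed miRNAs; ``fixed`` takes an externally supplied
annotation count.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import InteractionSet

logger = logging.getLogger(__name__)

__all__ = [
    "hypergeom_p",
    "CeRNANetworkBuilder",
    "build_cerna_network",
    "extract_subnetwork",
]


_LOG_FACT = np.zeros(1)  # grown on demand: _LOG_FACT[n] = log(n!)


def _log_factorials(n_max: int) -> np.ndarray:
    global _LOG_FACT
    if n_max >= _LOG_FACT.size:
        _LOG_FACT = np.concatenate(
            [[0.0], np.cumsum(np.log(np.arange(1, max(n_max, 1024) + 1)))]
        )
    return _LOG_FACT


def _log_comb(n: int, k) -> float:
    lf = _log_factorials(n)
    return lf[n] - lf[k] - lf[n - k]


def hypergeom_p(T: int, t: int, N: int, r: int) -> float:
    """Upper-tail probability P(X >= r) for X ~ Hypergeometric(T, t, N).

    Computed by summing the tail terms C(t,k) C(T-t,N-k) / C(T,N) for
    k = r..min(t, N) in log space, which stays accurate for large counts
    where the complementary sum 1 - P(X < r) would cancel.

    ``r = 0`` returns exactly 1 (the tail is the whole distribution).
    """
    for name, val in (("T", T), ("t", t), ("N", N), ("r", r)):
        if val < 0 or int(val) != val:
            raise ValueError(f"{name} must be a nonnegative integer, got {val!r}")
    if t > T or N > T:
        raise ValueError(f"t={t} and N={N} must not exceed the universe T={T}")
    if r > min(t, N):
        raise ValueError(f"r={r} exceeds min(t, N)={min(t, N)}")
    if r == 0:
        return 1.0
    k = np.arange(r, min(t, N) + 1)
    # support of the pmf also requires N - k <= T - t
    k = k[(N - k) <= (T - t)]
    if k.size == 0:
        return 0.0
    log_terms = _log_comb(t, k) + _log_comb(T - t, N - k) - _log_comb(T, N)
    m = float(log_terms.max())
    return float(min(1.0, math.exp(m) * float(np.exp(log_terms - m).sum())))


class CeRNANetworkBuilder(BaseEstimator):
    """Assemble the lncRNA-mRNA ceRNA network from DE calls and interactions.

    Parameters
    ----------
    alpha : float
        Raw hypergeometric p-value threshold for keeping a pair
        (uncorrected by default, per common ceRNA practice).
    universe_mode : {"interaction-union", "de-only", "fixed"}
        How the miRNA universe size T is determined (see module docs).
    universe_size : int or None
        Required when ``universe_mode == "fixed"``.
    require_de_targets : bool
        Require both the lncRNA and the mRNA to be differentially
        expressed before testing (default True).
    filter_mirnas_first : bool
        Restrict interaction tables to DE miRNAs before counting
        overlaps (default True); if False, overlaps are counted on the
        full tables and only the pair endpoints are DE-filtered.
    adjust : bool
        Apply Benjamini-Hochberg across candidate pairs and threshold
        the adjusted p instead of the raw p.

    Attributes
    ----------
    network_ : networkx.Graph
        Bipartite graph; nodes carry ``node_class`` in {lncRNA, mRNA},
        edges carry T, t, N, r, p_value and the shared miRNA set.
    pairs_ : pandas.DataFrame
        All candidate pairs with r >= 1 and their evidence, retained or not.
    universe_ : frozenset[str]
        The miRNA universe actually used.
    """

    def __init__(
        self,
        alpha: float = 0.01,
        universe_mode: str = "interaction-union",
        universe_size: int | None = None,
        require_de_targets: bool = True,
        filter_mirnas_first: bool = True,
        adjust: bool = False,
    ):
        self.alpha = alpha
        self.universe_mode = universe_mode
        self.universe_size = universe_size
        self.require_de_targets = require_de_targets
        self.filter_mirnas_first = filter_mirnas_first
        self.adjust = adjust

    def fit(
        self,
        interactions: InteractionSet,
        de_mirnas: Iterable[str],
        de_mrnas: Iterable[str],
        de_lncrnas: Iterable[str],
    ) -> "CeRNANetworkBuilder":
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.universe_mode not in ("interaction-union", "de-only", "fixed"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        if self.universe_mode == "fixed" and not self.universe_size:
            raise ValueError("universe_mode='fixed' requires universe_size")
        de_mirnas = set(de_mirnas)
        targets = None
        if self.require_de_targets:
            targets = {"mRNA": set(de_mrnas), "lncRNA": set(de_lncrnas)}
        filtered = interactions.subset(
            mirnas=de_mirnas if self.filter_mirnas_first else None,
            targets_by_class=targets,
        )
        if len(filtered) == 0:
            logger.warning("no interactions survive DE filtering; network is empty")

        mrna_map = filtered.partner_map("mRNA")
        lnc_map = filtered.partner_map("lncRNA")

        if self.universe_mode == "interaction-union":
            universe = filtered.mirnas
        elif self.universe_mode == "de-only":
            universe = filtered.mirnas & de_mirnas
        else:
            universe = None  # count supplied externally
        T = self.universe_size if universe is None else len(universe)

        rows = []
        for lnc in sorted(lnc_map):
            lnc_set = lnc_map[lnc]
            for mrna in sorted(mrna_map):
                shared = lnc_set & mrna_map[mrna]
                if not shared:
                    continue  # r = 0 gives p = 1 by the tail formula
                t_cnt, n_cnt, r_cnt = len(mrna_map[mrna]), len(lnc_set), len(shared)
                p = hypergeom_p(T, t_cnt, n_cnt, r_cnt)
                rows.append(
                    {
                        "lncrna_id": lnc,
                        "mrna_id": mrna,
                        "T": T,
                        "t": t_cnt,
                        "N": n_cnt,
                        "r": r_cnt,
                        "p_value": p,
                        "shared_mirnas": frozenset(shared),
                    }
                )
        pairs = pd.DataFrame(
            rows,
            columns=["lncrna_id", "mrna_id", "T", "t", "N", "r", "p_value", "shared_mirnas"],
        )
        if len(pairs) and self.adjust:
            from statsmodels.stats.multitest import multipletests

            pairs["p_adj"] = multipletests(pairs["p_value"], method="fdr_bh")[1]
            keep = pairs["p_adj"] < self.alpha
        else:
            keep = pairs["p_value"] < self.alpha if len(pairs) else pd.Series(dtype=bool)
        pairs["retained"] = keep

        graph = nx.Graph()
        for row in pairs[pairs["retained"]].itertuples(index=False):
            graph.add_node(row.lncrna_id, node_class="lncRNA")
            graph.add_node(row.mrna_id, node_class="mRNA")
            graph.add_edge(
                row.lncrna_id,
                row.mrna_id,
                T=row.T,
                t=row.t,
                N=row.N,
                r=row.r,
                p_value=row.p_value,
                shared_mirnas=row.shared_mirnas,
            )
        self.pairs_ = pairs
        self.network_ = graph
        self.universe_ = frozenset(universe) if universe is not None else None
        return self


def build_cerna_network(
    interactions: InteractionSet,
    de_mirnas: Iterable[str],
    de_mrnas: Iterable[str],
    de_lncrnas: Iterable[str],
    alpha: float = 0.01,
    universe_mode: str = "interaction-union",
    universe_size: int | None = None,
) -> nx.Graph:
    """Functional wrapper around :class:`CeRNANetworkBuilder`."""
    builder = CeRNANetworkBuilder(
        alpha=alpha, universe_mode=universe_mode, universe_size=universe_size
    )
    return builder.fit(interactions, de_mirnas, de_mrnas, de_lncrnas).network_


def extract_subnetwork(network: nx.Graph, focal_lncrna: str) -> nx.Graph:
    """Build the triple lncRNA-miRNA-mRNA sub-network of one lncRNA.

    miRNA nodes are restored from the shared-miRNA annotations stored on
    the ceRNA edges: the result contains the focal lncRNA, each of its
    competing mRNAs, and the miRNAs mediating each competition, wired
    lncRNA-miRNA and miRNA-mRNA.
    """
    if focal_lncrna not in network:
        raise KeyError(f"lncRNA {focal_lncrna!r} is not a node of the network")
    sub = nx.Graph()
    sub.add_node(focal_lncrna, node_class="lncRNA")
    for mrna in network.neighbors(focal_lncrna):
        sub.add_node(mrna, node_class="mRNA")
        for mir in network.edges[focal_lncrna, mrna].get("shared_mirnas", ()):
            sub.add_node(mir, node_class="miRNA")
            sub.add_edge(focal_lncrna, mir)
            sub.add_edge(mir, mrna)
    return sub


def mirna_partner_subnetwork(
    interactions: InteractionSet, focal_lncrna: str
) -> nx.Graph:
    """Star sub-network of a lncRNA and its miRNA partners from raw
    interaction tables (no competing mRNAs required)."""
    partners = interactions.mirna_partners(focal_lncrna)
    if not partners:
        raise KeyError(f"lncRNA {focal_lncrna!r} has no interactions in the table")
    sub = nx.Graph()
    sub.add_node(focal_lncrna, node_class="lncRNA")
    for mir in sorted(partners):
        sub.add_node(mir, node_class="miRNA")
        sub.add_edge(focal_lncrna, mir)
    return sub
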