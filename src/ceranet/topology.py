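"""Centrality analysis and hub nomination on the ceRNA network.

The network is treated as undirected and unweighted.  Three node
centralities are computed:

degree
    incident edge count;
betweenness
    fraction of all-pairs shortest paths passing through the node
    (Brandes accumulation, normalized by (n-1)(n-2)/2);
closeness
    inverse mean geodesic distance, computed within each connected
    component with Wasserman-Faust scaling ``(k-1)/(n-1) * (k-1)/sum d``
    (k = reachable nodes) so scores remain comparable across components.

Hubs are the nodes appearing in the top-k lists of all three measures;
ties are broken lexicographically by node ID so rankings are
deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityReport",
    "centralities",
    "top_k",
    "hub_intersection",
    "degree_distribution",
]

METRICS = ("degree", "betweenness", "closeness")


@dataclass
class CentralityReport:
    """Per-node centrality table (columns: node, node_class, degree,
    betweenness, closeness)."""

    table: pd.DataFrame

    def metric(self, name: str) -> pd.Series:
        if name not in METRICS:
            raise KeyError(f"unknown metric {name!r}; expected one of {METRICS}")
        return self.table.set_index("node")[name]


def centralities(network: nx.Graph) -> CentralityReport:
    """Compute degree, betweenness and closeness for every node."""
    if network.number_of_nodes() < 2:
        raise ValueError("centrality analysis needs a network with >= 2 nodes")
    deg = dict(network.degree())
    btw = nx.betweenness_centrality(network, normalized=True)
    clo = nx.closeness_centrality(network, wf_improved=True)
    nodes = sorted(network.nodes())
    table = pd.DataFrame(
        {
            "node": nodes,
            "node_class": [network.nodes[n].get("node_class", "") for n in nodes],
            "degree": [deg[n] for n in nodes],
            "betweenness": [btw[n] for n in nodes],
            "closeness": [clo[n] for n in nodes],
        }
    )
    return CentralityReport(table)


def top_k(report: CentralityReport, metric: str, k: int = 10) -> list[str]:
    """Top-k node IDs by one metric, descending, lexicographic tie-break."""
    series = report.metric(metric)
    if k > len(series):
        raise ValueError(f"k={k} exceeds node count {len(series)}")
    order = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
    return [node for node, _ in order[:k]]


def hub_intersection(report: CentralityReport, k: int = 10) -> set[str]:
    """Nodes ranked in the top k of all three centrality measures."""
    sets = [set(top_k(report, m, k)) for m in METRICS]
    return sets[0] & sets[1] & sets[2]


def intersect_ranked_lists(lists: dict[str, list[str]]) -> set[str]:
    """Intersection of externally supplied ranked lists (one per metric)."""
    out: set[str] | None = None
    for names in lists.values():
        out = set(names) if out is None else out & set(names)
    return out or set()


def degree_distribution(
    report: CentralityReport, node_class: str | None = None
) -> tuple[pd.DataFrame, dict]:
    """Empirical degree histogram plus a log-log least-squares fit.

    Returns ``(histogram, fit)`` where the histogram has columns
    ``degree`` and ``frequency`` and the fit summary holds the OLS slope
    and R^2 of log(frequency) vs log(degree) over nonzero-degree bins.
    A network whose degree distribution follows a power law has a
    negative slope and only a few high-degree hubs.  Fewer than 5
    distinct degrees: the fit is skipped with a warning.
    """
    table = report.table
    if node_class is not None:
        table = table[table["node_class"] == node_class]
    counts = table["degree"].value_counts().sort_index()
    hist = pd.DataFrame({"degree": counts.index, "frequency": counts.to_numpy()})
    nz = hist[hist["degree"] > 0]
    fit: dict = {"slope": None, "r_squared": None, "fitted": False}
    if len(nz) < 5:
        logger.warning(
            "only %d distinct nonzero degrees; power-law fit skipped", len(nz)
        )
        return hist, fit
    x = np.log(nz["degree"].to_numpy(dtype=float))
    y = np.log(nz["frequency"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    fit.update(slope=float(slope), intercept=float(intercept), r_squared=r2, fitted=True)
    return hist, fit
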