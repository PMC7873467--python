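"""Correlation-gated target selection and over-representation analysis.

A hub lncRNA is functionally annotated through the competing mRNAs it
is positively co-expressed with: for each competing mRNA the Pearson
correlation coefficient (PCC) with the lncRNA is computed over the
expression samples, and mRNAs with PCC > 0 and two-sided p < 0.05 are
kept (positive co-expression is the signature of competition for shared
miRNAs — both transcripts rise and fall together as sponge capacity
shifts).  The retained targets are then tested for over-representation
in user-supplied gene sets (GMT) with the same upper-tail
hypergeometric machinery used for pair selection, plus BH adjustment
across sets.

Correlations default to all samples pooled across conditions; pass an
explicit sample subset to restrict (e.g. lesion samples only).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .network import hypergeom_p

logger = logging.getLogger(__name__)

__all__ = ["pearson_select", "ora"]


def pearson_select(
    lncrna_values: pd.Series,
    mrna_matrix: pd.DataFrame,
    alpha: float = 0.05,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gate competing mRNAs on positive correlation with a lncRNA.

    Parameters
    ----------
    lncrna_values : Series
        The lncRNA's expression indexed by sample ID.
    mrna_matrix : DataFrame
        Competing mRNAs x samples expression.
    alpha : float
        Two-sided p threshold (the test is the exact t transform
        ``t = PCC * sqrt((m-2)/(1-PCC^2))`` with m-2 df).
    samples : sequence of str, optional
        Restrict to these samples; default is every sample shared by
        the lncRNA vector and the matrix.

    Returns a frame with columns pcc, p_value, selected; mRNAs with zero
    variance are excluded with a warning (their PCC is undefined).
    """
    if samples is None:
        samples = [s for s in mrna_matrix.columns if s in lncrna_values.index]
    if len(samples) < 3:
        raise ValueError(f"need >= 3 common samples for correlation, got {len(samples)}")
    x = lncrna_values[list(samples)].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise ValueError("lncRNA expression has zero variance; PCC undefined")
    rows = []
    for mrna, row in mrna_matrix[list(samples)].iterrows():
        y = row.to_numpy(dtype=float)
        if np.std(y) == 0:
            logger.warning("mRNA %s has zero variance; excluded from PCC gating", mrna)
            continue
        pcc, p = stats.pearsonr(x, y)
        rows.append(
            {
                "mrna_id": mrna,
                "pcc": float(pcc),
                "p_value": float(p),
                "selected": bool(p < alpha and pcc > 0),
            }
        )
    return pd.DataFrame(rows, columns=["mrna_id", "pcc", "p_value", "selected"])


def ora(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    For each set the upper-tail probability of the observed overlap is
    computed with universe size T = |universe|, set size t, query size
    N and overlap r, then BH-adjusted across sets.  Sets are first
    intersected with the universe; the query must be a subset of it.
    """
    universe = set(universe)
    query = set(query_genes)
    if not query:
        raise ValueError("query gene list is empty")
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(
            f"{len(stray)} query genes missing from the universe (e.g. {sorted(stray)[:3]})"
        )
    T, N = len(universe), len(query)
    rows = []
    for name in collection.sets:
        members = collection.sets[name] & universe
        if not members:
            continue
        overlap = members & query
        p = hypergeom_p(T, len(members), N, len(overlap)) if overlap else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": len(overlap),
                "set_size": len(members),
                "query_size": N,
                "universe_size": T,
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if len(result):
        result["p_adj"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return result
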