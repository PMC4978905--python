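"""Pleiotropy inference from allelic-effect correlations.

For every pair of traits, QTL whose support intervals overlap on the same
chromosome are evaluated by correlating the two traits' per-population
additive-effect estimates across the populations where both are determined.
A QTL truly affecting both traits produces correlated effect vectors; the
Pearson p-values over all tested QTL pairs are controlled at FDR q by
Benjamini-Hochberg, and significant pairs are aggregated into a trait-level
pleiotropy network (edge weight = mean |r|, sign recorded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_SHARED_POPULATIONS = 3


def find_overlaps(qtl_a: pd.DataFrame, qtl_b: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs of QTL (peak markers) on the same chromosome with intersecting
    closed support intervals (a shared endpoint counts)."""
    pairs = []
    for _, ra in qtl_a.iterrows():
        for _, rb in qtl_b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            if ra["SI_left_cM"] <= rb["SI_right_cM"] and rb["SI_left_cM"] <= ra["SI_right_cM"]:
                pairs.append((ra["peak_marker"], rb["peak_marker"]))
    return pairs


def effect_correlation(effects_a: pd.Series, effects_b: pd.Series
                       ) -> tuple[int, float, float] | None:
    """Pearson r and two-sided p between two per-population effect vectors,
    using only populations with determined effects for both; ``None`` (edge
    untestable) below 3 shared populations or for constant vectors."""
    shared = effects_a.index.intersection(effects_b.index)
    a = effects_a[shared].to_numpy(float)
    b = effects_b[shared].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < MIN_SHARED_POPULATIONS:
        logger.info("effect correlation skipped: only %d shared populations", len(a))
        return None
    if np.std(a) == 0 or np.std(b) == 0:
        logger.info("effect correlation skipped: constant effect vector")
        return None
    res = stats.pearsonr(a, b)
    return len(a), float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values: np.ndarray, q: float = 0.05
               ) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (raw-p cutoff, rejection flags).

    The cutoff is the largest p_(i) with p_(i) <= (i/m) q; flags are True for
    p <= cutoff. With no rejection the cutoff is 0.0 and all flags False.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    m = p.size
    order = np.sort(p)
    thresh = (np.arange(1, m + 1) / m) * q
    passing = order <= thresh
    cutoff = float(order[passing].max()) if passing.any() else 0.0
    return cutoff, p <= cutoff if passing.any() else np.zeros(m, dtype=bool)


@dataclass
class PleiotropyResult:
    edges: pd.DataFrame       # per tested QTL pair
    cutoff: float             # realized BH raw-p cutoff
    graph: nx.Graph           # trait-level network of significant edges


class PleiotropyAnalyzer:
    """Detect pleiotropy between traits from fitted QTL tables.

    Parameters
    ----------
    q : float
        FDR level for Benjamini-Hochberg across all tested QTL pairs.

    Attributes (after ``fit``)
    ----------
    edges_ : tidy table: trait_A, trait_B, chrom, peakA, peakB, n, r, p,
        significant, sign
    cutoff_ : realized raw-p BH cutoff (data dependent)
    graph_ : networkx trait graph; edge weight = mean |r| over significant
        QTL pairs, attribute ``sign`` = sign of the mean r
    """

    def __init__(self, q: float = 0.05):
        self.q = q

    def get_params(self, deep: bool = True) -> dict:
        return {"q": self.q}

    def set_params(self, **params) -> "PleiotropyAnalyzer":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, qtl_tables: dict[str, pd.DataFrame],
            effect_tables: dict[str, pd.DataFrame]) -> "PleiotropyAnalyzer":
        """``qtl_tables[trait]``: QTL rows with chrom/peak_marker/SI columns;
        ``effect_tables[trait]``: tidy effects (peak_marker, population,
        effect; NaN = n.d.)."""
        traits = list(qtl_tables)
        rows = []
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                ta, tb = traits[i], traits[j]
                qa, qb = qtl_tables[ta], qtl_tables[tb]
                if not len(qa) or not len(qb):
                    continue
                for pa, pb in find_overlaps(qa, qb):
                    ea = effect_tables[ta].query("peak_marker == @pa") \
                        .set_index("population")["effect"]
                    eb = effect_tables[tb].query("peak_marker == @pb") \
                        .set_index("population")["effect"]
                    res = effect_correlation(ea, eb)
                    chrom = qa.loc[qa["peak_marker"] == pa, "chrom"].iloc[0]
                    if res is None:
                        rows.append((ta, tb, chrom, pa, pb, np.nan, np.nan,
                                     np.nan, False, ""))
                        continue
                    n, r, p = res
                    rows.append((ta, tb, chrom, pa, pb, n, r, p, False,
                                 "positive" if r >= 0 else "negative"))
        edges = pd.DataFrame(rows, columns=[
            "trait_A", "trait_B", "chrom", "peakA", "peakB",
            "n", "r", "p", "significant", "sign"])
        testable = edges["p"].notna()
        if testable.any():
            cutoff, flags = fdr_adjust(edges.loc[testable, "p"].to_numpy(), self.q)
            edges.loc[testable, "significant"] = flags
        else:
            cutoff = 0.0
        self.edges_ = edges
        self.cutoff_ = cutoff
        self.graph_ = build_network(edges)
        return self


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Trait-level graph of significant pleiotropy: one edge per trait pair,
    weight = mean |r| over its significant QTL pairs, ``sign`` from the mean
    r, ``n_qtl_pairs`` recorded."""
    g = nx.Graph()
    sig = edges[edges["significant"] == True]  # noqa: E712
    for (ta, tb), sub in sig.groupby(["trait_A", "trait_B"]):
        mean_r = sub["r"].mean()
        g.add_edge(ta, tb, weight=float(sub["r"].abs().mean()),
                   sign="positive" if mean_r >= 0 else "negative",
                   n_qtl_pairs=int(len(sub)))
    return g


def network_edge_list(graph: nx.Graph) -> pd.DataFrame:
    rows = [
        (a, b, d["weight"], d["sign"], d["n_qtl_pairs"])
        for a, b, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["trait_A", "trait_B", "weight", "sign",
                                       "n_qtl_pairs"])
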