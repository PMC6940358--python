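"""Expression-vs-cost statistics for secreted proteins.

Highly secretory cells tend to suppress translation of energetically
expensive proteins; this module provides the statistics used to quantify
that: a Spearman correlation between per-protein ATP cost and expression
(ribosome occupancy or mRNA, RPKM) after a low-expression cutoff,
hypergeometric enrichment of protein features among cost-inflated proteins,
and the cumulative ribosomal-load share of the most highly expressed
secreted proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .psim import LOCATIONS, PSIMEntry, SecretomeTable

__all__ = [
    "ExpressionTable",
    "CorrelationResult",
    "filter_low_expression",
    "cost_expression_correlation",
    "feature_enrichment",
    "select_cost_inflated",
    "secretory_load_ranking",
    "DEFAULT_RPKM_CUTOFF",
]

#: Default low-expression cutoff in RPKM.
DEFAULT_RPKM_CUTOFF = 1.0


@dataclass
class ExpressionTable:
    """Per-gene expression levels (RPKM) with a phase/tissue label."""

    levels: pd.Series
    label: str = ""
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.levels = pd.Series(self.levels, dtype=float)
        if (self.levels < 0).any():
            bad = self.levels.index[self.levels < 0].tolist()[:5]
            raise ValueError(f"negative expression for {bad}")
        if self.levels.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression table")

    def __len__(self) -> int:
        return len(self.levels)


def filter_low_expression(table: ExpressionTable,
                          cutoff: float = DEFAULT_RPKM_CUTOFF
                          ) -> ExpressionTable:
    """Drop genes expressed below ``cutoff`` RPKM.

    The returned table records how many entries were removed.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    kept = table.levels[table.levels >= cutoff]
    return ExpressionTable(levels=kept, label=table.label,
                           n_removed=len(table.levels) - len(kept))


@dataclass
class CorrelationResult:
    """Spearman correlation between cost and expression."""

    rho: float
    p_value: float
    n_used: int
    n_filtered: int


def cost_expression_correlation(costs: Mapping[str, float] | pd.Series,
                                expr: ExpressionTable,
                                cutoff: float = DEFAULT_RPKM_CUTOFF
                                ) -> CorrelationResult:
    """Spearman rho (average-rank ties, two-sided p) of ATP cost vs expression.

    Ids are matched exactly between the cost table and the expression table;
    genes below the RPKM cutoff are excluded first.
    """
    costs = pd.Series(costs, dtype=float)
    filtered = filter_low_expression(expr, cutoff)
    shared = costs.index.intersection(filtered.levels.index)
    n_filtered = len(costs) - len(shared)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared ids after filtering; need >= 3"
        )
    rho, p = stats.spearmanr(costs.loc[shared], filtered.levels.loc[shared])
    return CorrelationResult(rho=float(rho), p_value=float(p),
                             n_used=len(shared), n_filtered=n_filtered)


#: Binary features tested for enrichment, as (name, predicate) pairs.
_ENRICHMENT_FEATURES: tuple[tuple[str, object], ...] = (
    ("o_glycans", lambda e: e.o_glycans > 0),
    ("gpi_anchor", lambda e: e.has_gpi_anchor),
    ("transmembrane_domains", lambda e: e.transmembrane_domains > 0),
) + tuple(
    (f"location:{loc}", (lambda loc: lambda e: e.location == loc)(loc))
    for loc in LOCATIONS if loc != "other"
)


def feature_enrichment(population: SecretomeTable,
                       sample_ids: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of features within a sample.

    For each binary feature (O-glycans, GPI anchor, transmembrane domains,
    and each location class) the p-value is P[X >= k] for X hypergeometric
    with population size N, K feature carriers and sample size n. Raw
    p-values are the externally comparable quantity; Benjamini-Hochberg
    adjusted values are reported alongside.
    """
    from statsmodels.stats.multitest import multipletests

    sample_ids = set(sample_ids)
    if not sample_ids:
        raise ValueError("empty sample")
    pop_ids = set(population.ids())
    stray = sample_ids - pop_ids
    if stray:
        raise ValueError(f"sample ids not in population: {sorted(stray)[:5]}")

    N = len(population)
    n = len(sample_ids)
    rows = []
    for name, pred in _ENRICHMENT_FEATURES:
        carriers = [e.protein_id for e in population if pred(e)]
        K = len(carriers)
        k = len(sample_ids.intersection(carriers))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"feature": name, "population": N, "feature_count": K,
                     "sample": n, "sample_feature_count": k,
                     "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("feature")
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def select_cost_inflated(full_costs: Mapping[str, float] | pd.Series,
                         basal_costs: Mapping[str, float] | pd.Series,
                         threshold: float = 0.15) -> set[str]:
    """Ids whose full secretion cost exceeds the basal (translation-only)
    cost by more than ``threshold`` as a fraction: (full - basal)/basal.

    Proteins with zero basal cost are excluded with a warning.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    full = pd.Series(full_costs, dtype=float)
    basal = pd.Series(basal_costs, dtype=float)
    shared = full.index.intersection(basal.index)
    if len(shared) != len(full) or len(shared) != len(basal):
        raise ValueError("full and basal cost tables must share ids")
    zero = basal.index[basal == 0]
    if len(zero):
        warnings.warn(f"{len(zero)} protein(s) with zero basal cost excluded",
                      stacklevel=2)
    ok = basal.index[basal > 0]
    ratio = (full.loc[ok] - basal.loc[ok]) / basal.loc[ok]
    return set(ratio.index[ratio > threshold])


def secretory_load_ranking(expr: ExpressionTable,
                           secretome_ids: Iterable[str],
                           top_k: int = 30) -> tuple[pd.DataFrame, float]:
    """Cumulative expression share of secreted genes, ranked descending.

    Restricts the expression table to the secretome, sorts by expression,
    and returns (ranking table with cumulative fractions of the secretome
    total, share captured by the top ``top_k`` genes).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    ids = expr.levels.index.intersection(pd.Index(set(secretome_ids)))
    if len(ids) == 0:
        raise ValueError("no secretome ids present in expression table")
    levels = expr.levels.loc[ids].sort_values(ascending=False,
                                              kind="mergesort")
    total = float(levels.sum())
    if total <= 0:
        raise ValueError("secretome expression sums to zero")
    cumulative = levels.cumsum() / total
    table = pd.DataFrame({
        "rank": np.arange(1, len(levels) + 1),
        "expression": levels.to_numpy(),
        "cumulative_share": cumulative.to_numpy(),
    }, index=levels.index)
    share = float(cumulative.iloc[min(top_k, len(levels)) - 1])
    return table, share
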