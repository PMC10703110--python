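"""Post-ranking pattern analysis.

Once every configuration is ranked, the interesting managerial question
is *what makes a configuration good*: does piling ambulances into one
atom help or hurt, and which atoms reward extra servers?  Spearman rank
correlations between per-atom server counts (and the dispersion of the
allocation vector) and the ranks answer this; a concentration grouping
summarizes mean rank by how spread-out the allocation is; and a
cross-scenario agreement matrix shows how stable the ranking is across
demand/queue scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from emsrank.enumeration import Configuration


@dataclass
class CorrelationTable:
    """Spearman coefficients/p-values, atoms x scenarios, plus a dispersion row."""

    coefficients: pd.DataFrame
    pvalues: pd.DataFrame

    @property
    def stars(self) -> pd.DataFrame:
        return self.pvalues.map(significance_stars)

    def annotated(self) -> pd.DataFrame:
        """Coefficients with significance stars, as printed tables show them."""
        coef = self.coefficients.round(2).astype(str)
        return coef + self.stars


def significance_stars(p: float) -> str:
    """Three-level star convention: 0.05 (*), 0.01 (**), 0.001 (***)."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    Returns ``(coefficient, two-sided p-value)``; a constant vector has
    no defined rank correlation and yields ``(nan, nan)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _allocation_matrix(
    configs: Sequence[Configuration], server_type: str = "BSU"
) -> np.ndarray:
    return np.array([c.vector(server_type) for c in configs], dtype=float)


def atom_correlations(
    configs: Sequence[Configuration],
    ranks: Mapping[str, Sequence[float]],
    server_type: str = "BSU",
) -> CorrelationTable:
    """Correlate per-atom server counts (and allocation spread) with ranks.

    One column per scenario; rows are the atoms plus a ``std_dev`` row
    correlating the standard deviation of each allocation vector with
    the rank (does concentration help?).  A positive atom coefficient
    means more servers there push a configuration down the ranking
    (rank 1 is best).
    """
    counts = _allocation_matrix(configs, server_type)
    A = counts.shape[1]
    dispersion = counts.std(axis=1)
    index = [f"A{j + 1}" for j in range(A)] + ["std_dev"]
    coefs = pd.DataFrame(index=index, columns=list(ranks), dtype=float)
    pvals = pd.DataFrame(index=index, columns=list(ranks), dtype=float)
    for label, rank in ranks.items():
        rank = np.asarray(rank, float)
        if len(rank) != len(configs):
            raise ValueError(
                f"scenario {label!r}: {len(rank)} ranks for {len(configs)} configs"
            )
        for j in range(A):
            coefs.loc[f"A{j + 1}", label], pvals.loc[f"A{j + 1}", label] = \
                spearman(counts[:, j], rank)
        coefs.loc["std_dev", label], pvals.loc["std_dev", label] = \
            spearman(dispersion, rank)
    return CorrelationTable(coefs, pvals)


def concentration_groups(
    configs: Sequence[Configuration],
    ranks: Sequence[float],
    server_type: str = "BSU",
) -> pd.DataFrame:
    """Mean rank by allocation concentration.

    Configurations are grouped by the number of occupied atoms: the
    first group holds the fully spread allocations, the last the
    single-atom ones.  Reports count, mean/min/max rank and mean
    allocation standard deviation per group.
    """
    counts = _allocation_matrix(configs, server_type)
    ranks = np.asarray(ranks, float)
    if len(ranks) != len(configs):
        raise ValueError("ranks misaligned with configs")
    occupied = (counts > 0).sum(axis=1)
    df = pd.DataFrame(
        {
            "occupied_atoms": occupied,
            "rank": ranks,
            "alloc_std": counts.std(axis=1),
        }
    )
    out = (
        df.groupby("occupied_atoms", sort=True)
        .agg(
            n_configs=("rank", "size"),
            mean_rank=("rank", "mean"),
            min_rank=("rank", "min"),
            max_rank=("rank", "max"),
            mean_alloc_std=("alloc_std", "mean"),
        )
        .sort_index(ascending=False)  # fully spread first
        .reset_index()
    )
    labels = [chr(ord("A") + i) for i in range(len(out))]
    out.insert(0, "group", labels)
    return out


def rank_agreement(ranks: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Cross-scenario Spearman agreement matrix (symmetric, unit diagonal)."""
    labels = list(ranks)
    mat = pd.DataFrame(index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            if a == b:
                mat.loc[a, b] = 1.0
            else:
                mat.loc[a, b], _ = spearman(ranks[a], ranks[b])
    return mat
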