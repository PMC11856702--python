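"""Indicator redundancy analysis: Pearson correlations and greedy pruning.

Phenotype indicators measured on the same fermented product are often close
proxies of one another (pH vs titratable acidity; hardness vs gumminess vs
chewiness). A pair whose |r| exceeds a threshold carries essentially the
same information, so only one representative is kept. The representative is
chosen by an explicit user priority list rather than a graph heuristic,
because which proxy is "canonical" is a domain judgement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .phenotype import StrainPhenotypeTable


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided t-test p-values."""

    indicators: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    n: int

    def r_of(self, a: str, b: str) -> float:
        i, j = self.indicators.index(a), self.indicators.index(b)
        return float(self.r[i, j])

    def p_of(self, a: str, b: str) -> float:
        i, j = self.indicators.index(a), self.indicators.index(b)
        return float(self.p[i, j])


#: Priority order reproducing the published choice of representatives:
#: TTA over pH, hardness over the other texture proxies.
DEFAULT_PRIORITY: tuple[str, ...] = (
    "TTA",
    "Volume",
    "Hardness",
    "Springiness",
    "pH",
    "Cohesiveness",
    "Gumminess",
    "Chewiness",
)


@dataclass(frozen=True)
class PruningPolicy:
    """|r| threshold above which two indicators are declared interchangeable,
    plus the priority order deciding which of a redundant pair survives."""

    threshold: float = 0.6
    priority: tuple[str, ...] = field(default_factory=lambda: DEFAULT_PRIORITY)

    def __post_init__(self) -> None:
        if not 0 < self.threshold:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        object.__setattr__(self, "priority", tuple(self.priority))


def correlation_matrix(table: StrainPhenotypeTable) -> CorrelationResult:
    """Pearson correlation of every indicator pair.

    p-values come from the exact t-transform ``t = r sqrt((n-2)/(1-r^2))``
    with n−2 degrees of freedom (two-sided).
    """
    x = table.values
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 strains for correlation p-values, got {n}")
    sd = x.std(axis=0, ddof=1)
    constant = [ind for j, ind in enumerate(table.indicators) if sd[j] == 0 or not np.isfinite(sd[j])]
    if constant:
        raise ValueError(f"correlation undefined for constant column(s): {constant}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[~np.isfinite(t)] = 0.0  # |r| == 1 exactly
    np.fill_diagonal(p, np.nan)
    return CorrelationResult(indicators=table.indicators, r=r, p=p, n=n)


def prune_redundant(corr: CorrelationResult, policy: PruningPolicy | None = None) -> list[str]:
    """Greedy sweep in priority order; keep an indicator iff its |r| with
    every already-kept indicator is below the threshold.

    Returns kept names in priority order. Any retained pair therefore has
    |r| < threshold.
    """
    if policy is None:
        policy = PruningPolicy()
    missing = [i for i in corr.indicators if i not in policy.priority]
    if missing:
        raise ValueError(f"priority list missing indicator(s): {missing}")
    order = [i for i in policy.priority if i in corr.indicators]
    kept: list[str] = []
    for cand in order:
        ci = corr.indicators.index(cand)
        if all(abs(corr.r[ci, corr.indicators.index(k)]) < policy.threshold for k in kept):
            kept.append(cand)
    return kept


def prune_table(
    table: StrainPhenotypeTable, policy: PruningPolicy | None = None
) -> tuple[StrainPhenotypeTable, CorrelationResult, list[str]]:
    """Convenience: correlate, prune, and subset the table to the kept columns."""
    corr = correlation_matrix(table)
    kept = prune_redundant(corr, policy)
    return table.subset(kept), corr, kept
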