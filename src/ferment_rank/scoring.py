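"""Composite fermentation-ability scoring.

The score is a Cos2-weighted composite selection index built from a
correlation-matrix PCA of standardized phenotype indicators:

1. z-score each direction-corrected indicator column (ddof=1);
2. eigendecompose the Pearson correlation matrix of the columns;
3. retain components with eigenvalue λ > 1 (Kaiser criterion);
4. weight each indicator by Σ_retained λ_i · Cos2[indicator, i], where
   Cos2 is the squared loading (squared variable–component correlation);
5. score each strain as the dot product of its z-row with the weights and
   rank descending.

Because Cos2 values are squares, every coefficient is non-negative and the
ranking is invariant to component sign conventions and to any positive
rescaling of the coefficients.

``CompositeScoreModel`` wraps steps 1–5 behind a statsmodels-style
``fit()`` returning a ``CompositeScoreResults`` object with a ``summary()``
table; the step functions remain available individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phenotype import (
    StandardizedIndicatorTable,
    StrainPhenotypeTable,
    apply_directionality,
)
from .selection import PruningPolicy, prune_table


def standardize(table: StrainPhenotypeTable, ddof: int = 1) -> StandardizedIndicatorTable:
    """Z-score every column: subtract the mean, divide by the sd (sample sd
    by default, matching common R practice)."""
    x = table.values
    if x.shape[0] < 2:
        raise ValueError("need at least 2 strains to standardize")
    if np.isnan(x).any():
        raise ValueError("missing values are not allowed in scoring input")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    constant = [ind for j, ind in enumerate(table.indicators) if sd[j] == 0]
    if constant:
        raise ValueError(f"cannot standardize constant column(s): {constant}")
    return StandardizedIndicatorTable(
        strain_ids=table.strain_ids, indicators=table.indicators, z=(x - mu) / sd
    )


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the indicator correlation matrix.

    ``loadings[j, i]`` is the correlation of variable j with component i
    (eigenvector scaled by sqrt(λ_i)), so ``cos2 = loadings**2`` row-sums to
    1 per variable and column-sums to λ_i per component. Eigenvalues are in
    descending order and sum to the number of indicators.
    """

    indicators: tuple[str, ...]
    eigenvalues: np.ndarray
    loadings: np.ndarray
    cos2: np.ndarray
    explained_fraction: np.ndarray


def pca_correlation(std: StandardizedIndicatorTable) -> PCAResult:
    """Eigendecomposition of the Pearson correlation matrix of the columns.

    Component signs are fixed so each loading column sums to a non-negative
    value; Cos2 weights are squares, so downstream scores do not depend on
    this convention.
    """
    z = std.z
    if np.isnan(z).any() or not np.isfinite(z).all():
        raise ValueError("PCA input contains NaN or infinite values")
    corr = np.corrcoef(z, rowvar=False)
    if np.isnan(corr).any():
        raise ValueError("correlation matrix undefined (constant column?)")
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    signs = np.where(evecs.sum(axis=0) < 0, -1.0, 1.0)
    evecs = evecs * signs
    loadings = evecs * np.sqrt(evals)
    cos2 = loadings**2
    return PCAResult(
        indicators=std.indicators,
        eigenvalues=evals,
        loadings=loadings,
        cos2=cos2,
        explained_fraction=evals / evals.sum(),
    )


def kaiser_select(pca: PCAResult) -> list[int]:
    """Indices of components with eigenvalue strictly greater than 1."""
    return [i for i, lam in enumerate(pca.eigenvalues) if lam > 1.0]


def composite_coefficients(pca: PCAResult, retained: Sequence[int]) -> np.ndarray:
    """Per-indicator weight: Σ over retained components of λ_i · Cos2[j, i].

    All weights are ≥ 0. Raises if no component was retained (fall back to
    the leading component explicitly in that case).
    """
    retained = list(retained)
    if not retained:
        raise ValueError(
            "no components retained; pass retained=[0] to fall back to the leading component"
        )
    lam = pca.eigenvalues[retained]
    return pca.cos2[:, retained] @ lam


@dataclass(frozen=True)
class ScoreTable:
    """Per-strain composite score y, descending rank (1 = best), and an
    optional least-squares positive scale c mapping y onto an external
    reference score column (diagnostic only)."""

    strain_ids: tuple[str, ...]
    coefficients: np.ndarray
    y: np.ndarray
    rank: np.ndarray
    scale: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"strain": list(self.strain_ids), "y": self.y, "rank": self.rank}
        ).set_index("strain")


def _rank_descending(y: np.ndarray, strain_ids: Sequence[str]) -> np.ndarray:
    # ties broken by ascending strain ID for determinism
    order = sorted(range(len(y)), key=lambda i: (-y[i], str(strain_ids[i])))
    rank = np.empty(len(y), dtype=int)
    for pos, i in enumerate(order, start=1):
        rank[i] = pos
    return rank


def score_strains(
    std: StandardizedIndicatorTable,
    coefficients: np.ndarray | Mapping[str, float],
) -> ScoreTable:
    """y_s = Σ_j coeff_j · z[s, j]; rank descending by y.

    If the table carries reference scores, the positive scale c minimizing
    Σ(c·y − reference)² is reported as a diagnostic.
    """
    if isinstance(coefficients, Mapping):
        missing = [i for i in std.indicators if i not in coefficients]
        if missing:
            raise ValueError(f"coefficient(s) missing for indicator(s): {missing}")
        coeffs = np.array([coefficients[i] for i in std.indicators], dtype=float)
    else:
        coeffs = np.asarray(coefficients, dtype=float)
        if coeffs.shape != (len(std.indicators),):
            raise ValueError(
                f"coefficient vector length {coeffs.shape} does not match "
                f"{len(std.indicators)} indicators"
            )
    y = std.z @ coeffs
    scale = None
    if std.reference_scores is not None:
        denom = float(y @ y)
        if denom > 0:
            scale = float(y @ std.reference_scores / denom)
    return ScoreTable(
        strain_ids=std.strain_ids,
        coefficients=coeffs,
        y=y,
        rank=_rank_descending(y, std.strain_ids),
        scale=scale,
    )


@dataclass(frozen=True)
class GroupAssignment:
    """Top-k (strong) and bottom-k (weak) strains by composite score."""

    strong: tuple[str, ...]
    weak: tuple[str, ...]
    k: int

    def __post_init__(self) -> None:
        if set(self.strong) & set(self.weak):
            raise ValueError("strong and weak groups overlap")


def select_extremes(scores: ScoreTable, k: int) -> GroupAssignment:
    """Strong = k best-ranked strains, weak = k worst-ranked."""
    n = len(scores.strain_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the {n} scored strains")
    by_rank = sorted(range(n), key=lambda i: scores.rank[i])
    strong = tuple(scores.strain_ids[i] for i in by_rank[:k])
    weak = tuple(scores.strain_ids[i] for i in by_rank[-k:])
    return GroupAssignment(strong=strong, weak=weak, k=k)


class CompositeScoreModel:
    """Composite selection-index model over a strain × indicator table.

    Parameters
    ----------
    table
        Raw phenotype table. Direction correction (sign-flipping
        lower-is-better indicators) is applied at fit time from the table's
        own direction flags.
    prune
        Optional redundancy-pruning policy applied before scoring; by
        default all columns of ``table`` are used as-is.
    ddof
        Delta degrees of freedom for the standardization sd.
    """

    def __init__(
        self,
        table: StrainPhenotypeTable,
        prune: PruningPolicy | None = None,
        ddof: int = 1,
    ) -> None:
        self.table = table
        self.prune = prune
        self.ddof = ddof

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        direction: Mapping[str, int] | None = None,
        **kwargs,
    ) -> "CompositeScoreModel":
        """Build from a DataFrame whose index holds strain IDs."""
        from .phenotype import DEFAULT_DIRECTIONS

        direction = dict(DEFAULT_DIRECTIONS if direction is None else direction)
        table = StrainPhenotypeTable(
            strain_ids=tuple(str(s) for s in df.index),
            indicators=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
            direction={k: v for k, v in direction.items() if k in df.columns},
        )
        return cls(table, **kwargs)

    @classmethod
    def from_standardized(cls, std: StandardizedIndicatorTable, **kwargs) -> "CompositeScoreModel":
        """Build from an already z-scored table (e.g. the packaged fixture)."""
        model = cls.__new__(cls)
        model.table = None
        model.prune = None
        model.ddof = kwargs.get("ddof", 1)
        model._std = std
        return model

    def fit(self, k_extremes: int | None = None) -> "CompositeScoreResults":
        """Run directionality → (optional pruning) → standardize → PCA →
        Kaiser → Cos2 weights → scores → ranks."""
        kept = None
        corr = None
        if getattr(self, "_std", None) is not None:
            std = self._std
        else:
            corrected = apply_directionality(self.table)
            if self.prune is not None:
                corrected, corr, kept = prune_table(corrected, self.prune)
            std = standardize(corrected, ddof=self.ddof)
        pca = pca_correlation(std)
        retained = kaiser_select(pca)
        effective = retained if retained else [0]
        coeffs = composite_coefficients(pca, effective)
        scores = score_strains(std, coeffs)
        groups = select_extremes(scores, k_extremes) if k_extremes else None
        return CompositeScoreResults(
            model=self,
            std=std,
            correlation=corr,
            kept_indicators=kept,
            pca=pca,
            retained=retained,
            coefficients=coeffs,
            scores=scores,
            groups=groups,
        )


@dataclass(frozen=True)
class CompositeScoreResults:
    """Fit artefacts of a :class:`CompositeScoreModel`."""

    model: CompositeScoreModel
    std: StandardizedIndicatorTable
    correlation: object | None
    kept_indicators: list[str] | None
    pca: PCAResult
    retained: list[int]
    coefficients: np.ndarray
    scores: ScoreTable
    groups: GroupAssignment | None = None

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.pca.eigenvalues

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.pca.explained_fraction

    def select_extremes(self, k: int) -> GroupAssignment:
        return select_extremes(self.scores, k)

    def summary(self) -> str:
        lines = ["Composite fermentation-ability score", "=" * 40]
        if self.kept_indicators is not None:
            lines.append(f"Indicators retained after pruning: {', '.join(self.kept_indicators)}")
        lines.append("Eigenvalues (correlation PCA): " + ", ".join(f"{v:.4f}" for v in self.eigenvalues))
        lines.append(
            "Retained components (Kaiser, lambda > 1): "
            + (", ".join(f"PC{i + 1}" for i in self.retained) if self.retained else "none (fell back to PC1)")
        )
        lines.append(
            f"Variance explained by retained components: "
            f"{100 * self.explained_fraction[self.retained or [0]].sum():.2f}%"
        )
        lines.append("Coefficients:")
        for ind, c in zip(self.std.indicators, self.coefficients):
            lines.append(f"  {ind:<14s} {c:.4f}")
        if self.scores.scale is not None:
            lines.append(f"Scale vs reference scores (diagnostic c): {self.scores.scale:.4f}")
        df = self.scores.to_frame().sort_values("rank")
        lines.append("")
        lines.append(df.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Optional bar chart of ranked scores (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        df = self.scores.to_frame().sort_values("rank")
        ax.bar(df.index, df["y"])
        ax.set_ylabel("composite score y")
        ax.set_xlabel("strain")
        ax.tick_params(axis="x", rotation=90)
        return ax
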