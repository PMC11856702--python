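"""Strain × phenotype-indicator tables and directionality correction.

A phenotype table holds one row per yeast strain and one column per quality
indicator measured on the fermented product (total titratable acidity,
specific volume, texture-profile measures ...). Indicators differ in
direction: a large specific volume is good, a large hardness is bad. Before
any composite scoring, lower-is-better columns are multiplied by −1 so that
"larger = stronger fermentation ability" holds for every column.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HIGHER_IS_BETTER = 1
LOWER_IS_BETTER = -1

#: Only hardness is flipped by default; the other texture indicators that
#: share its direction (gumminess, chewiness) are usually pruned as redundant
#: before scoring, so flipping them is left to the caller's DirectionMap.
DEFAULT_DIRECTIONS: dict[str, int] = {"Hardness": LOWER_IS_BETTER}


class PhenotypeError(ValueError):
    """Raised for malformed phenotype tables or direction maps."""


def _validate_direction_map(dirs: Mapping[str, int]) -> None:
    bad = {k: v for k, v in dirs.items() if v not in (HIGHER_IS_BETTER, LOWER_IS_BETTER)}
    if bad:
        raise PhenotypeError(f"direction multipliers must be +1 or -1, got {bad}")


@dataclass(frozen=True)
class StrainPhenotypeTable:
    """Raw strain × indicator measurements with per-indicator direction flags.

    Parameters
    ----------
    strain_ids
        Unique strain labels, one per row.
    indicators
        Indicator names, one per column.
    values
        Real matrix of shape ``(n_strains, n_indicators)``.
    direction
        Per-indicator multiplier: +1 (higher is better) or −1 (lower is
        better). Indicators absent from the mapping default to +1.
    """

    strain_ids: tuple[str, ...]
    indicators: tuple[str, ...]
    values: np.ndarray
    direction: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_ids", tuple(str(s) for s in self.strain_ids))
        object.__setattr__(self, "indicators", tuple(str(i) for i in self.indicators))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dupes = sorted({s for s in self.strain_ids if self.strain_ids.count(s) > 1})
            raise PhenotypeError(f"duplicate strain labels: {dupes}")
        if values.shape != (len(self.strain_ids), len(self.indicators)):
            raise PhenotypeError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.indicators)} indicators"
            )
        _validate_direction_map(self.direction)
        if values.size and np.isnan(values).all(axis=0).any():
            empty = [ind for j, ind in enumerate(self.indicators) if np.isnan(values[:, j]).all()]
            raise PhenotypeError(f"indicator column(s) entirely missing: {empty}")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_indicators(self) -> int:
        return len(self.indicators)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.strain_ids), columns=list(self.indicators))

    def subset(self, indicators: Sequence[str]) -> "StrainPhenotypeTable":
        """Column subset preserving strain order and direction flags."""
        missing = [i for i in indicators if i not in self.indicators]
        if missing:
            raise PhenotypeError(f"unknown indicator(s): {missing}")
        idx = [self.indicators.index(i) for i in indicators]
        return StrainPhenotypeTable(
            strain_ids=self.strain_ids,
            indicators=tuple(indicators),
            values=self.values[:, idx],
            direction={k: v for k, v in self.direction.items() if k in indicators},
        )


@dataclass(frozen=True)
class StandardizedIndicatorTable:
    """Z-scored, direction-corrected indicator matrix.

    ``reference_scores`` carries an externally supplied per-strain score
    column (kept as metadata, never recomputed) when the table was loaded
    from the packaged fixture.
    """

    strain_ids: tuple[str, ...]
    indicators: tuple[str, ...]
    z: np.ndarray
    reference_scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "strain_ids", tuple(str(s) for s in self.strain_ids))
        object.__setattr__(self, "indicators", tuple(str(i) for i in self.indicators))
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if z.shape != (len(self.strain_ids), len(self.indicators)):
            raise PhenotypeError("z matrix shape inconsistent with labels")
        if self.reference_scores is not None:
            ref = np.asarray(self.reference_scores, dtype=float)
            if ref.shape != (len(self.strain_ids),):
                raise PhenotypeError("reference_scores length inconsistent with strains")
            object.__setattr__(self, "reference_scores", ref)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.z, index=list(self.strain_ids), columns=list(self.indicators))
        if self.reference_scores is not None:
            df["Score"] = self.reference_scores
        return df


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_phenotype_table(
    path: str | Path,
    direction: Mapping[str, int] | None = None,
    delimiter: str | None = None,
    allow_missing: bool = False,
) -> StrainPhenotypeTable:
    """Read a delimited strain × indicator table.

    The first column holds strain labels; the header row holds indicator
    names. Non-numeric cells are hard errors naming the offending row and
    column; missing (empty) cells are errors unless ``allow_missing``.
    """
    path = Path(path)
    text = path.read_text()
    if delimiter is None:
        delimiter = _sniff_delimiter(text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=delimiter, dtype=str)
    if df.shape[1] < 2:
        raise PhenotypeError(f"{path}: need a strain column plus at least one indicator")
    strain_ids = [s.strip() for s in df.iloc[:, 0]]
    if len(set(strain_ids)) != len(strain_ids):
        dupes = sorted({s for s in strain_ids if strain_ids.count(s) > 1})
        raise PhenotypeError(f"{path}: duplicate strain labels {dupes}")
    indicators = [c.strip() for c in df.columns[1:]]
    values = np.empty((len(strain_ids), len(indicators)))
    for j, col in enumerate(df.columns[1:]):
        for i, cell in enumerate(df[col]):
            cell = (cell or "").strip() if isinstance(cell, str) else cell
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
                if not allow_missing:
                    raise PhenotypeError(
                        f"{path}: missing value at strain {strain_ids[i]!r}, "
                        f"indicator {indicators[j]!r}"
                    )
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise PhenotypeError(
                    f"{path}: non-numeric value {cell!r} at strain "
                    f"{strain_ids[i]!r}, indicator {indicators[j]!r}"
                ) from None
    direction = dict(direction) if direction is not None else dict(DEFAULT_DIRECTIONS)
    direction = {k: v for k, v in direction.items() if k in indicators}
    return StrainPhenotypeTable(tuple(strain_ids), tuple(indicators), values, direction)


def write_phenotype_table(table: StrainPhenotypeTable, path: str | Path, delimiter: str = ",") -> None:
    df = table.to_frame()
    df.index.name = "strain"
    df.to_csv(path, sep=delimiter, float_format="%.17g")


def apply_directionality(
    table: StrainPhenotypeTable, dirs: Mapping[str, int] | None = None
) -> StrainPhenotypeTable:
    """Multiply lower-is-better columns by −1 so all indicators point the same way.

    After correction every direction flag is reset to higher-is-better, so a
    second application is the identity.
    """
    if dirs is None:
        dirs = dict(table.direction)
        for ind in table.indicators:
            dirs.setdefault(ind, HIGHER_IS_BETTER)
    _validate_direction_map(dirs)
    missing = [i for i in table.indicators if i not in dirs]
    if missing:
        raise PhenotypeError(f"direction map missing indicator(s): {missing}")
    mult = np.array([dirs[i] for i in table.indicators], dtype=float)
    return replace(
        table,
        values=table.values * mult,
        direction={i: HIGHER_IS_BETTER for i in table.indicators},
    )


_FIXTURE = "reference_scores.csv"


def load_reference_scores() -> StandardizedIndicatorTable:
    """Load the packaged 36-strain standardized indicator matrix and scores.

    The fixture holds the four direction-corrected, z-scored evaluation
    indicators (TTA, specific volume, hardness, springiness) for 36
    *S. cerevisiae* isolates together with each strain's published composite
    fermentation-ability score. Scores are reference metadata; they are
    never recomputed here.
    """
    with resources.files("ferment_rank.data").joinpath(_FIXTURE).open() as fh:
        df = pd.read_csv(fh, dtype={"strain": str})
    indicators = ("TTA", "Volume", "Hardness", "Springiness")
    return StandardizedIndicatorTable(
        strain_ids=tuple(df["strain"]),
        indicators=indicators,
        z=df[list(indicators)].to_numpy(dtype=float),
        reference_scores=df["Score"].to_numpy(dtype=float),
    )
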