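"""Meristem-average to whorl-resolved concentration transformation.

Microarray intensities are whole-meristem averages, but the model needs
whorl-specific protein concentrations.  The five-step reconstruction:

1. scale intensities uniformly so the grand mean is the typical
   transcription-factor concentration (1e3 nM);
2. a gene that is off in a whorl sits at 1% of an expressed gene's level;
3. the on/off pattern per gene/whorl/day comes from the developmental
   expression table (uniform expression before day 2);
4. whorl volumes (sepal 1.1e4, petal 2.7e4, stamen 2.9e4, carpel 1.1e4
   um^3) are treated as constant over days 2-5;
5. the volume-weighted mass balance
       c_avg_i(t) = sum_w V_w c_i^w(t) / sum_w V_w
   with c_i^w = e_i^w * alpha_i(t) fixes the scaling factor
       alpha_i(t) = c_avg_i(t) * sum_w V_w / sum_w e_i^w V_w,
   which reproduces the meristem average exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .network import GENES

__all__ = [
    "WHORLS",
    "ExpressionPattern",
    "WhorlGeometry",
    "MeristemAverageSeries",
    "ConcentrationGrid",
    "TransformRecord",
    "scale_intensities",
    "expression_fraction",
    "whorl_concentrations",
]

WHORLS: tuple[int, ...] = (1, 2, 3, 4)

#: Typical transcription-factor concentration used as the scaling target (nM).
ON_LEVEL = 1.0e3

#: Off-state expression as a fraction of an expressed gene's level.
OFF_FRACTION = 0.01

#: Expressed genes per whorl for days 2..5 (SEP is on everywhere, always).
_PATTERN_DAYS_2_5: dict[int, dict[int, tuple[str, ...]]] = {
    1: {d: ("AP1",) for d in (2, 3, 4, 5)},
    2: {d: ("AP1", "AP3", "PI") for d in (2, 3, 4, 5)},
    3: {d: ("AP3", "PI", "AG") for d in (2, 3, 4, 5)},
    4: {2: ("AG",), 3: ("AG",), 4: ("AG", "SHP"), 5: ("AG", "SHP")},
}


@dataclass(frozen=True)
class ExpressionPattern:
    """On/off truth table per (gene, whorl, day).

    Days 0-1 precede organ primordium initiation: expression is uniform
    over the meristem, encoded as "on" in every whorl, so the whorl values
    all equal the meristem average there.
    """

    on_off: Mapping[tuple[str, int, int], bool] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ExpressionPattern":
        table: dict[tuple[str, int, int], bool] = {}
        for w in WHORLS:
            for day in range(0, 6):
                for g in GENES:
                    if day < 2:
                        on = True
                    else:
                        on = g == "SEP" or g in _PATTERN_DAYS_2_5[w][day]
                    table[(g, w, day)] = on
        return cls(on_off=table)

    def is_on(self, gene: str, whorl: int, day: int) -> bool:
        try:
            return self.on_off[(gene, whorl, day)]
        except KeyError:
            raise KeyError(f"no pattern entry for ({gene}, whorl {whorl}, day {day})") from None


@dataclass(frozen=True)
class WhorlGeometry:
    """Whorl volumes in um^3 (sepal, petal, stamen, carpel primordia)."""

    volumes: tuple[float, float, float, float] = (1.1e4, 2.7e4, 2.9e4, 1.1e4)

    def __post_init__(self) -> None:
        if len(self.volumes) != 4 or any(v <= 0 for v in self.volumes):
            raise ValueError("need 4 strictly positive whorl volumes")

    @property
    def weights(self) -> np.ndarray:
        v = np.asarray(self.volumes, dtype=float)
        return v / v.sum()


@dataclass
class MeristemAverageSeries:
    """Meristem-averaged concentration per (gene, day), nM; shape (6, D)."""

    values: np.ndarray
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(GENES), len(self.days)):
            raise ValueError("values must have shape (6, n_days)")

    def value(self, gene: str, day: int) -> float:
        return float(self.values[GENES.index(gene), self.days.index(day)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "day": d, "concentration_nM": self.values[i, j]}
            for i, g in enumerate(GENES)
            for j, d in enumerate(self.days)
        ]
        return pd.DataFrame(rows)


@dataclass
class ConcentrationGrid:
    """Whorl-resolved concentrations, shape (6 genes, 4 whorls, D days)."""

    values: np.ndarray
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(GENES), len(WHORLS), len(self.days)):
            raise ValueError("values must have shape (6, 4, n_days)")

    def value(self, gene: str, whorl: int, day: int) -> float:
        return float(
            self.values[GENES.index(gene), whorl - 1, self.days.index(day)]
        )

    def whorl_matrix(self, whorl: int) -> np.ndarray:
        """(D, 6) matrix of concentrations in one whorl, days by genes."""
        return self.values[:, whorl - 1, :].T

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "whorl": w, "day": d,
             "concentration_nM": self.values[i, w - 1, j]}
            for i, g in enumerate(GENES)
            for w in WHORLS
            for j, d in enumerate(self.days)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConcentrationGrid":
        days = tuple(sorted(frame["day"].unique()))
        values = np.empty((len(GENES), len(WHORLS), len(days)))
        values[:] = np.nan
        for _, row in frame.iterrows():
            values[GENES.index(row["gene"]), int(row["whorl"]) - 1,
                   days.index(row["day"])] = row["concentration_nM"]
        if np.isnan(values).any():
            raise ValueError("incomplete (gene, whorl, day) grid")
        return cls(values=values, days=days)


@dataclass
class TransformRecord:
    """Result of the whorl reconstruction: alpha factors and whorl grid."""

    alpha: np.ndarray  # (6, D) scaling factor per gene/day, nM
    grid: ConcentrationGrid
    pattern: ExpressionPattern
    geometry: WhorlGeometry

    def sidecar(self) -> dict:
        """JSON-ready record of the alpha values and conventions used."""
        return {
            "alpha_nM": {
                g: {str(d): float(self.alpha[i, j]) for j, d in enumerate(self.grid.days)}
                for i, g in enumerate(GENES)
            },
            "whorl_volumes_um3": list(self.geometry.volumes),
            "off_fraction": OFF_FRACTION,
            "scaling": "single joint factor over all genes and days",
        }


def scale_intensities(
    raw: Mapping[tuple[str, int], float] | pd.DataFrame,
    target_mean: float = ON_LEVEL,
) -> MeristemAverageSeries:
    """Scale raw intensities to concentrations with grand mean ``target_mean``.

    A single multiplicative factor is applied jointly over all genes and
    days (linearity of intensity vs concentration is assumed), so the
    output is invariant to a uniform rescaling of the input.
    """
    if isinstance(raw, pd.DataFrame):
        raw = {
            (row["gene"], int(row["day"])): float(row["intensity"])
            for _, row in raw.iterrows()
        }
    days = tuple(sorted({d for (_, d) in raw}))
    values = np.empty((len(GENES), len(days)))
    for i, g in enumerate(GENES):
        for j, d in enumerate(days):
            try:
                v = raw[(g, d)]
            except KeyError:
                raise ValueError(f"missing intensity for ({g}, day {d})") from None
            if not v > 0:
                raise ValueError(f"non-positive intensity for ({g}, day {d}): {v}")
            values[i, j] = v
    values *= target_mean / values.mean()
    return MeristemAverageSeries(values=values, days=days)


def expression_fraction(
    gene: str, whorl: int, day: int, pattern: ExpressionPattern | None = None
) -> float:
    """Expression fraction e_i^w: 1.0 when on, 0.01 when off."""
    if whorl not in WHORLS:
        raise KeyError(f"unknown whorl {whorl}")
    if gene not in GENES:
        raise KeyError(f"unknown gene {gene!r}")
    pattern = pattern or ExpressionPattern.default()
    return 1.0 if pattern.is_on(gene, whorl, day) else OFF_FRACTION


def whorl_concentrations(
    series: MeristemAverageSeries,
    pattern: ExpressionPattern | None = None,
    geometry: WhorlGeometry | None = None,
) -> TransformRecord:
    """Reconstruct whorl-specific concentrations from meristem averages.

    alpha_i(t) = c_avg_i(t) * sum_w V_w / sum_w e_i^w V_w and
    c_i^w = e_i^w * alpha_i(t); the volume-weighted whorl mean then equals
    the input average exactly (mass balance by construction).
    """
    pattern = pattern or ExpressionPattern.default()
    geometry = geometry or WhorlGeometry()
    V = np.asarray(geometry.volumes, dtype=float)
    alpha = np.empty((len(GENES), len(series.days)))
    values = np.empty((len(GENES), len(WHORLS), len(series.days)))
    for i, g in enumerate(GENES):
        for j, d in enumerate(series.days):
            e = np.array([expression_fraction(g, w, d, pattern) for w in WHORLS])
            alpha[i, j] = series.values[i, j] * V.sum() / float(e @ V)
            values[i, :, j] = e * alpha[i, j]
    grid = ConcentrationGrid(values=values, days=series.days)
    return TransformRecord(alpha=alpha, grid=grid, pattern=pattern, geometry=geometry)
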