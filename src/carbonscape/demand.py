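"""Per-class land-demand projection for the simulation horizon.

The baseline (natural-evolution) demand comes from a Markov chain fitted
to an observed transition cross-tabulation; an ordinary least-squares
trend over three or more dates is computed alongside as a cross-check,
and the two can be blended.  Every projection path conserves total mapped
area.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from carbonscape.raster_core import AreaTable, CLASS_CODES, TransitionCrosstab


@dataclass
class MarkovModel:
    """Row-stochastic transition-probability matrix over one interval."""

    P: np.ndarray
    codes: tuple[int, ...]
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        k = len(self.codes)
        if self.P.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        if ((self.P < -1e-12) | (self.P > 1 + 1e-12)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")


@dataclass
class DemandVector:
    """Target per-class areas (ha) at the horizon year."""

    areas_ha: pd.Series
    year: float | None = None

    def __post_init__(self) -> None:
        if (self.areas_ha < 0).any():
            raise ValueError("demand areas must be non-negative")

    def total(self) -> float:
        return float(self.areas_ha.sum())

    def write(self, path: str | Path) -> None:
        df = self.areas_ha.to_frame("area_ha")
        df.index.name = "class_code"
        df.to_csv(path)

    @classmethod
    def read(cls, path: str | Path, year: float | None = None) -> "DemandVector":
        df = pd.read_csv(path, index_col=0)
        return cls(df["area_ha"], year=year)


def fit_markov(xtab: TransitionCrosstab, interval_years: float = 1.0) -> MarkovModel:
    """Row-normalize a transition crosstab into a Markov chain.

    Empty from-classes get an identity row (they persist trivially).
    """
    if xtab.total() <= 0:
        raise ValueError("cannot fit a Markov chain to an all-zero crosstab")
    M = xtab.matrix.copy()
    rowsum = M.sum(axis=1)
    P = np.eye(len(xtab.codes))
    nz = rowsum > 0
    P[nz] = M[nz] / rowsum[nz, None]
    return MarkovModel(P=P, codes=xtab.codes, interval_years=interval_years)


def project_markov(
    model: MarkovModel, areas: AreaTable, n_intervals: int
) -> DemandVector:
    """Project areas forward: a · Pⁿ.  Total area is conserved."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    a = areas.ha().reindex(list(model.codes), fill_value=0.0).to_numpy()
    Pn = np.linalg.matrix_power(model.P, n_intervals)
    out = a @ Pn
    return DemandVector(pd.Series(out, index=list(model.codes)))


def project_linear(
    areas_by_date: AreaTable, years: list[float], target_year: float
) -> DemandVector:
    """OLS line per class over >= 3 dated area vectors, evaluated at target.

    Negative extrapolations are clamped to zero and the shortfall is
    redistributed proportionally over the positive classes so the total
    mapped area is conserved.
    """
    cols = list(areas_by_date.table.columns)
    if len(cols) < 3 or len(years) != len(cols):
        raise ValueError("need at least 3 dated columns with matching years")
    t = np.asarray(years, dtype=float)
    Y = areas_by_date.table.to_numpy()  # (K, T)
    # per-class OLS: slope & intercept via polyfit on the shared time axis
    coeffs = np.polyfit(t, Y.T, deg=1)  # (2, K)
    pred = coeffs[0] * target_year + coeffs[1]
    total = Y[:, -1].sum()  # conserve the most recent mapped total
    pred = _clamp_redistribute(pred, total)
    return DemandVector(pd.Series(pred, index=areas_by_date.table.index),
                        year=target_year)


def _clamp_redistribute(values: np.ndarray, total: float) -> np.ndarray:
    """Clamp negatives to 0 and rescale positives to hit ``total``."""
    v = np.clip(values, 0.0, None)
    s = v.sum()
    if s <= 0:
        raise ValueError("all projected areas non-positive")
    return v * (total / s)


def blend_demand(
    markov: DemandVector, linear: DemandVector, weight_markov: float = 1.0
) -> DemandVector:
    """Convex blend of the Markov and linear projections (default all-Markov)."""
    if not 0.0 <= weight_markov <= 1.0:
        raise ValueError("blend weight must be in [0, 1]")
    idx = markov.areas_ha.index
    mixed = (weight_markov * markov.areas_ha
             + (1.0 - weight_markov) * linear.areas_ha.reindex(idx, fill_value=0.0))
    return DemandVector(mixed, year=markov.year or linear.year)


def demand_to_cells(demand: DemandVector, cell_area_ha: float, total_cells: int) -> dict[int, int]:
    """Round a demand vector to whole cells summing exactly to total_cells.

    Largest-remainder rounding keeps every class within one cell of its
    real-valued target.
    """
    raw = demand.areas_ha / cell_area_ha
    scale = total_cells / raw.sum() if raw.sum() > 0 else 1.0
    raw = raw * scale
    base = np.floor(raw.to_numpy()).astype(int)
    short = total_cells - base.sum()
    rema = raw.to_numpy() - base
    order = np.argsort(-rema)
    for i in range(int(short)):
        base[order[i % len(base)]] += 1
    return {c: int(n) for c, n in zip(raw.index, base)}
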