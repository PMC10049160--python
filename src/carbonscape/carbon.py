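"""Ecosystem carbon-storage accounting and gray forecasting of densities.

Carbon storage follows the InVEST carbon-module bookkeeping: each land-use
class carries four pool densities (aboveground biomass, belowground
biomass, soil, dead organic matter), all in Mg·ha⁻¹, and the storage of a
parcel is its area times the summed pool density of its class.  Open water
stores nothing (all four pools zero).  Totals are reported in Tg
(1 Tg = 10⁶ Mg); transition flows use 10⁴ Mg.

Future densities come from a GM(1,1) gray model: a first-order accumulated
generating operation turns the observed series into a near-exponential
one, least squares on background values yields the development coefficient
``a`` and gray action quantity ``b``, and the restored (differenced)
forecast extrapolates the series.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from carbonscape.raster_core import (
    AreaTable,
    DEFAULT_LEGEND,
    LandUseGrid,
    TransitionCrosstab,
    class_areas,
)

POOLS = ("above", "below", "soil", "dead")

MG_PER_TG = 1e6


@dataclass
class CarbonDensityTable:
    """Per-class four-pool carbon densities (Mg·ha⁻¹) for one year.

    ``table`` is indexed by class code with columns ``above``, ``below``,
    ``soil``, ``dead``.  The waters class must be all zero — open water is
    treated as carrying no carbon pools.
    """

    table: pd.DataFrame
    year: str = ""
    waters_code: int = 5

    def __post_init__(self) -> None:
        missing = [p for p in POOLS if p not in self.table.columns]
        if missing:
            raise ValueError(f"density table missing pool columns {missing}")
        if (self.table[list(POOLS)] < 0).any().any():
            raise ValueError("carbon densities must be non-negative")
        if self.waters_code in self.table.index:
            if self.table.loc[self.waters_code, list(POOLS)].abs().sum() > 0:
                raise ValueError("waters row must be all zeros")

    @classmethod
    def from_records(
        cls, rows: Mapping[int, tuple[float, float, float, float]], year: str = ""
    ) -> "CarbonDensityTable":
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(POOLS)).sort_index()
        return cls(df, year=year)

    @classmethod
    def read(cls, path: str | Path, year: str = "") -> "CarbonDensityTable":
        df = pd.read_csv(path, index_col=0)
        return cls(df[[c for c in df.columns if c in POOLS]], year=year)

    def write(self, path: str | Path, legend: Mapping[int, str] = DEFAULT_LEGEND) -> None:
        df = self.table.copy()
        df.insert(0, "class_name", [legend.get(c, str(c)) for c in df.index])
        df.index.name = "class_code"
        df.to_csv(path)

    def total_density(self) -> pd.Series:
        """Summed four-pool density per class (Mg·ha⁻¹)."""
        return self.table[list(POOLS)].sum(axis=1)


@dataclass
class CarbonResult:
    """Carbon storage per class and in total (Tg), optional per-cell map (Mg)."""

    per_class_tg: pd.Series
    label: str = ""
    cell_map_mg: np.ndarray | None = None

    @property
    def total_tg(self) -> float:
        return float(self.per_class_tg.sum())

    def to_frame(self, legend: Mapping[int, str] = DEFAULT_LEGEND) -> pd.DataFrame:
        out = self.per_class_tg.rename(index=lambda c: legend.get(c, str(c))).to_frame("CS_Tg")
        out.loc["total"] = self.total_tg
        return out


def compute_cs(
    grid_or_areas: LandUseGrid | AreaTable,
    density: CarbonDensityTable,
    label: str = "",
    cell_map: bool = False,
) -> CarbonResult:
    """Carbon storage from a land-use map or an area table.

    Per class: area (ha) × summed pool density (Mg·ha⁻¹), reported in Tg.
    Classes absent from the density table raise unless absent from the map
    too; the waters class contributes zero by construction.
    """
    if isinstance(grid_or_areas, LandUseGrid):
        areas = class_areas(grid_or_areas)
    else:
        areas = grid_or_areas
    area_ha = areas.ha()
    dens = density.total_density()
    present = area_ha[area_ha > 0].index
    missing = [c for c in present if c not in dens.index]
    if missing:
        raise ValueError(f"density table lacks classes {missing} present in the map")
    dens = dens.reindex(area_ha.index, fill_value=0.0)
    per_class = area_ha * dens / MG_PER_TG
    cmap = None
    if cell_map and isinstance(grid_or_areas, LandUseGrid):
        grid = grid_or_areas
        lut = np.zeros(max(list(grid.legend) + [0]) + 1)
        for c in dens.index:
            if 0 <= c < lut.size:
                lut[c] = dens[c]
        cmap = np.where(grid.valid_mask, lut[np.clip(grid.codes, 0, lut.size - 1)], np.nan)
        cmap = cmap * grid.cell_area_ha  # Mg per cell
    return CarbonResult(per_class_tg=per_class, label=label, cell_map_mg=cmap)


def cs_change(result_a: CarbonResult, result_b: CarbonResult) -> pd.Series:
    """Elementwise carbon-storage change b − a (Tg); index includes 'total'."""
    if not result_a.per_class_tg.index.equals(result_b.per_class_tg.index):
        raise ValueError("carbon results cover different class sets")
    delta = result_b.per_class_tg - result_a.per_class_tg
    delta.loc["total"] = delta.sum()
    return delta


def transition_cs_flows(
    xtab: TransitionCrosstab,
    density_from: CarbonDensityTable,
    density_to: CarbonDensityTable,
    from_at_start: bool = False,
) -> pd.DataFrame:
    """Carbon-storage change attributable to each land transition (10⁴ Mg).

    Entry (i, j) is the transition area i→j times the density difference
    of the destination and origin classes.  By default both classes are
    priced at the horizon-year table (``density_to``), isolating the
    land-change effect; with ``from_at_start`` the origin class uses
    ``density_from`` instead.  Diagonal (persistence) entries are zero;
    positive values are carbon gains.
    """
    d_to = density_to.total_density()
    d_from = density_from.total_density() if from_at_start else d_to
    codes = list(xtab.codes)
    k = len(codes)
    flows = np.zeros((k, k))
    for i, ci in enumerate(codes):
        for j, cj in enumerate(codes):
            if i == j:
                continue
            per_ha = d_to.get(cj, 0.0) - d_from.get(ci, 0.0)
            flows[i, j] = xtab.matrix[i, j] * per_ha / 1e4  # Mg -> 10^4 Mg
    return pd.DataFrame(flows, index=codes, columns=codes)


# ---------------------------------------------------------------------------
# GM(1,1) gray model


@dataclass
class GM11Model:
    """First-order one-variable gray model.

    ``a`` is the development coefficient, ``b`` the gray action quantity;
    the model is defined for strictly positive series of length >= 4.
    """

    a: float
    b: float
    x1: float
    n: int


def gm11_fit(series: np.ndarray | list[float]) -> GM11Model:
    """Fit GM(1,1) by the standard accumulated-generating construction.

    The 1-AGO series x¹ accumulates the input x⁰; background values
    z¹(k) = (x¹(k) + x¹(k−1))/2; least squares on
    x⁰(k) = −a·z¹(k) + b yields (a, b).
    """
    x0 = np.asarray(series, dtype=float)
    if x0.ndim != 1 or x0.size < 4:
        raise ValueError("GM(1,1) needs a 1-D series of length >= 4")
    if (x0 <= 0).any():
        raise ValueError("GM(1,1) requires strictly positive observations")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    # design: x0[k] = -a z[k] + b
    B = np.column_stack([-z, np.ones_like(z)])
    (a, b), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    return GM11Model(a=float(a), b=float(b), x1=float(x0[0]), n=int(x0.size))


def gm11_predict(model: GM11Model, k: int) -> float:
    """Restored forecast x̂⁰(k), 1-based; k=1 returns the first observation.

    For a ≠ 0:  x̂⁰(k) = (x⁰(1) − b/a)(1 − eᵃ)·e^(−a(k−1)); the a → 0
    limit is the constant b.
    """
    if k < 1:
        raise ValueError("forecast index k must be >= 1")
    if k == 1:
        return model.x1
    if abs(model.a) < 1e-12:
        return model.b
    a, b = model.a, model.b
    return float((model.x1 - b / a) * (1.0 - np.exp(a)) * np.exp(-a * (k - 1)))


def gm11_forecast_series(series: np.ndarray | list[float], horizon: int) -> np.ndarray:
    """Convenience: fit on ``series`` and restore values 1..n+horizon."""
    model = gm11_fit(series)
    return np.array([gm11_predict(model, k) for k in range(1, model.n + horizon + 1)])
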