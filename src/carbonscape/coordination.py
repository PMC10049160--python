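"""Coordination between land-use intensity and carbon storage.

Land-use intensity (LUI) ranks classes by how strongly human activity has
reshaped them — 1 unused land, 2 ecological classes (forests, grassland,
wetland, waters), 3 farmland, 4 construction land — and weights class
areas by that ordinal level.  On square aggregation blocks (3 km default)
the annual growth rates of LUI and carbon storage are compared through

    O = |(ALUI + ACS) / 2| / sqrt(ALUI² + ACS²)

which is 1 when both grow at the same (signed) rate and 0 when the rates
exactly oppose.  Blocks are labelled uncoordinated / adapted / coordinated
by O thresholds 0.5 and 0.8, with an ahead/lagging sub-label from the sign
of ACS − ALUI.  The classified pattern is summarized by standard
deviational ellipses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from carbonscape.carbon import CarbonDensityTable
from carbonscape.raster_core import LandUseGrid, block_class_areas

logger = logging.getLogger(__name__)

#: intensity levels: unused 1; forests/grassland/wetland/waters 2; farmland 3; construction 4
DEFAULT_LEVELS: dict[int, int] = {1: 3, 2: 2, 3: 2, 4: 2, 5: 2, 6: 4, 7: 1}


@dataclass
class IntensityLevels:
    """Ordinal human-disturbance level per land-use class."""

    levels: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_LEVELS))

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.levels.values()):
            raise ValueError("intensity levels must be >= 1")

    def __getitem__(self, code: int) -> int:
        return self.levels[code]


def lui(
    class_areas: Mapping[int, float],
    levels: IntensityLevels | None = None,
    normalize: bool = False,
) -> float:
    """Land-use intensity of one block: Σ level(i) × area_i.

    ``class_areas`` maps class code to area within the block (any
    consistent unit).  With ``normalize`` the sum is divided by the block
    area, giving a dimensionless mean level.
    """
    levels = levels or IntensityLevels()
    if any(a < 0 for a in class_areas.values()):
        raise ValueError("areas must be non-negative")
    total = sum(class_areas.values())
    s = sum(levels[c] * a for c, a in class_areas.items())
    if normalize:
        return s / total if total > 0 else 0.0
    return s


def annual_growth(v_t0: float, v_t1: float, years: float) -> float:
    """Simple annualized relative change ((v1 − v0)/v0)/years.

    A zero base with a zero endpoint gives 0; a zero base with growth is
    undefined (returns NaN, caller excludes and logs the block).
    """
    if years <= 0:
        raise ValueError("years must be positive")
    if v_t0 < 0 or v_t1 < 0:
        raise ValueError("growth inputs must be non-negative")
    if v_t0 == 0:
        return 0.0 if v_t1 == 0 else float("nan")
    return ((v_t1 - v_t0) / v_t0) / years


def coordination_index(alui: float, acs: float, rms: bool = False) -> float:
    """O = |(ALUI + ACS)/2| / sqrt(ALUI² + ACS²), in [0, √2/2].

    The index is scale-invariant, zero for exactly opposed rates and
    maximal (√2/2) only when the rates are equal.  Note the upper
    classification band [0.8, 1] is unreachable under this normalization;
    ``rms=True`` divides by the root-mean-square instead (a √2 rescale),
    stretching the range to [0, 1] with 1 attained at equal rates.
    Raises when both rates are zero (the block carries a no-change label
    instead of an index).
    """
    norm = float(np.hypot(alui, acs))
    if norm == 0.0:
        raise ValueError("coordination undefined: both growth rates are zero")
    if rms:
        norm /= np.sqrt(2.0)
    return abs((alui + acs) / 2.0) / norm


COORD_TYPES = ("uncoordinated", "adapted", "coordinated")


def classify_coordination(o: float, alui: float, acs: float) -> str:
    """Label a block from its index and growth rates.

    O in [0, 0.5) → uncoordinated, [0.5, 0.8) → adapted, [0.8, 1] →
    coordinated; sub-label 'ahead' when carbon growth outpaces intensity
    growth (ALUI < ACS), else 'lagging'; exact ties go to 'ahead'.
    """
    if not (0.0 <= o <= 1.0 + 1e-12):
        raise ValueError("coordination index outside [0, 1]")
    if o < 0.5:
        coord = "uncoordinated"
    elif o < 0.8:
        coord = "adapted"
    else:
        coord = "coordinated"
    if alui == acs:
        logger.debug("ALUI == ACS; labelling 'ahead' by convention")
    sub = "ahead" if alui <= acs else "lagging"
    return f"{coord}/{sub}"


def coordination_grid(
    grid_t0: LandUseGrid,
    grid_t1: LandUseGrid,
    density_t0: CarbonDensityTable,
    density_t1: CarbonDensityTable,
    years: float,
    block: float = 3000.0,
    levels: IntensityLevels | None = None,
) -> pd.DataFrame:
    """Per-block coordination table between two dated maps.

    For every block: LUI and carbon storage at both dates, annual growth
    rates, the coordination index and the Table-style label.  Blocks where
    either growth rate is undefined (zero base with growth) or where both
    rates are zero are labelled 'no-change' with NaN index; they are
    excluded from ellipse summaries.  Density tables may differ by date
    (year-specific densities) or be the same object (fixed densities).
    """
    levels = levels or IntensityLevels()
    areas0 = block_class_areas(grid_t0, block)
    areas1 = block_class_areas(grid_t1, block)
    d0 = density_t0.total_density()
    d1 = density_t1.total_density()
    nbr, nbc = next(iter(areas0.values())).shape
    half = block / 2.0
    rows = []
    for br in range(nbr):
        for bc in range(nbc):
            a0 = {c: areas0[c][br, bc] for c in areas0}
            a1 = {c: areas1[c][br, bc] for c in areas1}
            if sum(a0.values()) == 0 and sum(a1.values()) == 0:
                continue  # block entirely nodata
            lui0 = lui(a0, levels)
            lui1 = lui(a1, levels)
            cs0 = sum(a0[c] * d0.get(c, 0.0) for c in a0)  # Mg
            cs1 = sum(a1[c] * d1.get(c, 0.0) for c in a1)
            alui = annual_growth(lui0, lui1, years)
            acs = annual_growth(cs0, cs1, years)
            x = grid_t0.origin[0] + bc * block + half
            y = grid_t0.origin[1] - br * block - half
            if np.isnan(alui) or np.isnan(acs):
                o, label = np.nan, "no-change"
                logger.debug("block (%d,%d): undefined growth, excluded", br, bc)
            elif alui == 0.0 and acs == 0.0:
                o, label = np.nan, "no-change"
            else:
                o = coordination_index(alui, acs)
                label = classify_coordination(o, alui, acs)
            rows.append(
                dict(block_row=br, block_col=bc, x=x, y=y,
                     lui_t0=lui0, lui_t1=lui1, cs_t0_mg=cs0, cs_t1_mg=cs1,
                     alui=alui, acs=acs, o=o, label=label)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# standard deviational ellipse


@dataclass
class SDEllipse:
    """Standard deviational ellipse of a weighted point pattern.

    ``angle_deg`` is measured clockwise from north (map convention);
    semiaxes are the weighted standard deviations along the rotated axes,
    area = π · major · minor.
    """

    center: tuple[float, float]
    major: float
    minor: float
    angle_deg: float
    degenerate: bool = False

    @property
    def area(self) -> float:
        return float(np.pi * self.major * self.minor)


def sde(
    points: np.ndarray, weights: np.ndarray | None = None
) -> SDEllipse:
    """Standard deviational ellipse of (n, 2) points with optional weights.

    The rotation solves the classical SDE angle equation; axis lengths are
    the weighted standard deviations of the coordinates projected on the
    rotated axes (the 1-sigma convention; callers wanting the sqrt(2)
    variant scale the axes).  Collinear input yields a zero minor axis and
    the degenerate flag.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive total")
    wsum = w.sum()
    cx, cy = (w @ pts) / wsum
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    sxx = float(w @ (dx * dx))
    syy = float(w @ (dy * dy))
    sxy = float(w @ (dx * dy))
    # classical SDE angle (theta clockwise from north)
    if abs(sxy) < 1e-15:
        theta = 0.0 if sxx >= syy else np.pi / 2.0
    else:
        diff = sxx - syy
        theta = np.arctan((diff + np.hypot(diff, 2.0 * sxy)) / (2.0 * sxy))
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    # deviations along the rotated axes
    s1 = np.sqrt(float(w @ (dx * cos_t - dy * sin_t) ** 2) / wsum)
    s2 = np.sqrt(float(w @ (dx * sin_t + dy * cos_t) ** 2) / wsum)
    # axis 1 corresponds to the direction theta clockwise from north
    if s1 >= s2:
        major, minor, angle = s1, s2, theta
    else:
        major, minor, angle = s2, s1, theta + np.pi / 2.0
    angle_deg = float(np.degrees(angle) % 180.0)
    degenerate = bool(minor < 1e-12 * max(major, 1.0))
    return SDEllipse(center=(float(cx), float(cy)), major=float(major),
                     minor=float(minor), angle_deg=angle_deg, degenerate=degenerate)


def sde_of_coordination(
    table: pd.DataFrame, weight_col: str = "o", scale: float = 1.0
) -> SDEllipse:
    """Ellipse of the coordination blocks, weighted by the index.

    No-change blocks (NaN index) are excluded; ``scale`` multiplies both
    semiaxes (e.g. sqrt(2) for the variance-doubling convention).
    """
    ok = table.dropna(subset=[weight_col])
    ell = sde(ok[["x", "y"]].to_numpy(), ok[weight_col].to_numpy())
    return SDEllipse(center=ell.center, major=ell.major * scale,
                     minor=ell.minor * scale, angle_deg=ell.angle_deg,
                     degenerate=ell.degenerate)
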