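"""Patch-generating cellular-automaton allocation (CARS stage).

Starting from a base map, cells are converted between classes until each
class's total meets its demand within tolerance.  A conversion's score is

    development probability × neighborhood effect × adaptive inertia
        × scenario multiplier(from, to)

zeroed wherever the transition matrix forbids the pair, the cell is
restricted, or the target class has already met demand.  Cells with no
same-class neighbors can still nucleate a new patch through random patch
seeding: with probability μ per class, and only while the cell's
development probability beats a threshold that decays geometrically each
sweep — so seeding starts conservative and loosens as allocation
progresses.  Conversions run from surplus classes to deficit classes
only, which makes every per-class demand gap non-increasing sweep over
sweep and conserves the total cell count by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from carbonscape.demand import DemandVector, demand_to_cells
from carbonscape.leas import DevelopmentProbability
from carbonscape.raster_core import CLASS_CODES, LandUseGrid


@dataclass
class TransitionMatrix:
    """Boolean allowed(from, to) over the class codes; persistence always allowed."""

    allowed: np.ndarray
    codes: tuple[int, ...] = CLASS_CODES

    def __post_init__(self) -> None:
        self.allowed = np.asarray(self.allowed, dtype=bool).copy()
        k = len(self.codes)
        if self.allowed.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        np.fill_diagonal(self.allowed, True)

    @classmethod
    def all_allowed(cls, codes: tuple[int, ...] = CLASS_CODES) -> "TransitionMatrix":
        k = len(codes)
        return cls(np.ones((k, k), dtype=bool), codes)

    @classmethod
    def none_allowed(cls, codes: tuple[int, ...] = CLASS_CODES) -> "TransitionMatrix":
        k = len(codes)
        return cls(np.eye(k, dtype=bool), codes)


@dataclass
class CarsParams:
    """Tunables of the patch allocator.

    neighborhood_radius : Moore-window radius in cells (default 1).
    neighborhood_weights : per-class weight in [0, 1] on the neighborhood
        fraction (default 1.0 for every class).
    patch_seed_prob : per-class probability μ that a zero-neighborhood
        cell is offered as a new patch seed each sweep (default 0.02).
    decay : geometric shrink factor δ of the seeding threshold per sweep.
    inertia_step : ε of the self-adaptive inertia — inertia is multiplied
        by (1+ε) while a class is under demand, divided while over.
    tolerance_cells : per-class demand gap accepted as met; default
        max(1, 0.1% of the class demand).
    """

    neighborhood_radius: int = 1
    neighborhood_weights: Mapping[int, float] = field(default_factory=dict)
    patch_seed_prob: float | Mapping[int, float] = 0.02
    decay: float = 0.9
    inertia_step: float = 0.1
    max_iters: int = 300
    tolerance_cells: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.tolerance_cells is not None and self.tolerance_cells < 0:
            raise ValueError("tolerance must be >= 0")
        for w in dict(self.neighborhood_weights).values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("neighborhood weights must be in [0, 1]")

    def weight(self, code: int) -> float:
        return dict(self.neighborhood_weights).get(code, 1.0)

    def mu(self, code: int) -> float:
        if isinstance(self.patch_seed_prob, Mapping):
            return self.patch_seed_prob.get(code, 0.02)
        return float(self.patch_seed_prob)

    def tolerance(self, demand_cells: int) -> int:
        if self.tolerance_cells is not None:
            return self.tolerance_cells
        return max(1, int(round(0.001 * demand_cells)))


def neighborhood_effect(
    grid: LandUseGrid, class_i: int, params: CarsParams | None = None
) -> np.ndarray:
    """Fraction of class-i cells in the window around each cell, × weight.

    The (2r+1)² Moore window excludes the center; off-map neighbors count
    as absent, so the value ranges over [0, weight].
    """
    params = params or CarsParams()
    r = params.neighborhood_radius
    indicator = (grid.codes == class_i).astype(float)
    kernel = np.ones((2 * r + 1, 2 * r + 1))
    total = ndimage.convolve(indicator, kernel, mode="constant", cval=0.0)
    neighbors = total - indicator
    denom = kernel.size - 1
    return params.weight(class_i) * neighbors / denom


@dataclass
class AllocationResult:
    """Outcome of one allocation run."""

    grid: LandUseGrid
    log: pd.DataFrame  # iteration, class, gap, inertia
    iterations: int
    converged: bool
    unmet: dict[int, int]  # class -> remaining gap (cells) beyond tolerance

    def diagnostic(self) -> str:
        if self.converged:
            return f"demand met within tolerance in {self.iterations} sweeps"
        gaps = ", ".join(f"class {c}: gap {g}" for c, g in self.unmet.items())
        return f"infeasible demand after {self.iterations} sweeps — unmet: {gaps}"


def allocate(
    base: LandUseGrid,
    probs: Mapping[int, DevelopmentProbability | np.ndarray],
    demand: DemandVector | Mapping[int, int],
    tmatrix: TransitionMatrix | None = None,
    restricted: np.ndarray | None = None,
    multipliers: np.ndarray | None = None,
    params: CarsParams | None = None,
    max_conversions: Mapping[int, int] | None = None,
    spatial_multipliers: Mapping[int, np.ndarray] | None = None,
) -> AllocationResult:
    """Evolve the base map until class totals meet demand.

    Parameters
    ----------
    base : starting land-use map; nodata cells never move.
    probs : per-class development-probability surfaces.
    demand : target areas (``DemandVector``, ha) or cell counts per class;
        cell demands are reconciled to the mapped cell total by
        largest-remainder rounding.
    tmatrix : allowed from→to conversions (default: all allowed).
    restricted : boolean mask of frozen cells (scenario restrictions).
    multipliers : 7×7 scenario factors on conversion scores.
    max_conversions : optional per-source-class cap on converted cells
        (development-intensity ceiling).
    spatial_multipliers : optional per-target-class spatial factor maps
        (planned-development zones, buffers).

    Each sweep scores every admissible (cell, target) pair, picks a target
    per cell by roulette over its class scores, orders candidate cells by
    a weighted random draw, and converts greedily while both the source
    surplus and the target deficit persist.  Infeasible demand ends with a
    partial allocation and an explicit diagnostic.
    """
    params = params or CarsParams()
    tmatrix = tmatrix or TransitionMatrix.all_allowed()
    codes = list(CLASS_CODES)
    k = len(codes)
    state = base.codes.copy()
    valid = base.valid_mask
    n_valid = int(valid.sum())
    if restricted is None:
        restricted = np.zeros(base.shape, dtype=bool)
    if multipliers is None:
        multipliers = np.ones((k, k))
    if isinstance(demand, DemandVector):
        demand_cells = demand_to_cells(demand, base.cell_area_ha, n_valid)
    else:
        demand_cells = {int(c): int(n) for c, n in demand.items()}
        if sum(demand_cells.values()) != n_valid:
            raise ValueError(
                f"cell demand total {sum(demand_cells.values())} != mapped cells {n_valid}")
    demand_arr = np.array([demand_cells.get(c, 0) for c in codes])
    tol = np.array([params.tolerance(demand_cells.get(c, 0)) for c in codes])

    surfaces: dict[int, np.ndarray] = {}
    for c in codes:
        p = probs.get(c)
        if p is None:
            surfaces[c] = np.zeros(base.shape)
        else:
            surfaces[c] = p.surface if isinstance(p, DevelopmentProbability) else np.asarray(p)
    rng = np.random.default_rng(params.seed)

    counts = np.array([int(np.sum(state[valid] == c)) for c in codes])
    inertia = np.ones(k)
    tau = 1.0
    converted_from = np.zeros(k, dtype=int)
    cap = None
    if max_conversions is not None:
        cap = np.array([max_conversions.get(c, np.iinfo(np.int32).max) for c in codes])

    # class-index lookup per cell (k for nodata, rows of zeros appended)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    log_rows: list[dict] = []
    it = 0
    converged = False
    movable = valid & ~restricted
    for it in range(1, params.max_iters + 1):
        gap = demand_arr - counts
        for i, c in enumerate(codes):
            log_rows.append(dict(iteration=it, class_code=c, gap=int(gap[i]),
                                 inertia=float(inertia[i])))
        if np.all(np.abs(gap) <= tol):
            converged = True
            break
        # adaptive inertia
        inertia = np.where(gap > tol, inertia * (1 + params.inertia_step), inertia)
        inertia = np.where(gap < -tol, inertia / (1 + params.inertia_step), inertia)

        targets = [i for i in range(k) if gap[i] > 0]
        sources = [i for i in range(k) if gap[i] < 0]
        if not targets or not sources:
            break
        state_idx = np.full(base.shape, -1, dtype=int)
        for c, i in code_to_idx.items():
            state_idx[state == c] = i
        src_ok = movable & np.isin(state_idx, sources)
        if cap is not None:
            exhausted = [i for i in sources if converted_from[i] >= cap[i]]
            if exhausted:
                src_ok &= ~np.isin(state_idx, exhausted)
        grid_now = base.copy_with(state)

        scores = np.zeros((len(targets), *base.shape))
        feasible_any = False
        for ti, i in enumerate(targets):
            ci = codes[i]
            p = np.nan_to_num(surfaces[ci], nan=0.0)
            allowed = tmatrix.allowed[np.clip(state_idx, 0, k - 1), i] & (state_idx >= 0)
            admissible = src_ok & allowed & (state != ci)
            if not (admissible & (p > 0)).any():
                continue
            feasible_any = True
            neigh = neighborhood_effect(grid_now, ci, params)
            mu = params.mu(ci)
            seed_draw = rng.random(base.shape)
            seed_ok = (neigh <= 0) & (seed_draw < mu) & (p > tau)
            factor = np.where(neigh > 0, neigh, np.where(seed_ok, mu, 0.0))
            mult = multipliers[np.clip(state_idx, 0, k - 1), i]
            s = p * factor * inertia[i] * mult
            if spatial_multipliers is not None and ci in spatial_multipliers:
                s = s * spatial_multipliers[ci]
            s[~admissible] = 0.0
            scores[ti] = s
        if not feasible_any:
            break  # structurally infeasible: no admissible cell has support

        cell_total = scores.sum(axis=0)
        cand = np.flatnonzero(cell_total.ravel() > 0)
        if cand.size == 0:
            tau *= params.decay
            continue
        # roulette draw of the target class per candidate cell
        col = scores.reshape(len(targets), -1)[:, cand]
        cum = np.cumsum(col, axis=0)
        draw = rng.random(cand.size) * cum[-1]
        choice = (draw[None, :] >= cum).sum(axis=0)
        weight = col[choice, np.arange(cand.size)]
        keep = weight > 0  # boundary draws can land on a zero-score class
        cand, choice, weight = cand[keep], choice[keep], weight[keep]
        # weighted order without replacement (exponential-keys trick)
        order = np.argsort(rng.exponential(size=cand.size) / weight)
        gap_live = gap.copy()
        flat_state = state.ravel()
        for j in order:
            cell = cand[j]
            ti = choice[j]
            i = targets[ti]
            f = code_to_idx[flat_state[cell]]
            if gap_live[i] <= 0 or gap_live[f] >= 0:
                continue
            if cap is not None and converted_from[f] >= cap[f]:
                continue
            flat_state[cell] = codes[i]
            counts[i] += 1
            counts[f] -= 1
            gap_live[i] -= 1
            gap_live[f] += 1
            converted_from[f] += 1
        tau *= params.decay
    gap = demand_arr - counts
    unmet = {codes[i]: int(gap[i]) for i in range(k) if abs(gap[i]) > tol[i]}
    if not converged:
        converged = not unmet
    return AllocationResult(
        grid=base.copy_with(state),
        log=pd.DataFrame(log_rows),
        iterations=it,
        converged=converged,
        unmet=unmet,
    )


def random_allocation(
    base: LandUseGrid,
    demand: Mapping[int, int],
    seed: int = 0,
    restricted: np.ndarray | None = None,
) -> LandUseGrid:
    """Baseline allocator: meet cell demand by uniformly random conversions.

    Used as the null model when scoring the CA's figure of merit — same
    demand, no probabilities, no neighborhood.
    """
    rng = np.random.default_rng(seed)
    codes = list(CLASS_CODES)
    state = base.codes.copy()
    valid = base.valid_mask
    if restricted is None:
        restricted = np.zeros(base.shape, dtype=bool)
    counts = {c: int(np.sum(state[valid] == c)) for c in codes}
    gap = {c: demand.get(c, 0) - counts[c] for c in codes}
    movable = valid & ~restricted
    sources = [c for c in codes if gap[c] < 0]
    pool = np.flatnonzero(movable.ravel() & np.isin(state.ravel(), sources))
    rng.shuffle(pool)
    flat = state.ravel()
    deficit = [c for c in codes if gap[c] > 0]
    for cell in pool:
        f = flat[cell]
        if gap[f] >= 0:
            continue
        deficit = [c for c in deficit if gap[c] > 0]
        if not deficit:
            break
        t = deficit[rng.integers(len(deficit))]
        flat[cell] = t
        gap[f] += 1
        gap[t] -= 1
    return base.copy_with(state)
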