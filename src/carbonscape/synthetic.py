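"""Synthetic landscapes with known transition ground truth.

Downstream stages (development-probability estimation, patch allocation,
validation, coordination) are exercised on generated data: multi-date
seven-class maps whose transitions are logistic functions of spatially
autocorrelated driver fields, plus geometric series for density
forecasting.  Every output is fully determined by the spec seed, and each
simulated transition ships with the exact per-cell probability used, so
fitted surfaces can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from carbonscape.raster_core import DriverStack, LandUseGrid

#: rough class proportions of a forested river basin
DEFAULT_PROPORTIONS: dict[int, float] = {
    1: 0.28, 2: 0.53, 3: 0.06, 4: 0.02, 5: 0.03, 6: 0.05, 7: 0.03,
}

#: default transition rules: logit coefficients over
#: [1, field_0 .. field_{n-1}, dist_city]; keys are (from_class, to_class)
DEFAULT_RULES: dict[tuple[int, int], tuple[float, ...]] = {
    # urbanization pulls toward the city (negative distance coefficient)
    (1, 6): (-3.0, 0.0, 0.0, 0.0, 0.0, -2.5),
    (3, 6): (-3.5, 0.0, 0.0, 0.0, 0.0, -2.5),
    # afforestation follows the first terrain field, away from the city
    (1, 2): (-3.5, 2.0, 0.0, 0.0, 0.0, 0.8),
    (3, 2): (-3.5, 2.0, 0.0, 0.0, 0.0, 0.5),
    # wetland restoration follows the second field
    (1, 4): (-4.5, 0.0, 2.0, 0.0, 0.0, 0.3),
}


@dataclass
class SyntheticSpec:
    """Recipe for one reproducible synthetic study area.

    ``rules`` maps (from_class, to_class) to logit coefficients over the
    intercept, the ``n_fields`` smooth noise drivers, and the
    distance-to-city layer (standardized).  ``demand`` optionally fixes
    the exact number of cells gained per step by a target class; demanded
    conversions are drawn without replacement ranked by true probability,
    making the generator demand-exact.
    """

    shape: tuple[int, int] = (120, 120)
    cell_size: float = 30.0
    n_fields: int = 4
    correlation_length: float = 8.0  # cells
    proportions: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    rules: Mapping[tuple[int, int], Sequence[float]] = field(
        default_factory=lambda: dict(DEFAULT_RULES))
    demand: Mapping[int, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 2:
            raise ValueError("degenerate grid shape")
        n_coef = self.n_fields + 2
        for key, coefs in self.rules.items():
            if len(coefs) != n_coef:
                raise ValueError(
                    f"rule {key} needs {n_coef} coefficients (intercept, "
                    f"{self.n_fields} fields, distance)")
            if not np.all(np.isfinite(coefs)):
                raise ValueError(f"rule {key} has non-finite coefficients")
        total = int(np.prod(self.shape))
        for cls, k in self.demand.items():
            if k < 0 or k > total:
                raise ValueError(f"demand for class {cls} outside [0, n_cells]")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if corr > 0:
        noise = ndimage.gaussian_filter(noise, sigma=corr, mode="reflect")
    return (noise - noise.mean()) / noise.std()


def make_drivers(spec: SyntheticSpec) -> DriverStack:
    """Driver stack: standardized smooth fields plus a distance-to-city layer.

    The city seed cell is drawn from the spec's RNG stream; the distance
    layer is the Euclidean cell-center distance to it, standardized like
    the noise fields.  Identical seeds give identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    layers: dict[str, np.ndarray] = {}
    for i in range(spec.n_fields):
        layers[f"field_{i}"] = _smooth_field(rng, spec.shape, spec.correlation_length)
    rows, cols = np.indices(spec.shape)
    city = (rng.integers(0, spec.shape[0]), rng.integers(0, spec.shape[1]))
    dist = np.hypot(rows - city[0], cols - city[1])
    layers["dist_city"] = (dist - dist.mean()) / dist.std()
    return DriverStack(layers=layers)


def make_initial(spec: SyntheticSpec, drivers: DriverStack | None = None) -> LandUseGrid:
    """Spatially coherent starting map with the spec's class proportions.

    Classes are carved from quantiles of an independent smooth field, then
    construction land is re-seeded around the city (nearest cells), giving
    a compact urban core for expansion rules to act on.
    """
    drivers = drivers if drivers is not None else make_drivers(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    base_field = _smooth_field(rng, spec.shape, spec.correlation_length)
    order = [c for c in sorted(spec.proportions) if spec.proportions[c] > 0]
    probs = np.array([spec.proportions[c] for c in order], dtype=float)
    probs = probs / probs.sum()
    edges = np.quantile(base_field, np.cumsum(probs)[:-1])
    codes = np.asarray(order, dtype=np.int32)[np.searchsorted(edges, base_field)]
    # compact construction core around the city
    n_constr = int(round(spec.proportions.get(6, 0.0) * codes.size))
    if n_constr > 0:
        dist = drivers.layers["dist_city"]
        flat = np.argsort(dist, axis=None)[:n_constr]
        codes.flat[codes.flat == 6] = 1  # recycle scattered construction
        codes.flat[flat] = 6
    return LandUseGrid(codes, spec.cell_size)


def _rule_probability(
    spec: SyntheticSpec, drivers: DriverStack, coefs: Sequence[float]
) -> np.ndarray:
    X = [np.ones(spec.shape)]
    for i in range(spec.n_fields):
        X.append(drivers.layers[f"field_{i}"])
    X.append(drivers.layers["dist_city"])
    logit = sum(c * x for c, x in zip(coefs, X))
    return 1.0 / (1.0 + np.exp(-logit))


def evolve_landscape(
    spec: SyntheticSpec, steps: int = 1
) -> tuple[list[LandUseGrid], list[dict[int, np.ndarray]]]:
    """Evolve the synthetic map and return the exact transition truth.

    Returns ``steps + 1`` maps and, per step, a mapping
    ``target class -> per-cell true conversion probability`` (zero where
    the cell's current class has no rule into the target).  Without a
    demand entry a cell converts by a Bernoulli draw of its probability;
    with demand k for a class, exactly the k highest-probability eligible
    cells convert (ranked draw without replacement).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    drivers = make_drivers(spec)
    grid = make_initial(spec, drivers)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    maps = [grid]
    truths: list[dict[int, np.ndarray]] = []
    rule_p = {key: _rule_probability(spec, drivers, coefs)
              for key, coefs in spec.rules.items()}
    targets = sorted({t for _, t in spec.rules})
    for _ in range(steps):
        state = maps[-1].codes
        truth: dict[int, np.ndarray] = {}
        prop: dict[int, np.ndarray] = {}
        for t in targets:
            p = np.zeros(spec.shape)
            for (f, tt), pmat in rule_p.items():
                if tt == t:
                    p = np.where(state == f, pmat, p)
            truth[t] = p
            prop[t] = p
        new_state = state.copy()
        taken = np.zeros(spec.shape, dtype=bool)
        for t in targets:
            p = np.where(taken | (state == t), 0.0, prop[t])
            k = spec.demand.get(t)
            if k is not None:
                eligible = p > 0
                avail = int(eligible.sum())
                if k > avail:
                    raise ValueError(
                        f"demand {k} for class {t} exceeds {avail} eligible cells")
                # ranked without replacement, random tie-break
                keys = p + rng.random(spec.shape) * 1e-12
                keys[~eligible] = -np.inf
                chosen = np.argsort(keys, axis=None)[::-1][:k]
                sel = np.zeros(spec.shape, dtype=bool)
                sel.flat[chosen] = True
            else:
                sel = rng.random(spec.shape) < p
            new_state[sel] = t
            taken |= sel
        maps.append(maps[-1].copy_with(new_state))
        truths.append(truth)
    return maps, truths


def make_series(start: float, ratio: float, n: int) -> np.ndarray:
    """Geometric series start·ratio^(k−1), k = 1..n — a gray-model fixture."""
    if start <= 0 or ratio <= 0:
        raise ValueError("start and ratio must be positive")
    if n < 4:
        raise ValueError("need at least 4 terms")
    return start * ratio ** np.arange(n)
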