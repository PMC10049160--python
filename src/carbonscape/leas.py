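"""Development-probability estimation from historical land expansion.

For each class, cells that converted to it between two dates (expansion
cells) are positive examples and a balanced sample of unconverted cells
negatives; an ensemble of decision trees (random forest) fitted on the
driver stack then yields a per-cell development-probability surface.
One binary model is fitted per class rather than a single multiclass
model, so each class's expansion is explained on its own terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from carbonscape.raster_core import DriverStack, LandUseGrid, _check_aligned

logger = logging.getLogger(__name__)


@dataclass
class ExpansionSamples:
    """Labelled training cells for one class's expansion model."""

    class_code: int
    rows: np.ndarray
    cols: np.ndarray
    labels: np.ndarray  # 1 = expanded into class, 0 = did not
    no_expansion: bool = False

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


@dataclass
class DevelopmentProbability:
    """Per-class development-probability surface in [0, 1]."""

    class_code: int
    surface: np.ndarray
    importances: pd.Series | None = None

    def __post_init__(self) -> None:
        finite = self.surface[np.isfinite(self.surface)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")


def sample_expansion(
    grid_t0: LandUseGrid,
    grid_t1: LandUseGrid,
    class_i: int,
    seed: int = 0,
    balance: float = 1.0,
    max_positives: int | None = None,
) -> ExpansionSamples:
    """Expansion cells of one class plus sampled negatives.

    Positives are exactly the cells converted to ``class_i`` between the
    dates; negatives are drawn uniformly from cells that neither were nor
    became the class, ``balance`` negatives per positive (default 1:1).
    Zero expansion returns an explicit no-expansion marker.
    """
    _check_aligned(grid_t0, grid_t1)
    rng = np.random.default_rng(seed)
    valid = grid_t0.valid_mask & grid_t1.valid_mask
    pos = valid & (grid_t1.codes == class_i) & (grid_t0.codes != class_i)
    if not pos.any():
        return ExpansionSamples(class_i, np.empty(0, int), np.empty(0, int),
                                np.empty(0, int), no_expansion=True)
    neg_pool = valid & (grid_t0.codes != class_i) & (grid_t1.codes != class_i)
    pr, pc = np.nonzero(pos)
    if max_positives is not None and pr.size > max_positives:
        keep = rng.choice(pr.size, size=max_positives, replace=False)
        pr, pc = pr[keep], pc[keep]
    nr, nc = np.nonzero(neg_pool)
    n_neg = min(int(round(balance * pr.size)), nr.size)
    keep = rng.choice(nr.size, size=n_neg, replace=False)
    nr, nc = nr[keep], nc[keep]
    rows = np.concatenate([pr, nr])
    cols = np.concatenate([pc, nc])
    labels = np.concatenate([np.ones(pr.size, int), np.zeros(nr.size, int)])
    return ExpansionSamples(class_i, rows, cols, labels)


def fit_development(
    samples: ExpansionSamples,
    drivers: DriverStack,
    seed: int = 0,
    n_trees: int = 100,
) -> DevelopmentProbability:
    """Random-forest development probability for one class.

    The surface is the forest's predicted expansion probability at every
    cell; a no-expansion sample yields an all-zero surface.  Deterministic
    for a given seed.
    """
    if samples.no_expansion:
        return DevelopmentProbability(samples.class_code, np.zeros(drivers.shape))
    if samples.n_positive < 2 or (samples.labels == 0).sum() < 2:
        raise ValueError("need at least 2 samples of each label")
    X_all = drivers.as_feature_matrix()
    flat = samples.rows * drivers.shape[1] + samples.cols
    clf = RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(X_all[flat], samples.labels)
    proba = clf.predict_proba(X_all)[:, list(clf.classes_).index(1)]
    surface = proba.reshape(drivers.shape)
    nodata = ~np.all([np.isfinite(a) for a in drivers.layers.values()], axis=0)
    surface = np.where(nodata, np.nan, surface)
    importances = pd.Series(clf.feature_importances_, index=drivers.names)
    return DevelopmentProbability(samples.class_code, surface, importances)


def fit_all_development(
    grid_t0: LandUseGrid,
    grid_t1: LandUseGrid,
    drivers: DriverStack,
    seed: int = 0,
    n_trees: int = 100,
    balance: float = 1.0,
    max_positives: int | None = None,
) -> dict[int, DevelopmentProbability]:
    """Fit one expansion model per legend class; zero surfaces where none expanded."""
    out: dict[int, DevelopmentProbability] = {}
    for k, code in enumerate(sorted(grid_t0.legend)):
        samples = sample_expansion(
            grid_t0, grid_t1, code, seed=seed + k, balance=balance,
            max_positives=max_positives)
        if samples.no_expansion:
            logger.info("class %d: no expansion observed", code)
        out[code] = fit_development(samples, drivers, seed=seed + k, n_trees=n_trees)
    return out
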