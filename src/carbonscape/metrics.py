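"""Map-agreement statistics for simulation verification.

Overall accuracy and Cohen's kappa summarize cellwise agreement between a
reference and a simulated map; the figure of merit (FoM) scores agreement
in observed-change space only, which is the stricter and more informative
test for land-change models (persistence usually dominates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from carbonscape.raster_core import LandUseGrid, _check_aligned


@dataclass
class ConfusionMatrix:
    """K×K cell counts, reference rows versus simulated columns."""

    counts: np.ndarray
    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(reference: LandUseGrid, simulated: LandUseGrid) -> ConfusionMatrix:
    """Cellwise cross-tabulation of two aligned maps, nodata excluded."""
    _check_aligned(reference, simulated)
    valid = reference.valid_mask & simulated.valid_mask
    ref = reference.codes[valid]
    sim = simulated.codes[valid]
    labels = tuple(sorted(set(np.unique(ref)) | set(np.unique(sim))))
    idx = {c: i for i, c in enumerate(labels)}
    k = len(labels)
    ri = np.vectorize(idx.get)(ref)
    si = np.vectorize(idx.get)(sim)
    counts = np.bincount(ri * k + si, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, labels)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of cells on the diagonal: trace / total."""
    return float(np.trace(cm.counts)) / cm.total


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's kappa: (p_o − p_e) / (1 − p_e) with marginal-product chance.

    Raises for the degenerate single-class case where expected agreement
    is 1 and the coefficient is undefined.
    """
    n = cm.total
    p_o = overall_accuracy(cm)
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(np.dot(row, col))
    if abs(1.0 - p_e) < 1e-12:
        raise ValueError("kappa undefined: expected agreement equals 1")
    return (p_o - p_e) / (1.0 - p_e)


def figure_of_merit(
    reference_t0: LandUseGrid,
    reference_t1: LandUseGrid,
    simulated_t1: LandUseGrid,
) -> float:
    """Figure of merit B / (A + B + C + D) over observed-change space.

    A — observed change simulated as persistence (misses);
    B — observed change simulated as the correct new class (hits);
    C — observed change simulated as change to a wrong class;
    D — observed persistence simulated as change (false alarms).

    Undefined (raises) when neither observed nor simulated change exists.
    """
    _check_aligned(reference_t0, reference_t1)
    _check_aligned(reference_t0, simulated_t1)
    valid = (
        reference_t0.valid_mask & reference_t1.valid_mask & simulated_t1.valid_mask
    )
    t0 = reference_t0.codes[valid]
    t1 = reference_t1.codes[valid]
    sim = simulated_t1.codes[valid]
    obs_change = t1 != t0
    sim_change = sim != t0
    a = int(np.sum(obs_change & ~sim_change))
    b = int(np.sum(obs_change & sim_change & (sim == t1)))
    c = int(np.sum(obs_change & sim_change & (sim != t1)))
    d = int(np.sum(~obs_change & sim_change))
    denom = a + b + c + d
    if denom == 0:
        raise ValueError("figure of merit undefined: no observed or simulated change")
    return b / denom
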