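"""Declarative policy scenarios compiled into allocation inputs.

Four 2030-style scenarios ship with the package:

- **nes** (natural evolution): historical trend continued — identity
  multipliers, no restrictions.
- **eps** (ecological protection): conversions of farmland and unused
  land to forests/wetland/waters and of grassland to forests boosted by
  60% (×1.6); farmland and unused land to construction cut by 80%
  (×0.2); ecological-barrier zones frozen for ecological classes except
  inside a 10-km buffer around existing construction.
- **eds** (economic development): every class except waters 50% likelier
  (×1.5) to convert to farmland or construction; planned-development
  zones favored; existing waters frozen.
- **pds** (planned development): barrier zones freeze forests, wetland
  and waters; agricultural zones freeze farmland; conversion of each
  class outside restrictions capped at 6.9% of its area (development
  intensity ceiling); planned-development zones favored for construction.

Relative phrases ("improve by 60%") act multiplicatively on allocation
scores, and the same multiplier matrix re-weights the Markov transition
rows before demand projection, so scenario pressure shows up in both the
demand totals and the spatial allocation; either path can be disabled.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from carbonscape.cars import TransitionMatrix
from carbonscape.demand import MarkovModel
from carbonscape.raster_core import CLASS_CODES, DEFAULT_LEGEND, LandUseGrid, buffer_mask

_NAME_TO_CODE = {v: k for k, v in DEFAULT_LEGEND.items()}

SHIPPED_SCENARIOS = ("nes", "eps", "eds", "pds")


def _codes(names: Sequence[str | int]) -> list[int]:
    out = []
    for n in names:
        if isinstance(n, int):
            out.append(n)
        elif n in _NAME_TO_CODE:
            out.append(_NAME_TO_CODE[n])
        else:
            raise ValueError(f"unknown land-use class {n!r}")
    return out


@dataclass
class ScenarioConfig:
    """One named scenario as declarative rules.

    multiplier_rules : list of {from, to, factor} entries (class names or
        codes); unlisted pairs keep factor 1.
    restrictions : list of rule dicts —
        {mask, classes, exempt_buffer:{class, radius_m}} freezes the
        listed classes inside the named mask layer (minus the optional
        buffer), {freeze_class} freezes every current cell of a class.
    planned_development : optional {mask, factor} favoring conversion to
        construction inside the masked zone.
    intensity_cap : optional fraction capping per-class conversions
        outside restrictions.
    """

    name: str
    demand_source: str = "markov"
    multiplier_rules: list[dict] = field(default_factory=list)
    restrictions: list[dict] = field(default_factory=list)
    planned_development: dict | None = None
    intensity_cap: float | None = None
    transition_forbidden: list[dict] = field(default_factory=list)
    apply_to_demand: bool = True
    apply_to_allocation: bool = True

    def __post_init__(self) -> None:
        if self.demand_source not in {"markov", "explicit"}:
            raise ValueError("demand_source must be 'markov' or 'explicit'")
        if self.intensity_cap is not None and not 0.0 <= self.intensity_cap <= 1.0:
            raise ValueError("intensity cap must be in [0, 1]")
        for rule in self.multiplier_rules:
            if rule.get("factor", 1.0) < 0:
                raise ValueError("multipliers must be >= 0")

    def multiplier_matrix(self) -> np.ndarray:
        k = len(CLASS_CODES)
        M = np.ones((k, k))
        for rule in self.multiplier_rules:
            rows = [c - 1 for c in _codes(rule["from"])]
            cols = [c - 1 for c in _codes(rule["to"])]
            for r in rows:
                for c in cols:
                    if r != c:
                        M[r, c] = rule.get("factor", 1.0)
        return M


@dataclass
class CompiledScenario:
    """Scenario rules resolved against a concrete base map."""

    name: str
    multipliers: np.ndarray
    restricted: np.ndarray
    tmatrix: TransitionMatrix
    demand_markov: MarkovModel | None
    max_conversions: dict[int, int] | None
    spatial_multipliers: dict[int, np.ndarray] | None


def load_scenario(name_or_path: str | Path) -> ScenarioConfig:
    """Load a shipped scenario by name (nes/eps/eds/pds) or a YAML file."""
    p = Path(name_or_path)
    if p.suffix in {".yaml", ".yml"} and p.exists():
        text = p.read_text()
    else:
        ref = importlib.resources.files("carbonscape") / "data" / "scenarios" / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no shipped scenario {name_or_path!r} and no such file")
        text = ref.read_text()
    raw = yaml.safe_load(text)
    return ScenarioConfig(
        name=raw["name"],
        demand_source=raw.get("demand", "markov"),
        multiplier_rules=raw.get("multipliers", []),
        restrictions=raw.get("restrictions", []),
        planned_development=raw.get("planned_development"),
        intensity_cap=raw.get("intensity_cap"),
        transition_forbidden=raw.get("transition_forbidden", []),
        apply_to_demand=raw.get("apply_to_demand", True),
        apply_to_allocation=raw.get("apply_to_allocation", True),
    )


def _adjust_markov(markov: MarkovModel, multipliers: np.ndarray) -> MarkovModel:
    """Re-weight Markov rows by the scenario multipliers and renormalize."""
    P = markov.P * multipliers
    rowsum = P.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return MarkovModel(P=P / rowsum, codes=markov.codes,
                       interval_years=markov.interval_years)


def compile_scenario(
    config: ScenarioConfig,
    base: LandUseGrid,
    masks: Mapping[str, np.ndarray] | None = None,
    markov: MarkovModel | None = None,
) -> CompiledScenario:
    """Resolve a scenario's rules against a base map and mask layers.

    Returns the multiplier matrix, the frozen-cell mask, transition-matrix
    overrides, the demand-side adjusted Markov chain (when demand comes
    from the chain), per-class conversion caps and spatial multipliers.
    Referencing a mask layer that was not supplied raises.
    """
    masks = masks or {}
    mult = config.multiplier_matrix() if config.apply_to_allocation else np.ones(
        (len(CLASS_CODES),) * 2)
    restricted = np.zeros(base.shape, dtype=bool)
    for rule in config.restrictions:
        if "freeze_class" in rule:
            for c in _codes([rule["freeze_class"]]):
                restricted |= base.codes == c
            continue
        mask_name = rule["mask"]
        if mask_name not in masks:
            raise KeyError(
                f"scenario {config.name!r} references mask {mask_name!r} "
                f"but only {sorted(masks)} were supplied")
        zone = np.asarray(masks[mask_name], dtype=bool)
        if zone.shape != base.shape:
            raise ValueError(f"mask {mask_name!r} shape {zone.shape} != map {base.shape}")
        if "exempt_buffer" in rule:
            eb = rule["exempt_buffer"]
            buf = buffer_mask(base, _codes([eb["class"]])[0], float(eb["radius_m"]))
            zone = zone & ~buf
        if "classes" in rule:
            in_classes = np.isin(base.codes, _codes(rule["classes"]))
            restricted |= zone & in_classes
        else:
            restricted |= zone

    tmatrix = TransitionMatrix.all_allowed()
    for rule in config.transition_forbidden:
        for f in _codes(rule["from"]):
            for t in _codes(rule["to"]):
                if f != t:
                    tmatrix.allowed[f - 1, t - 1] = False

    spatial = None
    if config.planned_development is not None:
        pd_rule = config.planned_development
        mask_name = pd_rule["mask"]
        if mask_name not in masks:
            raise KeyError(
                f"scenario {config.name!r} references mask {mask_name!r} "
                f"but only {sorted(masks)} were supplied")
        zone = np.asarray(masks[mask_name], dtype=bool)
        factor = float(pd_rule.get("factor", 1.5))
        layer = np.where(zone, factor, 1.0)
        spatial = {_NAME_TO_CODE["construction"]: layer}

    caps = None
    if config.intensity_cap is not None:
        caps = {}
        for c in CLASS_CODES:
            free = int(np.sum((base.codes == c) & ~restricted & base.valid_mask))
            caps[c] = int(np.floor(config.intensity_cap * free))

    demand_markov = None
    if config.demand_source == "markov" and markov is not None:
        demand_markov = (_adjust_markov(markov, config.multiplier_matrix())
                         if config.apply_to_demand else markov)
    return CompiledScenario(
        name=config.name,
        multipliers=mult,
        restricted=restricted,
        tmatrix=tmatrix,
        demand_markov=demand_markov,
        max_conversions=caps,
        spatial_multipliers=spatial,
    )
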