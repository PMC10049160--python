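"""Reference tables for the Dongting Lake Basin study region.

Published per-class carbon densities (four pools, Mg·ha⁻¹, 2020 estimates
and 2030 gray-model forecasts) and per-class areas (km²) for 2020 and the
four 2030 policy scenarios.  These small tables are the worked-example
inputs of the package: feeding them through :func:`carbonscape.compute_cs`
reproduces the basin's published carbon-storage bookkeeping.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from carbonscape.carbon import CarbonDensityTable, POOLS
from carbonscape.raster_core import AreaTable

AREA_LABELS = ("2020", "2030_nes", "2030_eps", "2030_eds", "2030_pds")


def _data_path(name: str):
    return importlib.resources.files("carbonscape") / "data" / name


def load_dlb_density(year: str) -> CarbonDensityTable:
    """Dongting Lake Basin density table for '2020' or '2030'."""
    with importlib.resources.as_file(_data_path("dlb_carbon_density.csv")) as p:
        df = pd.read_csv(p)
    sub = df[df["year"] == int(year)].set_index("class_code")
    if sub.empty:
        raise ValueError(f"no density table for year {year!r}")
    return CarbonDensityTable(sub[list(POOLS)], year=str(year))


def load_dlb_areas(label: str | None = None) -> AreaTable:
    """Per-class areas in hectares; one label or all five columns.

    Labels: '2020', '2030_nes', '2030_eps', '2030_eds', '2030_pds'.
    The source file is in km²; values are converted to ha (×100).
    """
    with importlib.resources.as_file(_data_path("dlb_class_areas.csv")) as p:
        df = pd.read_csv(p).set_index("class_code")
    cols = [label] if label is not None else list(AREA_LABELS)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"unknown area labels {missing}; have {list(AREA_LABELS)}")
    return AreaTable(table=df[cols] * 100.0)
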