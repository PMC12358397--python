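"""Overlay of suitable areas with categorical land-use rasters.

Stable suitable areas (cells suitable in every period considered) are
intersected with an integer-coded land-use layer to report how the
candidate habitat splits across land-use types (Cropland, Forest,
Grassland, Urban, Unused, Water by default) and what share of each type
falls inside the habitat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classification_change import binarize
from .grid_io import GridLayer, assert_coregistered

__all__ = [
    "DEFAULT_LANDUSE_CODES",
    "LandUseLayer",
    "stable_suitable",
    "landuse_composition",
    "class_share_inside",
    "suitable_area_by_landuse",
]

logger = logging.getLogger(__name__)

DEFAULT_LANDUSE_CODES = {
    1: "Cropland",
    2: "Forest",
    3: "Grassland",
    4: "Urban",
    5: "Unused",
    6: "Water",
}


@dataclass
class LandUseLayer:
    """Categorical raster plus its integer -> class-name code table."""

    layer: GridLayer
    codes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LANDUSE_CODES))

    def __post_init__(self) -> None:
        if self.layer.kind != "categorical":
            raise ValueError("land-use layer must be categorical")
        finite = self.layer.values[np.isfinite(self.layer.values)]
        unknown = set(np.unique(finite).astype(int)) - set(self.codes)
        if unknown:
            raise ValueError(f"land-use codes without table entry: {sorted(unknown)}")

    def write_code_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("code\tname\n")
            for code, name in sorted(self.codes.items()):
                fh.write(f"{code}\t{name}\n")


def stable_suitable(bin_layers: list[GridLayer]) -> GridLayer:
    """Intersection of binary suitable maps: 1 iff suitable in all inputs."""
    if len(bin_layers) < 2:
        raise ValueError("need at least 2 binary layers")
    assert_coregistered(bin_layers)
    for lyr in bin_layers:
        if lyr.kind != "binary":
            raise ValueError("all inputs must be binary layers")
    ok = np.isfinite(bin_layers[0].values)
    acc = bin_layers[0].values == 1.0
    for lyr in bin_layers[1:]:
        ok &= np.isfinite(lyr.values)
        acc &= lyr.values == 1.0
    out = np.where(ok, acc.astype(float), np.nan)
    return bin_layers[0].copy_with(out, kind="binary", name="stable_suitable")


def landuse_composition(
    stable: GridLayer, lu: LandUseLayer, cell_areas: GridLayer
) -> pd.DataFrame:
    """Area and percentage of each land-use class inside the stable mask.

    Percentages sum to 100 over the classes present in the mask; an empty
    mask yields all-zero areas with a logged warning.
    """
    assert_coregistered([stable, lu.layer, cell_areas])
    inside = stable.values == 1.0
    rows = []
    total = 0.0
    for code, name in sorted(lu.codes.items()):
        sel = inside & (lu.layer.values == code)
        area = float(np.nansum(np.where(sel, cell_areas.values, 0.0)))
        rows.append({"class": name, "code": code, "area_km2": area})
        total += area
    if total == 0:
        logger.warning("stable suitable mask is empty; composition all zero")
    for row in rows:
        row["percent"] = 100.0 * row["area_km2"] / total if total > 0 else 0.0
    return pd.DataFrame(rows)


def class_share_inside(
    stable: GridLayer, lu: LandUseLayer, class_name: str, cell_areas: GridLayer
) -> float:
    """Share of one land-use class that lies inside the stable mask, percent."""
    assert_coregistered([stable, lu.layer, cell_areas])
    code = next((c for c, n in lu.codes.items() if n == class_name), None)
    if code is None:
        raise ValueError(f"unknown land-use class {class_name!r}")
    is_class = lu.layer.values == code
    everywhere = float(np.nansum(np.where(is_class, cell_areas.values, 0.0)))
    if everywhere == 0:
        raise ValueError(f"class {class_name!r} absent from the land-use layer")
    inside = float(
        np.nansum(np.where(is_class & (stable.values == 1.0), cell_areas.values, 0.0))
    )
    return 100.0 * inside / everywhere


def suitable_area_by_landuse(
    suitability: dict[str, GridLayer],
    landuse: LandUseLayer | dict[str, LandUseLayer],
    cell_areas: GridLayer,
    theta: float = 0.4,
) -> pd.DataFrame:
    """Suitable area (P >= theta) per land-use class for each period/scenario.

    ``suitability`` maps a period (or period/scenario) label to a continuous
    suitability layer.  ``landuse`` is either one layer reused for every
    period or a per-period mapping.
    """
    rows = []
    for period, p_layer in suitability.items():
        lu = landuse[period] if isinstance(landuse, dict) else landuse
        b = binarize(p_layer, theta)
        assert_coregistered([b, lu.layer, cell_areas])
        suitable = b.values == 1.0
        for code, name in sorted(lu.codes.items()):
            sel = suitable & (lu.layer.values == code)
            area = float(np.nansum(np.where(sel, cell_areas.values, 0.0)))
            rows.append({"period": period, "class": name, "area_km2": area})
    return pd.DataFrame(rows)
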