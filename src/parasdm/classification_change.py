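"""Suitability classification, binary change detection and centroid shift.

The continuous suitability index P is cut into four levels —
unsuitable (P < 0.2), low (0.2 <= P < 0.4), medium (0.4 <= P < 0.6) and
high (P >= 0.6) — and, for range-dynamics analyses, into a single binary
"suitable" map at P >= 0.4 (the medium-and-high set).  Change between two
periods is coded per cell as 0-0 (stable unsuitable), 0-1 (expansion),
1-0 (contraction) or 1-1 (stable suitable), and range movement is tracked
through the area-weighted centroid of the suitable region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid_io import AUTHALIC_RADIUS_KM, GridLayer, assert_coregistered

__all__ = [
    "ClassificationScheme",
    "ChangeSummary",
    "classify_suitability",
    "class_areas",
    "binarize",
    "change_map",
    "suitable_centroid",
    "centroid_shift",
    "CHANGE_CODES",
]

#: integer codes of the change map
CHANGE_CODES = {
    "stable_unsuitable": 0,  # 0-0
    "expansion": 1,          # 0-1
    "contraction": 2,        # 1-0
    "stable_suitable": 3,    # 1-1
}


@dataclass(frozen=True)
class ClassificationScheme:
    breaks: tuple[float, float, float] = (0.2, 0.4, 0.6)
    labels: tuple[str, str, str, str] = ("unsuitable", "low", "medium", "high")

    def __post_init__(self) -> None:
        b = self.breaks
        if not (0.0 < b[0] < b[1] < b[2] < 1.0):
            raise ValueError("breaks must be strictly increasing within (0, 1)")
        if len(self.labels) != 4:
            raise ValueError("exactly four class labels required")


@dataclass
class ChangeSummary:
    areas: dict[str, float]        # km² per change category
    change_map: GridLayer = field(repr=False)


def classify_suitability(p: GridLayer, scheme: ClassificationScheme = ClassificationScheme()) -> GridLayer:
    """Four-level classification of P with half-open bins; nodata propagates.

    Codes: 0 = unsuitable, 1 = low, 2 = medium, 3 = high.  The lower bound
    of each class is inclusive (P = 0.2 is low, P = 0.4 medium, P = 0.6 high).
    """
    v = p.values
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    b1, b2, b3 = scheme.breaks
    out[ok] = 0.0
    out[ok & (v >= b1)] = 1.0
    out[ok & (v >= b2)] = 2.0
    out[ok & (v >= b3)] = 3.0
    return p.copy_with(out, kind="class4", name=(p.name + "_class4").lstrip("_"))


def class_areas(
    classes: GridLayer,
    cell_areas: GridLayer,
    scheme: ClassificationScheme = ClassificationScheme(),
) -> dict[str, float]:
    """Total km² per suitability class (sum of spherical cell areas)."""
    assert_coregistered([classes, cell_areas])
    out: dict[str, float] = {}
    for code, label in enumerate(scheme.labels):
        sel = classes.values == code
        out[label] = float(np.nansum(np.where(sel, cell_areas.values, 0.0)))
    return out


def binarize(p: GridLayer, theta: float = 0.4) -> GridLayer:
    """Binary suitable map: 1 where P >= theta, 0 below; nodata propagates."""
    if not (0.0 < theta < 1.0):
        raise ValueError("theta must lie in (0, 1)")
    v = p.values
    out = np.full(v.shape, np.nan)
    ok = np.isfinite(v)
    out[ok] = (v[ok] >= theta).astype(float)
    return p.copy_with(out, kind="binary", name=(p.name + "_bin").lstrip("_"))


def change_map(bin_t1: GridLayer, bin_t2: GridLayer, cell_areas: GridLayer) -> ChangeSummary:
    """Per-cell change category between two binary maps, with km² per category.

    Codes 0..3 = stable unsuitable (0-0), expansion (0-1), contraction (1-0),
    stable suitable (1-1); the four areas partition the jointly valid grid.
    """
    assert_coregistered([bin_t1, bin_t2, cell_areas])
    for lyr in (bin_t1, bin_t2):
        if lyr.kind != "binary":
            raise ValueError("change_map expects binary layers")
    a, b = bin_t1.values, bin_t2.values
    ok = np.isfinite(a) & np.isfinite(b)
    code = np.full(a.shape, np.nan)
    code[ok & (a == 0) & (b == 0)] = CHANGE_CODES["stable_unsuitable"]
    code[ok & (a == 0) & (b == 1)] = CHANGE_CODES["expansion"]
    code[ok & (a == 1) & (b == 0)] = CHANGE_CODES["contraction"]
    code[ok & (a == 1) & (b == 1)] = CHANGE_CODES["stable_suitable"]
    cmap = bin_t1.copy_with(code, kind="class4", name="change")
    areas = {
        label: float(np.nansum(np.where(code == c, cell_areas.values, 0.0)))
        for label, c in CHANGE_CODES.items()
    }
    return ChangeSummary(areas=areas, change_map=cmap)


def suitable_centroid(bin_layer: GridLayer, cell_areas: GridLayer) -> tuple[float, float]:
    """Area-weighted mean (lon, lat) of the centers of suitable cells.

    Assumes the suitable region does not straddle the antimeridian (the
    longitude span of suitable cells must be < 180 degrees; error if not).
    """
    assert_coregistered([bin_layer, cell_areas])
    sel = bin_layer.values == 1.0
    if not sel.any():
        raise ValueError("no suitable cells; centroid undefined")
    rows, cols = np.nonzero(sel)
    lons, lats = bin_layer.cell_centers()
    lon_c = lons[cols]
    lat_c = lats[rows]
    if lon_c.max() - lon_c.min() >= 180.0:
        raise ValueError("suitable region spans >= 180 degrees of longitude; "
                         "antimeridian-safe averaging not supported")
    w = cell_areas.values[rows, cols]
    return (float(np.average(lon_c, weights=w)), float(np.average(lat_c, weights=w)))


def centroid_shift(
    c1: tuple[float, float], c2: tuple[float, float], radius_km: float = AUTHALIC_RADIUS_KM
) -> tuple[float, float]:
    """Great-circle distance (km) and initial bearing (degrees, [0, 360))
    from centroid c1 = (lon, lat) to c2."""
    lon1, lat1 = map(math.radians, c1)
    lon2, lat2 = map(math.radians, c2)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    dist = 2 * radius_km * math.asin(min(1.0, math.sqrt(h)))
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    bearing = math.degrees(math.atan2(y, x)) % 360.0
    return dist, bearing
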