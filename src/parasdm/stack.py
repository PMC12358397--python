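"""Internal helpers to move between raster stacks, cell indices and matrices."""

from __future__ import annotations

import numpy as np

from .grid_io import GridLayer, assert_coregistered
from .occurrences import OccurrenceSet

__all__ = [
    "joint_valid_mask",
    "predictor_matrix",
    "values_at_cells",
    "layer_from_valid",
    "occurrence_cells",
]


def joint_valid_mask(layers: list[GridLayer]) -> np.ndarray:
    """Cells valid (finite) in every layer."""
    assert_coregistered(layers)
    mask = np.isfinite(layers[0].values)
    for lyr in layers[1:]:
        mask &= np.isfinite(lyr.values)
    return mask


def predictor_matrix(layers: list[GridLayer]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack layers into an (n_valid, p) matrix.

    Returns (X, cells, names) where ``cells`` is (n_valid, 2) row/col indices
    of the jointly valid cells in row-major order.
    """
    mask = joint_valid_mask(layers)
    rows, cols = np.nonzero(mask)
    X = np.column_stack([lyr.values[rows, cols] for lyr in layers])
    names = [lyr.name or f"var{i}" for i, lyr in enumerate(layers)]
    return X, np.column_stack([rows, cols]), names


def values_at_cells(layers: list[GridLayer], cells: np.ndarray) -> np.ndarray:
    """Variable values (k, p) at the given (row, col) cells."""
    cells = np.atleast_2d(np.asarray(cells, dtype=int))
    return np.column_stack([lyr.values[cells[:, 0], cells[:, 1]] for lyr in layers])


def layer_from_valid(template: GridLayer, cells: np.ndarray, values: np.ndarray,
                     kind: str = "continuous", name: str = "") -> GridLayer:
    """Scatter per-cell values back onto the grid; other cells are nodata."""
    out = np.full(template.shape, np.nan)
    cells = np.atleast_2d(np.asarray(cells, dtype=int))
    out[cells[:, 0], cells[:, 1]] = values
    return template.copy_with(out, kind=kind, name=name)


def occurrence_cells(occ: OccurrenceSet, template: GridLayer,
                     unique: bool = True) -> np.ndarray:
    """(row, col) cell indices of occurrence points inside the grid."""
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for lon, lat, _ in occ.records:
        idx = template.cell_index(lon, lat)
        if idx is None:
            continue
        if unique:
            if idx in seen:
                continue
            seen.add(idx)
        out.append(idx)
    return np.array(out, dtype=int).reshape(-1, 2)
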