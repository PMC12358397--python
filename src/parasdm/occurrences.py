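"""Occurrence record ingestion, deduplication, masking and spatial thinning.

Presence-only records arrive as delimited text (species, longitude,
latitude).  Before modelling they are deduplicated, clipped to a study
region mask, and thinned so at most one record remains per analysis-grid
cell — the standard defence against spatially redundant, opportunistically
collected points.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import pandas as pd

from .grid_io import GridLayer

__all__ = ["OccurrenceSet", "read_occurrences", "deduplicate", "filter_to_region", "thin_to_grid"]

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence points for one species in geographic coordinates."""

    species: str
    records: list[tuple[float, float, str]] = field(default_factory=list)  # (lon, lat, source)

    def __post_init__(self) -> None:
        for lon, lat, _ in self.records:
            if not (-180.0 <= lon < 360.0):
                raise ValueError(f"longitude {lon} outside [-180, 360)")
            if not (-90.0 <= lat <= 90.0):
                raise ValueError(f"latitude {lat} outside [-90, 90]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> list[float]:
        return [r[0] for r in self.records]

    @property
    def lats(self) -> list[float]:
        return [r[1] for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "longitude": self.lons,
                "latitude": self.lats,
                "source": [r[2] for r in self.records],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_occurrences(path, delimiter: str | None = None) -> OccurrenceSet:
    """Parse a delimited occurrence table with header species,longitude,latitude.

    Comma is the default delimiter; tab is accepted.  Rows whose coordinates
    do not parse are dropped and counted in a log message.  Missing required
    columns raise ValueError.
    """
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        if delimiter is None:
            delimiter = "\t" if ("\t" in sample.splitlines()[0] if sample else False) else ","
        reader = csv.DictReader(fh, delimiter=delimiter)
        cols = [c.strip().lower() for c in (reader.fieldnames or [])]
        required = {"species", "longitude", "latitude"}
        if not required.issubset(cols):
            raise ValueError(
                f"{path}: missing required columns {sorted(required - set(cols))}"
            )
        colmap = {c.strip().lower(): c for c in reader.fieldnames}
        species = ""
        records: list[tuple[float, float, str]] = []
        dropped = 0
        for row in reader:
            sp = (row[colmap["species"]] or "").strip()
            if sp and not species:
                species = sp
            try:
                lon = float(row[colmap["longitude"]])
                lat = float(row[colmap["latitude"]])
            except (TypeError, ValueError):
                dropped += 1
                continue
            if not (-180.0 <= lon < 360.0 and -90.0 <= lat <= 90.0):
                dropped += 1
                continue
            src = row.get(colmap.get("source", ""), "") or ""
            records.append((lon, lat, src))
    if dropped:
        logger.warning("%s: dropped %d rows with unparseable coordinates", path, dropped)
    return OccurrenceSet(species=species, records=records)


def deduplicate(occ: OccurrenceSet) -> OccurrenceSet:
    """Collapse exact (lon, lat) duplicates, keeping first appearance order."""
    seen: set[tuple[float, float]] = set()
    out = []
    for rec in occ.records:
        key = (rec[0], rec[1])
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return OccurrenceSet(species=occ.species, records=out)


def filter_to_region(occ: OccurrenceSet, mask: GridLayer) -> OccurrenceSet:
    """Keep records whose containing cell has mask value 1.

    Records falling outside the grid extent, in nodata cells, or in mask=0
    cells are removed.
    """
    if mask.kind != "binary":
        raise ValueError("region mask must be a binary layer")
    out = []
    for rec in occ.records:
        idx = mask.cell_index(rec[0], rec[1])
        if idx is None:
            continue
        if mask.values[idx] == 1.0:
            out.append(rec)
    return OccurrenceSet(species=occ.species, records=out)


def thin_to_grid(occ: OccurrenceSet, template: GridLayer) -> OccurrenceSet:
    """Spatial thinning: retain at most one record per template grid cell.

    Within a cell the first record in input order wins (deterministic);
    records outside the grid extent are dropped.  Idempotent.
    """
    occupied: set[tuple[int, int]] = set()
    out = []
    for rec in occ.records:
        idx = template.cell_index(rec[0], rec[1])
        if idx is None:
            continue
        if idx not in occupied:
            occupied.add(idx)
            out.append(rec)
    return OccurrenceSet(species=occ.species, records=out)
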