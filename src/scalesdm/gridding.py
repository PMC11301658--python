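"""Build the cell-level presence-absence dataset from tracks and sightings.

Survey effort and sightings are referenced to a regular grid (default
4 km x 4 km).  Each on-effort track segment is split at cell boundaries and
contributes a searched area of ``length_in_cell * strip_width``, where the
strip width is twice the year's effective strip width (ESW) for two-sided
observation and once the ESW when only one side of the plane was monitored.
Sightings become a binary presence flag per cell and survey period; cells
with effort but no sightings are absences, cells never surveyed are dropped.

Cell membership uses the half-open convention ``[x0, x0+c) x [y0, y0+c)`` so
boundary points belong to exactly one cell.  A cell surveyed in two years
yields two rows (year is a model covariate downstream).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from .raster import RasterField

__all__ = ["GridSpec", "assign_effort", "assign_presence", "merge_years",
           "build_cell_table"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Regular analysis grid: lower-left origin (km), cell size (km), extent."""

    origin: tuple[float, float] = (0.0, 0.0)
    cell_km: float = 4.0
    nx: int = 1
    ny: int = 1

    def __post_init__(self):
        if self.cell_km <= 0:
            raise ValueError("cell_km must be > 0")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid extent must be at least 1x1")

    def cell_of(self, x, y):
        """(row, col) of the containing cell; half-open membership."""
        col = np.floor((np.asarray(x, float) - self.origin[0]) / self.cell_km).astype(int)
        row = np.floor((np.asarray(y, float) - self.origin[1]) / self.cell_km).astype(int)
        return row, col

    def inside(self, row, col):
        return (row >= 0) & (row < self.ny) & (col >= 0) & (col < self.nx)

    def cell_id(self, row, col):
        return row * self.nx + col

    def centroid(self, row, col):
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_km
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_km
        return x, y


def _split_segment(grid: GridSpec, x0, y0, x1, y1):
    """Split one segment at grid lines; yield (row, col, length_km) pieces."""
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0.0:
        return []
    c = grid.cell_km
    # parameter values t in (0,1) where the segment crosses a grid line
    ts = [0.0, 1.0]
    for (p0, p1, o) in ((x0, x1, grid.origin[0]), (y0, y1, grid.origin[1])):
        if p1 != p0:
            k_lo = int(np.ceil((min(p0, p1) - o) / c))
            k_hi = int(np.floor((max(p0, p1) - o) / c))
            for k in range(k_lo, k_hi + 1):
                t = (o + k * c - p0) / (p1 - p0)
                if 0.0 < t < 1.0:
                    ts.append(t)
    ts = np.unique(ts)
    pieces = []
    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        row, col = grid.cell_of(x0 + tm * (x1 - x0), y0 + tm * (y1 - y0))
        pieces.append((int(row), int(col), (tb - ta) * length))
    return pieces


def assign_effort(
    segments: pd.DataFrame,
    grid: GridSpec,
    esw_by_year: dict[str, float],
) -> pd.DataFrame:
    """Per cell-year searched area (km^2) from track segments and ESWs.

    ``segments`` needs columns ``x0, y0, x1, y1`` (km), ``year``, ``date``
    and ``side`` ("both" for two-sided observation, anything else for
    one-sided).  ``esw_by_year`` maps year label to ESW in metres.  Returns
    one row per (cell, year) with ``effort_km2`` and the list of survey
    dates touching the cell.  Segments wholly outside the grid are logged
    and dropped.
    """
    required = {"x0", "y0", "x1", "y1", "year", "date", "side"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segments missing columns: {sorted(missing)}")
    acc: dict[tuple, float] = {}
    date_acc: dict[tuple, dict[str, float]] = {}
    n_dropped = 0
    for seg in segments.itertuples(index=False):
        esw_km = esw_by_year[str(seg.year)] / 1000.0
        width = 2.0 * esw_km if seg.side == "both" else esw_km
        any_inside = False
        for row, col, length in _split_segment(grid, seg.x0, seg.y0, seg.x1, seg.y1):
            if not grid.inside(row, col):
                continue
            any_inside = True
            key = (row, col, str(seg.year))
            acc[key] = acc.get(key, 0.0) + length * width
            date_acc.setdefault(key, {})
            d = date_acc[key]
            d[str(seg.date)] = d.get(str(seg.date), 0.0) + length * width
        if not any_inside:
            n_dropped += 1
    if n_dropped:
        logger.warning("%d segments fell entirely outside the grid", n_dropped)
    rows = []
    for (row, col, year), area in sorted(acc.items()):
        x, y = grid.centroid(row, col)
        dates = date_acc[(row, col, year)]
        rows.append(
            {
                "cell_id": int(grid.cell_id(row, col)),
                "row": row,
                "col": col,
                "x": float(x),
                "y": float(y),
                "year": year,
                "effort_km2": area,
                "dates": sorted(dates),
                "date_weights": [dates[d] for d in sorted(dates)],
            }
        )
    return pd.DataFrame(rows)


def assign_presence(
    sightings: pd.DataFrame, grid: GridSpec, effort: pd.DataFrame
) -> pd.DataFrame:
    """Attach a binary presence flag per cell-year to the effort table.

    ``sightings`` needs ``x_km, y_km, year``.  Presence is 1 iff at least one
    sighting fell in the cell in that year; surveyed cells without sightings
    are 0.  A sighting in a cell with no recorded effort is kept and warned
    about (it still creates no row — only surveyed cells enter the dataset).
    """
    out = effort.copy()
    out["presence"] = 0
    if len(sightings):
        row, col = grid.cell_of(sightings["x_km"].to_numpy(),
                                sightings["y_km"].to_numpy())
        keys = set(
            zip(row.tolist(), col.tolist(), sightings["year"].astype(str).tolist())
        )
        surveyed = set(zip(out["row"], out["col"], out["year"].astype(str)))
        orphan = keys - surveyed
        if orphan:
            warnings.warn(
                f"{len(orphan)} sighting cell(s) have no recorded effort; "
                "check effort assignment"
            )
        mask = [
            (r, c, y) in keys
            for r, c, y in zip(out["row"], out["col"], out["year"].astype(str))
        ]
        out.loc[mask, "presence"] = 1
    return out


def merge_years(tables: list[pd.DataFrame], grid: GridSpec | None = None) -> pd.DataFrame:
    """Stack per-year cell tables; rows stay keyed by (cell, year)."""
    if not tables:
        raise ValueError("no tables to merge")
    cols0 = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols0:
            raise ValueError("cell tables have mismatched columns (grid mismatch?)")
    merged = pd.concat(tables, ignore_index=True)
    dup = merged.duplicated(subset=["cell_id", "year"])
    if dup.any():
        raise ValueError("duplicate (cell, year) rows after merge")
    return merged


def build_cell_table(
    segments: pd.DataFrame,
    sightings: pd.DataFrame,
    grid: GridSpec,
    esw_by_year: dict[str, float],
    depth: RasterField | None = None,
) -> pd.DataFrame:
    """Full cell-observation table: effort, presence and centroid depth.

    Depth is sampled at the cell centroid, positive metres below sea level.
    """
    eff = assign_effort(segments, grid, esw_by_year)
    if eff.empty:
        raise ValueError("no effort fell inside the grid")
    tab = assign_presence(sightings, grid, eff)
    if depth is not None:
        tab["depth_m"] = depth.value_at(tab["x"].to_numpy(), tab["y"].to_numpy())
    return tab
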