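"""Planar raster fields and the spatial/temporal operations used to build
multi-scale oceanographic covariates.

A :class:`RasterField` is a single georeferenced grid of one variable at one
time (a day, a month, or a whole survey period), on a planar km coordinate
system.  Row 0 is the southernmost row; ``origin`` is the lower-left corner
of cell ``(0, 0)``.  Missing values are NaN.

The three operations mirror the standard covariate-engineering steps of
multi-scale habitat modelling:

* :func:`aggregate_spatial` — block-mean coarsening (e.g. a 5 km product
  aggregated by factors 4 and 8 to 20 and 40 km; a ~7 km product by 3 and 6);
* :func:`composite_temporal` — monthly or whole-period means of daily layers;
* :func:`front_index` — Horn's 3x3 gradient magnitude of SST, a thermal-front
  proxy, in degC per km.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import warnings
from collections.abc import Sequence

import numpy as np

__all__ = [
    "RasterField",
    "RasterStack",
    "aggregate_spatial",
    "composite_temporal",
    "front_index",
]


@dataclasses.dataclass
class RasterField:
    """One variable on one grid at one time (or composite period).

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Cell values; NaN marks missing cells.
    origin : (float, float)
        (x0, y0) of the lower-left corner, km.
    cell_km : float
        Cell edge length, km (> 0).
    name : str
        Variable name (e.g. ``"sst"``).
    time : str
        ISO date for daily layers, ``"YYYY-MM"`` for monthly composites, or a
        free period label such as ``"2016-period"``.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_km: float
    name: str = "var"
    time: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (ny, nx)")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean missing-value mask (True where missing)."""
        return np.isnan(self.values)

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/column of the cell containing each point, half-open convention."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        col = np.floor((x - self.origin[0]) / self.cell_km).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_km).astype(int)
        return row, col

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Raster value at point(s); NaN outside the grid."""
        row, col = self.cell_index(x, y)
        ny, nx = self.values.shape
        ok = (row >= 0) & (row < ny) & (col >= 0) & (col < nx)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[ok] = self.values[row[ok], col[ok]]
        return out


class RasterStack:
    """An ordered stack of daily :class:`RasterField` layers on one grid."""

    def __init__(self, layers: Sequence[RasterField]):
        if not layers:
            raise ValueError("empty stack")
        g0 = (layers[0].origin, layers[0].cell_km, layers[0].shape)
        for lay in layers:
            if (lay.origin, lay.cell_km, lay.shape) != g0:
                raise ValueError("all layers must share one grid")
        self.layers = list(layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    @property
    def dates(self) -> list[str]:
        return [lay.time for lay in self.layers]

    @property
    def name(self) -> str:
        return self.layers[0].name

    def by_date(self) -> dict[str, RasterField]:
        return {lay.time: lay for lay in self.layers}

    def map(self, fn) -> "RasterStack":
        """Apply a RasterField -> RasterField function to every layer."""
        return RasterStack([fn(lay) for lay in self.layers])


def aggregate_spatial(field: RasterField, factor: int) -> RasterField:
    """Coarsen a raster by averaging non-overlapping ``factor x factor`` blocks.

    Blocks are anchored at the raster origin (index 0,0); partial blocks at the
    far edges are averaged over the cells available.  A block whose members are
    all missing stays missing.  The output cell size is ``factor * cell_km``.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    ny, nx = field.shape
    if factor > max(ny, nx):
        raise ValueError(f"factor {factor} exceeds grid size {field.shape}")
    if factor == 1:
        return dataclasses.replace(field, values=field.values.copy())
    oy = (ny + factor - 1) // factor
    ox = (nx + factor - 1) // factor
    padded = np.full((oy * factor, ox * factor), np.nan)
    padded[:ny, :nx] = field.values
    blocks = padded.reshape(oy, factor, ox, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        out = np.nanmean(blocks, axis=(1, 3))
    return RasterField(
        values=out,
        origin=field.origin,
        cell_km=field.cell_km * factor,
        name=field.name,
        time=field.time,
    )


def _month_label(date: str) -> str:
    return _dt.date.fromisoformat(date).strftime("%Y-%m")


def composite_temporal(
    stack: RasterStack, mode: str, period_label: str = "period"
) -> list[RasterField]:
    """Cellwise mean of non-missing daily values, per month or over the period.

    ``mode="monthly"`` returns one layer per calendar month present in the
    stack (time label ``YYYY-MM``); ``mode="period"`` returns a single layer
    averaging every day.  Days with gaps contribute where observed; a cell
    missing on every contributing day stays missing.
    """
    if mode not in {"monthly", "period"}:
        raise ValueError("mode must be 'monthly' or 'period'")
    groups: dict[str, list[RasterField]] = {}
    if mode == "period":
        groups[period_label] = list(stack)
    else:
        for lay in stack:
            groups.setdefault(_month_label(lay.time), []).append(lay)
    out = []
    for label in sorted(groups):
        members = groups[label]
        cube = np.stack([m.values for m in members])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(cube, axis=0)
        if np.isnan(mean).all():
            warnings.warn(f"composite '{label}' is entirely missing")
        out.append(
            RasterField(
                values=mean,
                origin=members[0].origin,
                cell_km=members[0].cell_km,
                name=members[0].name,
                time=label,
            )
        )
    return out


def front_index(sst: RasterField) -> RasterField:
    """Thermal-front proxy: Horn's 3x3 gradient magnitude of SST, degC/km.

    For the 3x3 neighbourhood ``[[a,b,c],[d,e,f],[g,h,i]]`` of each cell::

        gx = ((c + 2f + i) - (a + 2d + g)) / (8 * dx)
        gy = ((g + 2h + i) - (a + 2b + c)) / (8 * dy)

    with slope ``sqrt(gx^2 + gy^2)``.  Edges use nearest-neighbour padding.
    NaNs propagate through the kernel, so a cell with any missing neighbour is
    missing in the output.
    """
    ny, nx = sst.shape
    if ny < 3 or nx < 3:
        raise ValueError("front index needs at least a 3x3 raster")
    v = np.pad(sst.values, 1, mode="edge")
    # rows increase northwards; a..i laid out with g,h,i the northern row
    a = v[:-2, :-2]
    b = v[:-2, 1:-1]
    c = v[:-2, 2:]
    d = v[1:-1, :-2]
    f = v[1:-1, 2:]
    g = v[2:, :-2]
    h = v[2:, 1:-1]
    i = v[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * sst.cell_km)
    gy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * sst.cell_km)
    slope = np.hypot(gx, gy)
    return RasterField(
        values=slope,
        origin=sst.origin,
        cell_km=sst.cell_km,
        name="fronts",
        time=sst.time,
    )


def stack_to_netcdf(stack: RasterStack, path) -> None:
    """Write a daily stack as a CF-style NetCDF cube (time, y, x)."""
    import pandas as pd
    import xarray as xr

    first = stack[0]
    ny, nx = first.shape
    x = first.origin[0] + (np.arange(nx) + 0.5) * first.cell_km
    y = first.origin[1] + (np.arange(ny) + 0.5) * first.cell_km
    da = xr.DataArray(
        np.stack([lay.values for lay in stack]),
        dims=("time", "y", "x"),
        coords={"time": pd.to_datetime(stack.dates), "y": y, "x": x},
        name=stack.name,
        attrs={"cell_km": first.cell_km,
               "origin_x": first.origin[0], "origin_y": first.origin[1]},
    )
    da.to_dataset().to_netcdf(path, engine="scipy")


def stack_from_netcdf(path, var: str | None = None) -> RasterStack:
    """Read a (time, y, x) NetCDF cube back into a RasterStack."""
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy")
    name = var or next(iter(ds.data_vars))
    da = ds[name]
    cell = float(da.attrs.get("cell_km", float(da.x[1] - da.x[0])))
    origin = (float(da.attrs.get("origin_x", float(da.x[0]) - cell / 2)),
              float(da.attrs.get("origin_y", float(da.y[0]) - cell / 2)))
    layers = [
        RasterField(values=np.asarray(da.isel(time=i)), origin=origin,
                    cell_km=cell, name=name,
                    time=str(da.time.values[i])[:10])
        for i in range(da.sizes["time"])
    ]
    ds.close()
    return RasterStack(layers)
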