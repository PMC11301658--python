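"""Multi-scale covariate engineering and attachment to grid cells.

Every oceanographic variable is carried at 3 spatial x 3 temporal = 9 scale
combinations: spatial levels 5, 20 and 40 km (block aggregation of the
native product: factors 4 and 8 for a ~5 km source, 3 and 6 for a ~7 km
source) and temporal levels daily, monthly and survey-period (means of daily
layers).  Candidate models are labelled ``<var><km><d|m|p>`` — e.g.
``sst5d``, ``sst20m``, ``sst40p``.

Cell attachment takes the value of the (aggregated, composited) raster cell
containing each 4-km cell centroid.  At the daily scale a cell surveyed on
several days gets the effort-weighted mean over its survey dates; monthly
uses the same weighting over the months those dates fall in.  Rows with any
missing value are excluded per covariate, so each oceanographic variable has
its own dataset (and its own base-model comparison).

Chlorophyll-a and mixed-layer depth are log-transformed before modelling;
every covariate (plus depth and effort) is then standardised to zero mean
and unit variance over the retained rows.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging

import numpy as np
import pandas as pd

from .raster import RasterField, RasterStack, aggregate_spatial, composite_temporal

__all__ = [
    "SPATIAL_SCALES",
    "TEMPORAL_SCALES",
    "scale_label",
    "aggregation_factors",
    "ScaleCube",
    "build_scale_cube",
    "extract_at_cells",
    "standardise",
    "transform_and_standardise",
    "prepare_covariate_dataset",
    "LOG_TRANSFORMED",
]

logger = logging.getLogger(__name__)

SPATIAL_SCALES = (5, 20, 40)            # km
TEMPORAL_SCALES = ("daily", "monthly", "period")
LOG_TRANSFORMED = ("chla", "mld")       # strictly positive, long-tailed


def scale_label(var: str, spatial: int, temporal: str) -> str:
    """Candidate label, e.g. ('sst', 40, 'monthly') -> 'sst40m'."""
    return f"{var}{spatial}{temporal[0]}"


def aggregation_factors(source_cell_km: float) -> dict[int, int]:
    """Block-aggregation factor per target spatial level for a source grid.

    ~5 km sources use factors 1/4/8; ~7 km sources use 1/3/6 (their native
    resolution stands in for the 5-km level).  Other resolutions round
    ``target / source`` to the nearest integer (minimum 1).
    """
    if abs(source_cell_km - 5.0) < 1.0:
        return {5: 1, 20: 4, 40: 8}
    if abs(source_cell_km - 7.0) < 1.0:
        return {5: 1, 20: 3, 40: 6}
    return {s: max(1, round(s / source_cell_km)) for s in SPATIAL_SCALES}


@dataclasses.dataclass
class ScaleCube:
    """All 9 scale combinations of one variable, per survey year.

    ``daily[(year, s)]`` maps date -> field; ``monthly[(year, s)]`` maps
    month label -> field; ``period[(year, s)]`` is a single field.
    """

    var: str
    daily: dict[tuple[str, int], dict[str, RasterField]]
    monthly: dict[tuple[str, int], dict[str, RasterField]]
    period: dict[tuple[str, int], RasterField]

    def lookup(self, year: str, spatial: int, temporal: str,
               date: str | None = None) -> RasterField:
        if temporal == "daily":
            return self.daily[(year, spatial)][date]
        if temporal == "monthly":
            month = _dt.date.fromisoformat(date).strftime("%Y-%m")
            return self.monthly[(year, spatial)][month]
        return self.period[(year, spatial)]


def build_scale_cube(
    stacks_by_year: dict[str, RasterStack], var: str | None = None
) -> ScaleCube:
    """Aggregate and composite one variable's daily stacks to all 9 scales."""
    if not stacks_by_year:
        raise ValueError("no stacks supplied")
    var = var or next(iter(stacks_by_year.values())).name
    daily: dict = {}
    monthly: dict = {}
    period: dict = {}
    for year, stack in stacks_by_year.items():
        factors = aggregation_factors(stack[0].cell_km)
        for s in SPATIAL_SCALES:
            agg = stack.map(lambda f, _fac=factors[s]: aggregate_spatial(f, _fac))
            daily[(year, s)] = agg.by_date()
            monthly[(year, s)] = {f.time: f for f in composite_temporal(agg, "monthly")}
            period[(year, s)] = composite_temporal(
                agg, "period", period_label=f"{year}-period"
            )[0]
    return ScaleCube(var=var, daily=daily, monthly=monthly, period=period)


def _weighted_value(fields_and_weights) -> float:
    num = den = 0.0
    for val, w in fields_and_weights:
        if np.isfinite(val):
            num += w * val
            den += w
    return num / den if den > 0 else np.nan


def extract_at_cells(cells: pd.DataFrame, cube: ScaleCube) -> pd.DataFrame:
    """Fill the 9 covariate slots for every cell-year row.

    ``cells`` needs ``x, y, year, dates, date_weights`` (from
    :func:`scalesdm.gridding.assign_effort`).  Returns a copy with one new
    column per scale combination; missing extractions are NaN (excluded
    later, per covariate).
    """
    out = cells.copy()
    for s in SPATIAL_SCALES:
        for t in TEMPORAL_SCALES:
            col = scale_label(cube.var, s, t)
            vals = np.full(len(out), np.nan)
            for i, rowt in enumerate(out.itertuples(index=False)):
                year = str(rowt.year)
                try:
                    if t == "period":
                        field = cube.lookup(year, s, t)
                        vals[i] = field.value_at(rowt.x, rowt.y)
                    else:
                        pairs = []
                        for d, w in zip(rowt.dates, rowt.date_weights):
                            field = cube.lookup(year, s, t, date=d)
                            pairs.append((field.value_at(rowt.x, rowt.y), w))
                        vals[i] = _weighted_value(pairs)
                except KeyError:
                    pass
            out[col] = vals
    return out


def standardise(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """z-score a column (sample sd, ddof=1); returns (standardised, mean, sd)."""
    v = np.asarray(values, dtype=float)
    m = float(np.mean(v))
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    if sd < 1e-12:
        raise ValueError("zero variance: cannot standardise a constant column")
    return (v - m) / sd, m, sd


def transform_and_standardise(
    df: pd.DataFrame, columns, log_columns=()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-transform listed columns, then z-score each column over the rows.

    Rows with non-positive values in a log column are excluded (count
    logged).  Returns the transformed frame and a (column, mean, sd) table.
    """
    out = df.copy()
    for col in log_columns:
        bad = out[col] <= 0
        if bad.any():
            logger.warning("%d rows with non-positive %s excluded before log",
                           int(bad.sum()), col)
            out = out[~bad].copy()
        out[col] = np.log(out[col])
    stats = []
    for col in columns:
        out[col], m, sd = standardise(out[col].to_numpy())
        stats.append({"column": col, "mean": m, "sd": sd})
    return out, pd.DataFrame(stats)


def prepare_covariate_dataset(
    cells: pd.DataFrame,
    var: str,
    extra_standardise: tuple[str, ...] = ("depth_m", "effort_km2"),
    log_transform: bool | None = None,
) -> pd.DataFrame:
    """The per-covariate modelling dataset for one oceanographic variable.

    Drops rows missing any of the variable's 9 scale columns (or depth), so
    all 9 candidate models share an identical row set; applies the log
    transform when the variable calls for it (CHLA, MLD); standardises the
    scale columns plus depth and effort.  Year stays categorical.
    """
    scale_cols = [scale_label(var, s, t) for s in SPATIAL_SCALES
                  for t in TEMPORAL_SCALES]
    missing_cols = [c for c in scale_cols + list(extra_standardise)
                    if c not in cells.columns]
    if missing_cols:
        raise ValueError(f"cells table lacks columns: {missing_cols}")
    keep = cells.dropna(subset=scale_cols + list(extra_standardise)).copy()
    n_drop = len(cells) - len(keep)
    if n_drop:
        logger.info("%s: %d rows with missing covariate values excluded",
                    var, n_drop)
    if log_transform is None:
        log_transform = var in LOG_TRANSFORMED
    log_cols = scale_cols if log_transform else []
    keep, _ = transform_and_standardise(
        keep, columns=scale_cols + list(extra_standardise), log_columns=log_cols
    )
    return keep.reset_index(drop=True)
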