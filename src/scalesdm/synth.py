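"""Synthetic survey worlds with known ground truth.

Every downstream stage (detection fitting, gridding, covariate engineering,
GAM scale selection, validation) can be exercised against data whose
generating process is known exactly:

* daily environmental fields: stationary Gaussian random fields with
  exponential spatial covariance (e-folding ``range_km``), evolving
  day-to-day as an AR(1) process, plus an optional seasonal trend —
  emulating gap-filled Level-4 oceanographic products;
* survey design: equally spaced zig-zag (or parallel) tracks within strata,
  flown at 183 m altitude and 167 km/h, chopped into dated segments;
* occupancy: animal groups placed by a logit-linear intensity in the driving
  covariate evaluated at the TRUE spatial/temporal scale, detected out to a
  500 m half-strip with a half-normal or hazard-rate detection function;
  group sizes are 1 + Poisson(0.5) (small groups, mostly singletons).

The planar km coordinate system has no geodesy; real-data use requires
pre-projected coordinates.  All randomness flows from a single integer seed
through ``numpy.random.SeedSequence`` spawns, so layer order is stable.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from collections.abc import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.fft import fft2, ifft2, next_fast_len
from scipy.special import expit
from shapely.geometry import LineString, Polygon

from .raster import RasterField, RasterStack, aggregate_spatial, composite_temporal
from .covariates import aggregation_factors

__all__ = [
    "EnvFieldSpec",
    "TruthSpec",
    "SurveyDesignSpec",
    "GaussianRandomField",
    "generate_env_stack",
    "generate_depth",
    "generate_transects",
    "simulate_sightings",
    "simulate_cell_rows",
    "default_depth_effect",
    "write_fixture_bundle",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EnvFieldSpec:
    """One synthetic daily environmental field (Level-4-like product).

    Defaults emulate a summer SST product on the Irish shelf: ~13 degC mean,
    1 degC marginal SD, ~15 km spatial decorrelation, day-to-day AR(1) of
    0.8 (anomalies persist about a week) and a slow seasonal warming trend.
    """

    name: str = "sst"
    extent_km: tuple[float, float] = (200.0, 200.0)
    cell_km: float = 5.0
    mean: float = 13.0
    sd: float = 1.0
    range_km: float = 15.0
    ar1: float = 0.8
    n_days: int = 61
    trend_per_day: float = 0.02
    start_date: str = "2016-06-01"
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.cell_km <= 0 or self.range_km <= 0:
            raise ValueError("cell_km and range_km must be > 0")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.extent_km[1] / self.cell_km)),
                int(round(self.extent_km[0] / self.cell_km)))


def default_depth_effect(depth_m: np.ndarray) -> np.ndarray:
    """Logit-scale bump for shelf waters: ~+1 shallower than 200 m, ->0 deep."""
    return expit((200.0 - np.asarray(depth_m, float)) / 60.0)


@dataclasses.dataclass(frozen=True)
class TruthSpec:
    """Ground truth for occupancy and detection.

    ``intercept`` and ``slope`` act on the logit scale on the *standardised*
    driving covariate at the true scale; defaults give a strong covariate
    effect at a moderate prevalence.  Detection defaults are a half-normal
    with a 200 m scale inside the 500 m search strip.
    """

    driving_var: str = "sst"
    spatial_km: int = 40
    temporal: str = "monthly"
    intercept: float = -2.0
    slope: float = 1.5
    depth_effect: Callable[[np.ndarray], np.ndarray] = default_depth_effect
    detection_key: str = "half-normal"
    detection_sigma: float = 200.0          # metres; inf => certain detection
    detection_b: float = 2.5                # hazard-rate shape
    truncation_w: float = 500.0             # metres
    group_size_rate: float = 0.5            # size ~ 1 + Poisson(rate)
    density_max: float = 0.15               # groups / km^2 at expit = 1

    def __post_init__(self):
        if self.spatial_km not in (5, 20, 40):
            raise ValueError("spatial_km must be one of 5, 20, 40")
        if self.temporal not in ("daily", "monthly", "period"):
            raise ValueError("temporal must be daily/monthly/period")
        if self.truncation_w <= 0:
            raise ValueError("truncation_w must be > 0")

    def g(self, dist_m: np.ndarray) -> np.ndarray:
        """Detection probability at perpendicular distance (m)."""
        d = np.asarray(dist_m, float)
        if not np.isfinite(self.detection_sigma):
            return np.ones_like(d)
        if self.detection_key == "half-normal":
            return np.exp(-(d**2) / (2.0 * self.detection_sigma**2))
        with np.errstate(divide="ignore", over="ignore"):
            out = 1.0 - np.exp(-((d / self.detection_sigma) ** (-self.detection_b)))
        return np.where(d <= 0, 1.0, out)


@dataclasses.dataclass(frozen=True)
class SurveyDesignSpec:
    """Aerial survey design: strata, track layout, platform parameters."""

    strata: Sequence[Polygon] = (Polygon([(0, 0), (200, 0), (200, 200), (0, 200)]),)
    design: str = "zig-zag"
    spacing_km: float = 25.0                # transect spacing (free parameter)
    altitude_m: float = 183.0
    speed_kmh: float = 167.0
    years: tuple[str, ...] = ("2016", "2021", "2022")
    season_start: str = "06-01"             # MM-DD within each year
    season_days: int = 61
    km_per_day: float = 800.0               # on-effort distance per flight day
    one_sided_fraction: float = 0.0
    segment_km: float = 10.0

    def __post_init__(self):
        if self.altitude_m <= 0:
            raise ValueError("altitude must be > 0")
        for poly in self.strata:
            if poly.area <= 0:
                raise ValueError("degenerate stratum with zero area")
        if self.design not in ("zig-zag", "parallel"):
            raise ValueError("design must be 'zig-zag' or 'parallel'")


# ---------------------------------------------------------------------------
# Gaussian random fields (circulant embedding)
# ---------------------------------------------------------------------------

class GaussianRandomField:
    """Stationary unit-variance GRF with exponential covariance on a grid.

    Sampling is exact (up to a clipped, practically negligible negative part
    of the embedding spectrum) via circulant embedding: the covariance is
    evaluated on an enlarged torus, its FFT gives the eigenvalues, and each
    sample is the real part of an inverse FFT of spectrally coloured complex
    white noise.  Construction cost is one FFT; each sample is one more.
    """

    def __init__(self, ny: int, nx: int, cell_km: float, range_km: float):
        pad_y = max(ny, int(math.ceil(6.0 * range_km / cell_km)))
        pad_x = max(nx, int(math.ceil(6.0 * range_km / cell_km)))
        my = next_fast_len(ny + pad_y)
        mx = next_fast_len(nx + pad_x)
        iy = np.minimum(np.arange(my), my - np.arange(my))
        ix = np.minimum(np.arange(mx), mx - np.arange(mx))
        d = cell_km * np.hypot(iy[:, None], ix[None, :])
        cov = np.exp(-d / range_km)
        e = np.real(fft2(cov))
        self.neg_fraction = float(np.sum(e < 0) / e.size)
        e = np.maximum(e, 0.0)
        self._amp = np.sqrt(e * (my * mx))
        self._shape = (my, mx)
        self.ny, self.nx = ny, nx

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        my, mx = self._shape
        xi = rng.standard_normal((my, mx)) + 1j * rng.standard_normal((my, mx))
        field = np.real(ifft2(self._amp * xi))
        return field[: self.ny, : self.nx]


_GRF_CACHE: dict[tuple, GaussianRandomField] = {}

def _grf(ny, nx, cell_km, range_km) -> GaussianRandomField:
    key = (ny, nx, float(cell_km), float(range_km))
    if key not in _GRF_CACHE:
        _GRF_CACHE[key] = GaussianRandomField(ny, nx, cell_km, range_km)
    return _GRF_CACHE[key]


def generate_env_stack(spec: EnvFieldSpec, seed: int) -> RasterStack:
    """Daily stack: AR(1)-evolving exponential-covariance fields.

    Day t has mean ``mean + trend_per_day * t`` and marginal SD ``sd``; the
    spatial anomaly follows ``a_t = ar1 * a_{t-1} + sqrt(1-ar1^2) * GRF_t``
    so every day is marginally a unit GRF and the lag-1 temporal
    autocorrelation at any cell is ``ar1``.
    """
    rng = np.random.default_rng(seed)
    ny, nx = spec.shape
    grf = _grf(ny, nx, spec.cell_km, spec.range_km)
    start = _dt.date.fromisoformat(spec.start_date)
    layers = []
    anom = grf.sample(rng)
    for t in range(spec.n_days):
        if t > 0:
            anom = spec.ar1 * anom + math.sqrt(1 - spec.ar1**2) * grf.sample(rng)
        values = spec.mean + spec.trend_per_day * t + spec.sd * anom
        layers.append(
            RasterField(
                values=values,
                origin=spec.origin,
                cell_km=spec.cell_km,
                name=spec.name,
                time=(start + _dt.timedelta(days=t)).isoformat(),
            )
        )
    return RasterStack(layers)


def generate_depth(
    extent_km: tuple[float, float] = (200.0, 200.0),
    cell_km: float = 2.0,
    seed: int = 0,
    shelf_slope: float = 2.2,      # m per km eastwards
    base_depth: float = 60.0,
    noise_sd: float = 40.0,
    noise_range_km: float = 50.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RasterField:
    """Static bathymetry: a deepening shelf plus smooth random relief.

    Positive metres below sea level; clipped at 5 m so the sea floor stays
    submerged.
    """
    rng = np.random.default_rng(seed)
    ny = int(round(extent_km[1] / cell_km))
    nx = int(round(extent_km[0] / cell_km))
    x = (np.arange(nx) + 0.5) * cell_km
    relief = _grf(ny, nx, cell_km, noise_range_km).sample(rng)
    depth = base_depth + shelf_slope * x[None, :] + noise_sd * relief
    return RasterField(
        values=np.maximum(depth, 5.0), origin=origin, cell_km=cell_km,
        name="depth", time="static",
    )


# ---------------------------------------------------------------------------
# transects
# ---------------------------------------------------------------------------

def _leg_lines(poly: Polygon, design: str, spacing: float) -> list[LineString]:
    x0, y0, x1, y1 = poly.bounds
    width = x1 - x0
    n_lines = int(math.floor(width / spacing)) + 1
    lines = []
    if design == "parallel":
        for k in range(n_lines):
            xk = x0 + k * spacing
            lines.append(LineString([(xk, y0), (xk, y1)]))
    else:  # zig-zag: alternate between bottom and top edges
        xs = [x0 + k * spacing for k in range(n_lines)]
        if xs[-1] < x1:
            xs.append(x1)
        pts = [(x, y0 if i % 2 == 0 else y1) for i, x in enumerate(xs)]
        for p, q in zip(pts[:-1], pts[1:]):
            lines.append(LineString([p, q]))
    return lines


def _chop(line: LineString, max_km: float):
    n = max(1, int(math.ceil(line.length / max_km)))
    pts = [line.interpolate(f, normalized=True) for f in np.linspace(0, 1, n + 1)]
    return [((a.x, a.y), (b.x, b.y)) for a, b in zip(pts[:-1], pts[1:])]


def generate_transects(design: SurveyDesignSpec, seed: int) -> pd.DataFrame:
    """Dated on-effort segments for every stratum and year.

    Legs are clipped to the stratum, chopped into <= ``segment_km`` pieces
    and assigned dates sequentially by the daily on-effort distance budget.
    Columns: x0, y0, x1, y1 (km), length_km, date, year, stratum, side.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for year in design.years:
        start = _dt.date.fromisoformat(f"{year}-{design.season_start}")
        dist_today = 0.0
        day = 0
        for si, poly in enumerate(design.strata):
            for line in _leg_lines(poly, design.design, design.spacing_km):
                clipped = line.intersection(poly)
                if clipped.is_empty:
                    continue
                parts = (
                    clipped.geoms if clipped.geom_type == "MultiLineString"
                    else [clipped]
                )
                for part in parts:
                    for (xa, ya), (xb, yb) in _chop(part, design.segment_km):
                        length = math.hypot(xb - xa, yb - ya)
                        if length == 0.0:
                            continue
                        if dist_today + length > design.km_per_day:
                            day = min(day + 1, design.season_days - 1)
                            dist_today = 0.0
                        dist_today += length
                        side = (
                            "both"
                            if rng.random() >= design.one_sided_fraction
                            else ("left" if rng.random() < 0.5 else "right")
                        )
                        rows.append({
                            "x0": xa, "y0": ya, "x1": xb, "y1": yb,
                            "length_km": length,
                            "date": (start + _dt.timedelta(days=day)).isoformat(),
                            "year": year, "stratum": si, "side": side,
                        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# occupancy + detection
# ---------------------------------------------------------------------------

def _true_scale_field(stack: RasterStack, truth: TruthSpec):
    """dict date -> RasterField of the driving covariate at the true scale."""
    fac = aggregation_factors(stack[0].cell_km)[truth.spatial_km]
    agg = stack.map(lambda f, _fac=fac: aggregate_spatial(f, _fac))
    if truth.temporal == "daily":
        return agg.by_date()
    if truth.temporal == "monthly":
        comp = {f.time: f for f in composite_temporal(agg, "monthly")}
        return {d: comp[d[:7]] for d in agg.dates}
    per = composite_temporal(agg, "period")[0]
    return {d: per for d in agg.dates}


def simulate_sightings(
    stacks_by_year: dict[str, RasterStack],
    depth: RasterField,
    transects: pd.DataFrame,
    truth: TruthSpec,
    seed: int,
) -> pd.DataFrame:
    """Place and detect groups along the surveyed strips.

    Along each dated segment, groups arise with intensity
    ``density_max * expit(intercept + slope * z + depth_effect)`` per km^2
    (z: the driving covariate at the true scale, standardised over the
    year's layers), uniformly across the +/-w strip, and are detected with
    probability ``g(perpendicular distance)``.  Each record carries the true
    perpendicular distance, the declination angle back-computed from the
    altitude, position, date, year, side and a zero-truncated-Poisson-like
    group size.
    """
    rng = np.random.default_rng(seed)
    w_km = truth.truncation_w / 1000.0
    fields_by_year = {y: _true_scale_field(st, truth) for y, st in stacks_by_year.items()}
    # standardise z over all layers so the logit scale is comparable
    allvals = np.concatenate([
        f.values.ravel()
        for fy in fields_by_year.values()
        for f in {id(v): v for v in fy.values()}.values()
    ])
    z_mean = float(np.nanmean(allvals))
    z_sd = float(np.nanstd(allvals))
    records = []
    altitude_m = 183.0
    for seg in transects.itertuples(index=False):
        fields = fields_by_year[str(seg.year)]
        field = fields[str(seg.date)]
        mx, my = 0.5 * (seg.x0 + seg.x1), 0.5 * (seg.y0 + seg.y1)
        zval = field.value_at(mx, my)
        dval = depth.value_at(mx, my)
        if not (np.isfinite(zval) and np.isfinite(dval)):
            continue
        z = (zval - z_mean) / (z_sd if z_sd > 0 else 1.0)
        eta = truth.intercept + truth.slope * z + truth.depth_effect(dval)
        lam = truth.density_max * expit(eta)
        length = math.hypot(seg.x1 - seg.x0, seg.y1 - seg.y0)
        strip_area = length * 2.0 * w_km
        n = rng.poisson(lam * strip_area)
        if n == 0:
            continue
        frac = rng.uniform(size=n)
        offset = rng.uniform(-w_km, w_km, size=n)
        perp_m = np.abs(offset) * 1000.0
        det = rng.uniform(size=n) < truth.g(perp_m)
        ux, uy = (seg.x1 - seg.x0) / length, (seg.y1 - seg.y0) / length
        for i in np.flatnonzero(det):
            px = seg.x0 + frac[i] * (seg.x1 - seg.x0) - offset[i] * uy
            py = seg.y0 + frac[i] * (seg.y1 - seg.y0) + offset[i] * ux
            decl = 90.0 if perp_m[i] == 0 else math.degrees(
                math.atan(altitude_m / perp_m[i])
            )
            records.append({
                "date": seg.date, "year": seg.year,
                "x_km": px, "y_km": py,
                "perp_distance_m": perp_m[i],
                "declination_deg": decl,
                "altitude_m": altitude_m,
                "group_size": 1 + rng.poisson(truth.group_size_rate),
                "side": "left" if offset[i] < 0 else "right",
            })
    cols = ["date", "year", "x_km", "y_km", "perp_distance_m",
            "declination_deg", "altitude_m", "group_size", "side"]
    return pd.DataFrame(records, columns=cols)


# ---------------------------------------------------------------------------
# cell-level generator (the scale-recovery test surface)
# ---------------------------------------------------------------------------

def simulate_cell_rows(
    truth: TruthSpec,
    env_spec: EnvFieldSpec | None = None,
    years: tuple[str, ...] = ("2016", "2021", "2022"),
    grid_cell_km: float = 4.0,
    mean_effort_km2: float = 1.4,
    seed: int = 0,
    add_noise_covariate: bool = False,
) -> pd.DataFrame:
    """Cell-year rows with known generating scale, ready for scale selection.

    Generates the driving variable's daily stacks (one per year), a static
    bathymetry, and a survey schedule assigning each 4-km cell one survey
    date with a lognormal effort area (mean ~``mean_effort_km2`` km^2, the
    searched area of a pass at a ~170 m ESW).  Observed presence combines
    occupancy at the TRUE scale with an effort-dependent encounter
    probability ``1 - exp(-effort / mean_effort)``:

        P(present) = expit(b0 + b1 * z_true + f(depth)) * (1 - exp(-E/Ebar))

    Returns the cell table with all 9 scale columns filled (plus ``noise``
    when requested: an independent field with the same covariance).
    """
    from .covariates import build_scale_cube, extract_at_cells

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(4 + len(years) * 2)
    env_spec = env_spec or EnvFieldSpec(name=truth.driving_var)
    rng = np.random.default_rng(child[0])

    stacks = {}
    noise_stacks = {}
    for i, year in enumerate(years):
        spec_y = dataclasses.replace(
            env_spec, start_date=f"{year}-{env_spec.start_date[5:]}"
        )
        stacks[year] = generate_env_stack(
            spec_y, int(child[1 + i].generate_state(1)[0] % (2**31))
        )
        if add_noise_covariate:
            # pure noise: same covariance structure, independent of occupancy,
            # and no shared seasonal trend (which would make it a season proxy)
            noise_stacks[year] = generate_env_stack(
                dataclasses.replace(spec_y, name="noise", trend_per_day=0.0),
                int(child[1 + len(years) + i].generate_state(1)[0] % (2**31)),
            )
    depth = generate_depth(
        extent_km=env_spec.extent_km,
        seed=int(child[1 + 2 * len(years)].generate_state(1)[0] % (2**31)),
        origin=env_spec.origin,
    )

    nx = int(round(env_spec.extent_km[0] / grid_cell_km))
    ny = int(round(env_spec.extent_km[1] / grid_cell_km))
    rows = []
    season_dates = [
        ( _dt.date.fromisoformat(f"{years[0]}-{env_spec.start_date[5:]}")
          + _dt.timedelta(days=t)).isoformat()[5:]
        for t in range(env_spec.n_days)
    ]
    for year in years:
        day_idx = rng.integers(0, env_spec.n_days, size=ny * nx)
        effort = rng.lognormal(
            mean=math.log(mean_effort_km2) - 0.125, sigma=0.5, size=ny * nx
        )
        k = 0
        for r in range(ny):
            for c in range(nx):
                x = env_spec.origin[0] + (c + 0.5) * grid_cell_km
                y = env_spec.origin[1] + (r + 0.5) * grid_cell_km
                rows.append({
                    "cell_id": r * nx + c, "row": r, "col": c,
                    "x": x, "y": y, "year": year,
                    "effort_km2": effort[k],
                    "dates": [f"{year}-{season_dates[day_idx[k]]}"],
                    "date_weights": [1.0],
                })
                k += 1
    cells = pd.DataFrame(rows)
    cells["depth_m"] = depth.value_at(cells["x"].to_numpy(), cells["y"].to_numpy())

    cube = build_scale_cube(stacks, var=truth.driving_var)
    cells = extract_at_cells(cells, cube)
    if add_noise_covariate:
        cells = extract_at_cells(cells, build_scale_cube(noise_stacks, var="noise"))

    # presence from the true-scale column, standardised over all rows
    true_col = f"{truth.driving_var}{truth.spatial_km}{truth.temporal[0]}"
    z = cells[true_col].to_numpy()
    z = (z - np.nanmean(z)) / np.nanstd(z)
    eta = truth.intercept + truth.slope * z + truth.depth_effect(
        cells["depth_m"].to_numpy()
    )
    p_occ = expit(eta)
    p_enc = 1.0 - np.exp(-cells["effort_km2"].to_numpy() / mean_effort_km2)
    cells["presence"] = (
        rng.uniform(size=len(cells)) < p_occ * p_enc
    ).astype(int)
    return cells


def write_fixture_bundle(out_dir, stacks_by_year, sightings, transects) -> None:
    """Write a synthetic world to disk: NetCDF raster cubes plus CSV tables.

    Sightings CSV columns: date (ISO-8601), year, x_km, y_km,
    perp_distance_m, declination_deg, altitude_m, group_size, side.
    Effort CSV: x0, y0, x1, y1, length_km, date, year, stratum, side.
    """
    from pathlib import Path

    from .raster import stack_to_netcdf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for year, stack in stacks_by_year.items():
        stack_to_netcdf(stack, out / f"{stack.name}_{year}.nc")
    sightings.to_csv(out / "sightings.csv", index=False)
    transects.to_csv(out / "effort.csv", index=False)
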