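"""Synthetic worlds: field statistics, transect geometry, detection thinning."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import Polygon

from scalesdm.synth import (EnvFieldSpec, SurveyDesignSpec, TruthSpec,
                            generate_env_stack, generate_transects,
                            simulate_cell_rows, simulate_sightings,
                            generate_depth)
from scalesdm.detection import half_normal_esw
from scalesdm.raster import RasterStack


class TestEnvFields:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            EnvFieldSpec(sd=-1.0)
        with pytest.raises(ValueError):
            EnvFieldSpec(range_km=0.0)
        with pytest.raises(ValueError):
            EnvFieldSpec(ar1=1.0)

    def test_white_noise_limit(self):
        """range -> 0: neighbouring cells are uncorrelated."""
        spec = EnvFieldSpec(extent_km=(500.0, 500.0), cell_km=5.0,
                            range_km=0.05, n_days=1, trend_per_day=0.0)
        f = generate_env_stack(spec, 1)[0].values
        c = np.mean((f[:, :-1] - f.mean()) * (f[:, 1:] - f.mean())) / f.var()
        assert abs(c) < 0.05

    def test_spatial_correlogram_oracle(self):
        """Correlation at one range of lag ~ e^-1, averaged over 10 seeds."""
        spec = EnvFieldSpec(extent_km=(200.0, 200.0), cell_km=1.0,
                            range_km=20.0, n_days=1, trend_per_day=0.0,
                            mean=0.0, sd=1.0)
        covs, vars_ = [], []
        for seed in range(10):
            f = generate_env_stack(spec, seed)[0].values
            vars_.append((f ** 2).mean())
            covs.append((f[:, :-20] * f[:, 20:]).mean())
        corr = np.mean(covs) / np.mean(vars_)
        assert corr == pytest.approx(np.exp(-1.0), abs=0.1)

    def test_temporal_ar1_oracle(self):
        """Lag-1 temporal autocorrelation ~ ar1, pooled over cells with the
        known marginal mean (avoids the sample-ACF small-n bias)."""
        spec = EnvFieldSpec(extent_km=(100.0, 100.0), cell_km=5.0,
                            ar1=0.9, n_days=120, trend_per_day=0.0)
        st = generate_env_stack(spec, 3)
        anom = np.stack([l.values for l in st]) - spec.mean
        ac = np.mean(anom[:-1] * anom[1:]) / np.mean(anom ** 2)
        assert ac == pytest.approx(0.9, abs=0.05)

    def test_marginal_moments_converge(self):
        """Mean/sd of layers approach spec values on a 200x200 grid,
        averaged over 5 seeds of independent (ar1=0) days."""
        spec = EnvFieldSpec(extent_km=(200.0, 200.0), cell_km=1.0,
                            range_km=10.0, mean=13.0, sd=1.0, n_days=3,
                            ar1=0.0, trend_per_day=0.0)
        layers = []
        for seed in range(5):
            layers += [l.values for l in generate_env_stack(spec, seed)]
        vals = np.stack(layers)
        # effective sample size per layer for the mean of an exponential-
        # covariance field: area / correlation area, with corr area
        # int exp(-d/r) dA = 2*pi*r^2
        n_eff = 15 * (200.0 * 200.0) / (2 * np.pi * 10.0 ** 2)
        assert abs(vals.mean() - 13.0) < 3.0 / np.sqrt(n_eff)
        assert abs(vals.std() - 1.0) < 3.0 / np.sqrt(2 * n_eff)

    def test_seasonal_trend(self):
        spec = EnvFieldSpec(extent_km=(100.0, 100.0), cell_km=5.0,
                            trend_per_day=0.05, n_days=41)
        st = generate_env_stack(spec, 9)
        daily_means = [l.values.mean() for l in st]
        slope = np.polyfit(np.arange(41), daily_means, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.02)

    def test_layer_dates(self):
        st = generate_env_stack(EnvFieldSpec(n_days=3), 0)
        assert st.dates == ["2016-06-01", "2016-06-02", "2016-06-03"]


class TestTransects:
    def test_endpoints_inside_stratum(self):
        poly = Polygon([(0, 0), (100, 0), (100, 60), (0, 60)])
        design = SurveyDesignSpec(strata=(poly,), years=("2016",),
                                  spacing_km=25.0)
        segs = generate_transects(design, 0)
        eps = poly.buffer(1e-6)
        from shapely.geometry import Point
        for s in segs.itertuples():
            assert eps.contains(Point(s.x0, s.y0))
            assert eps.contains(Point(s.x1, s.y1))

    def test_parallel_transect_count(self):
        """Parallel design over width W at spacing s: floor(W/s)+1 lines."""
        poly = Polygon([(0, 0), (103, 0), (103, 50), (0, 50)])
        design = SurveyDesignSpec(strata=(poly,), design="parallel",
                                  spacing_km=20.0, years=("2016",))
        segs = generate_transects(design, 0)
        assert segs["x0"].round(6).nunique() == int(103 // 20) + 1

    def test_length_scales_with_leg_count(self):
        poly = Polygon([(0, 0), (120, 0), (120, 80), (0, 80)])
        lengths = []
        for spacing in (40.0, 20.0):
            d = SurveyDesignSpec(strata=(poly,), design="parallel",
                                 spacing_km=spacing, years=("2016",))
            lengths.append(generate_transects(d, 0)["length_km"].sum())
        assert lengths[1] / lengths[0] == pytest.approx(7 / 4, rel=0.01)

    def test_degenerate_stratum_error(self):
        line = Polygon([(0, 0), (10, 0), (10, 0.0), (0, 0)])
        with pytest.raises(ValueError):
            SurveyDesignSpec(strata=(line,))


def _small_world(sigma, seed, density=3.0):
    spec = EnvFieldSpec(extent_km=(60.0, 60.0), n_days=10,
                        start_date="2016-06-01")
    stack = {"2016": generate_env_stack(spec, seed)}
    depth = generate_depth(extent_km=(60.0, 60.0), cell_km=4.0, seed=seed)
    design = SurveyDesignSpec(
        strata=(Polygon([(0, 0), (60, 0), (60, 60), (0, 60)]),),
        years=("2016",), spacing_km=15.0)
    transects = generate_transects(design, seed)
    truth = TruthSpec(detection_sigma=sigma, density_max=density,
                      temporal="daily", spatial_km=5)
    return simulate_sightings(stack, depth, transects, truth, seed + 1)


class TestSightings:
    def test_detection_thinning_matches_esw_ratio(self):
        """Detected fraction ~ ESW/w = 0.495 for half-normal sigma=200,
        w=500 (ESW 247.6 m by quadrature), pooled over 20 seeds."""
        n_all = sum(len(_small_world(np.inf, 100 + s)) for s in range(20))
        n_det = sum(len(_small_world(200.0, 100 + s)) for s in range(20))
        expected = half_normal_esw(200.0, 500.0) / 500.0
        assert expected == pytest.approx(0.495, abs=0.001)
        assert n_all > 2000
        assert n_det / n_all == pytest.approx(expected, abs=0.02)

    def test_record_schema_and_geometry(self):
        s = _small_world(200.0, 7)
        assert (s["perp_distance_m"] <= 500.0).all()
        assert (s["group_size"] >= 1).all()
        # declination back-computes the perpendicular distance
        d = 183.0 / np.tan(np.deg2rad(s["declination_deg"]))
        d[s["declination_deg"] == 90.0] = 0.0
        assert np.allclose(d, s["perp_distance_m"], atol=1e-6)

    def test_null_slope_gives_no_covariate_association(self):
        """slope = 0: logistic regression of presence on the covariate is flat."""
        import statsmodels.api as sm

        cells = simulate_cell_rows(
            TruthSpec(slope=0.0),
            env_spec=EnvFieldSpec(extent_km=(120.0, 120.0)),
            seed=21)
        z = (cells["sst40m"] - cells["sst40m"].mean()) / cells["sst40m"].std()
        X = sm.add_constant(z.to_numpy())
        fit = sm.GLM(cells["presence"].to_numpy(), X,
                     family=sm.families.Binomial()).fit()
        assert abs(fit.tvalues[1]) < 3.0


class TestCellRows:
    def test_rowcount_and_truth_association(self, small_cell_world):
        cells = small_cell_world
        assert len(cells) == 3 * 50 * 50
        assert {"sst5d", "sst20m", "sst40p", "noise40m"} <= set(cells.columns)
        # presence rate should rise with the true-scale covariate
        hi = cells.loc[cells["sst40m"] > cells["sst40m"].median(), "presence"]
        lo = cells.loc[cells["sst40m"] <= cells["sst40m"].median(), "presence"]
        assert hi.mean() > lo.mean() + 0.05

    def test_determinism(self):
        spec = EnvFieldSpec(extent_km=(80.0, 80.0), n_days=10)
        a = simulate_cell_rows(TruthSpec(), env_spec=spec, seed=5)
        b = simulate_cell_rows(TruthSpec(), env_spec=spec, seed=5)
        assert a.drop(columns=["dates", "date_weights"]).equals(
            b.drop(columns=["dates", "date_weights"]))
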