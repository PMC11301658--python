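"""Distance-sampling detection functions: geometry, MLE, ESW, selection, GOF."""

import numpy as np
import pytest
from scipy import integrate

from scalesdm.detection import (DegenerateFitError, DetectionModel,
                                DetectionResults, fit_detection_function,
                                half_normal_esw, perpendicular_distance,
                                select_detection_model)


class TestPerpendicularDistance:
    @pytest.mark.parametrize(
        "decl,alt,expected",
        [(90.0, 183.0, 0.0), (45.0, 183.0, 183.0), (30.0, 183.0, 316.97)],
    )
    def test_geometry(self, decl, alt, expected):
        assert perpendicular_distance(decl, alt) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("decl", [0.0, -5.0, 90.5])
    def test_invalid_declination(self, decl):
        with pytest.raises(ValueError):
            perpendicular_distance(decl, 183.0)

    def test_vectorised(self):
        out = perpendicular_distance([90.0, 45.0], 183.0)
        assert np.allclose(out, [0.0, 183.0])


class TestHalfNormalFit:
    def test_sigma_recovery(self, half_normal_distances):
        res = DetectionModel(half_normal_distances, key="half-normal",
                             truncation=500.0).fit()
        assert abs(res.sigma - 200.0) / 200.0 < 0.03

    def test_mle_dominates_grid(self, half_normal_distances):
        """Grid-search likelihood oracle: no grid point beats the optimiser."""
        x = half_normal_distances[:800]
        model = DetectionModel(x, key="half-normal", truncation=500.0)
        res = model.fit()
        best_grid = -np.inf
        for sigma in np.linspace(100.0, 400.0, 50):
            ll = -model._negloglik(np.array([np.log(sigma)]))
            best_grid = max(best_grid, ll)
        assert res.loglik >= best_grid - 1e-6

    def test_degenerate_input(self):
        with pytest.raises(DegenerateFitError):
            DetectionModel(np.zeros(50), key="half-normal").fit()

    def test_unit_rescaling_invariance(self, half_normal_distances):
        """Rescaling distances rescales sigma and leaves dAIC unchanged."""
        x = half_normal_distances[:1000]
        f1 = {k: fit_detection_function(x, key=k)
              for k in ("half-normal", "hazard-rate")}
        f2 = {k: fit_detection_function(2.0 * x, key=k, truncation=1000.0)
              for k in ("half-normal", "hazard-rate")}
        assert f2["half-normal"].sigma == pytest.approx(
            2.0 * f1["half-normal"].sigma, rel=1e-3)
        d1 = f1["half-normal"].aic - f1["hazard-rate"].aic
        d2 = f2["half-normal"].aic - f2["hazard-rate"].aic
        assert d1 == pytest.approx(d2, abs=0.05)


class TestHazardRateFit:
    def test_shape_recovery(self, rng):
        # hazard-rate draws by rejection from g(x)/w
        sigma, b, w = 220.0, 2.5, 500.0
        x = rng.uniform(0, w, size=120_000)
        g = 1.0 - np.exp(-((x / sigma) ** (-b)))
        keep = rng.uniform(size=x.size) < g
        res = DetectionModel(x[keep][:5000], key="hazard-rate",
                             truncation=w).fit()
        assert abs(res.sigma - sigma) / sigma < 0.10
        assert res.b >= 1.0

    def test_mle_dominates_grid(self, rng):
        sigma, b, w = 220.0, 2.5, 500.0
        x = rng.uniform(0, w, size=20_000)
        g = 1.0 - np.exp(-((x / sigma) ** (-b)))
        x = x[rng.uniform(size=x.size) < g][:600]
        model = DetectionModel(x, key="hazard-rate", truncation=w)
        res = model.fit()
        best = -np.inf
        for s in np.linspace(120.0, 400.0, 50):
            for bb in np.linspace(1.2, 6.0, 50):
                ll = -model._negloglik(np.array([np.log(s), np.log(bb - 1.0)]))
                best = max(best, ll)
        assert res.loglik >= best - 1e-6


class TestESW:
    def test_quadrature_matches_closed_form(self, half_normal_distances):
        res = fit_detection_function(half_normal_distances, key="half-normal")
        closed = half_normal_esw(res.sigma, res.truncation)
        assert abs(res.esw - closed) / closed < 1e-6

    def test_certain_detection(self, half_normal_distances):
        """sigma -> infinity limit: g == 1, ESW -> w."""
        res = fit_detection_function(half_normal_distances, key="half-normal")
        big = DetectionResults(
            key="half-normal", sigma=1e9, b=None, beta=None,
            covariate_name=None, loglik=0.0, n_params=1, esw=np.nan,
            truncation=500.0, distances=res.distances)
        esw, _ = integrate.quad(lambda x: big.g(x), 0, 500.0)
        assert esw == pytest.approx(500.0, rel=1e-9)

    def test_esw_linear_in_g(self):
        """Halving g pointwise halves the integral defining ESW."""
        sigma = 200.0
        esw, _ = integrate.quad(lambda x: np.exp(-x**2 / (2 * sigma**2)), 0, 500)
        half, _ = integrate.quad(
            lambda x: 0.5 * np.exp(-x**2 / (2 * sigma**2)), 0, 500)
        assert half == pytest.approx(esw / 2.0, rel=1e-12)


def _stub_fit(aic, covariate=False, n=100):
    n_params = 2 if covariate else 1
    return DetectionResults(
        key="half-normal", sigma=200.0, b=None,
        beta=np.array([5.3, 0.1]) if covariate else None,
        covariate_name="seastate" if covariate else None,
        loglik=-(aic - 2 * n_params) / 2.0, n_params=n_params,
        esw=250.0, truncation=500.0, distances=np.linspace(1, 499, n))


class TestModelSelection:
    def test_covariate_retained_above_two_units(self):
        base, cov = _stub_fit(1000.0), _stub_fit(997.5, covariate=True)
        assert select_detection_model([base, cov]) is cov

    def test_covariate_dropped_at_or_below_two_units(self):
        base, cov = _stub_fit(1000.0), _stub_fit(998.5, covariate=True)
        assert select_detection_model([base, cov]) is base

    def test_single_fit_identity(self):
        f = _stub_fit(1234.5)
        assert select_detection_model([f]) is f

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_detection_model([])

    def test_covariate_nesting(self, half_normal_distances):
        """A covariate model nests the plain one: its MLE loglik is >=."""
        x = half_normal_distances[:1000]
        z = np.random.default_rng(5).normal(size=x.size)
        plain = fit_detection_function(x, key="half-normal")
        withz = fit_detection_function(x, key="half-normal", covariate=z,
                                       covariate_name="z")
        assert withz.loglik >= plain.loglik - 1e-4


class TestCramerVonMises:
    def test_well_specified_p_uniformish(self):
        """p-values from data simulated under the fitted model look uniform."""
        from scipy.stats import kstest
        rng = np.random.default_rng(17)
        pvals = []
        for _ in range(30):
            x = np.abs(rng.normal(0, 200.0, 3000))
            x = x[x <= 500.0][:1000]
            res = fit_detection_function(x, key="half-normal")
            pvals.append(res.gof()[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_gross_misspecification_rejected(self):
        """Uniform distances against a near-spike g: p < 0.01."""
        x = np.linspace(1.0, 499.0, 500)
        spike = _stub_fit(0.0)
        spike.sigma = 60.0
        spike.distances = x
        stat, p = spike.gof()
        assert p < 0.01
        assert stat > 0.5

    def test_small_sample_bootstrap(self, half_normal_distances):
        res = fit_detection_function(half_normal_distances[:30],
                                     key="half-normal")
        stat, p = res.gof(n_boot=99, seed=1)
        assert 0.0 < p <= 1.0
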