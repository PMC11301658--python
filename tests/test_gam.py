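"""Penalised binary GAM: basis/penalties, IRLS fit, shrinkage, inference."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from scalesdm.gam import BinaryGAM, GamFitError, SmoothSpec, SmoothTerm


def _signal_frame(n, seed, slope=1.2, f=None):
    rng = np.random.default_rng(seed)
    x = rng.uniform(-2, 2, size=n)
    eta = -1.0 + (slope * x if f is None else f(x))
    y = (rng.uniform(size=n) < expit(eta)).astype(float)
    return pd.DataFrame({"presence": y, "x": x})


class TestBasis:
    def test_penalties_positive_semidefinite(self, rng):
        term = SmoothTerm(rng.normal(size=500), SmoothSpec("x", k=10))
        for S in (term.S_wiggle, term.S_null):
            assert np.min(np.linalg.eigvalsh(S)) >= -1e-10

    def test_columns_centred_over_data(self, rng):
        x = rng.normal(size=400)
        term = SmoothTerm(x, SmoothSpec("x", k=10))
        assert np.allclose(term.basis(x).mean(axis=0), 0.0, atol=1e-10)

    def test_full_shrinkage_limit_zeroes_the_smooth(self):
        df = _signal_frame(800, 0)
        gam = BinaryGAM.from_dataframe(df, "presence", smooths=["x"])
        res = gam.fit(lam=[1e12, 1e12])
        sl = gam.term_slices["s(x)"]
        contrib = gam.X[:, sl] @ res.params[sl]
        assert np.max(np.abs(contrib)) < 1e-6

    def test_unpenalised_matches_glm_oracle(self):
        """lam = 0 reproduces an unpenalised logistic GLM on the same basis."""
        import statsmodels.api as sm

        df = _signal_frame(600, 1)
        gam = BinaryGAM.from_dataframe(df, "presence", smooths=["x"])
        res = gam.fit(lam=[0.0, 0.0])
        glm = sm.GLM(gam.y, gam.X, family=sm.families.Binomial()).fit()
        assert res.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_k_autoreduced_with_few_distinct_values(self):
        x = np.repeat([0.0, 1.0, 2.0, 3.0, 4.0], 20)
        with pytest.warns(UserWarning, match="k reduced"):
            SmoothTerm(x, SmoothSpec("x", k=10))


class TestFit:
    def test_intercept_only_closed_form(self, presence_frame):
        res = BinaryGAM.from_dataframe(presence_frame, "presence").fit()
        assert res.params[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-8)
        assert np.allclose(res.fitted, 0.25, atol=1e-8)

    def test_aic_definition(self, presence_frame):
        res = BinaryGAM.from_dataframe(presence_frame, "presence",
                                       smooths=["x"]).fit()
        assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.edf, abs=1e-10)

    def test_single_class_error(self):
        df = pd.DataFrame({"presence": np.zeros(50), "x": np.arange(50.0)})
        with pytest.raises(GamFitError):
            BinaryGAM.from_dataframe(df, "presence", smooths=["x"])

    def test_affine_rescaling_invariance(self):
        df = _signal_frame(800, 2)
        r1 = BinaryGAM.from_dataframe(df, "presence", smooths=["x"]).fit()
        df2 = df.assign(x=3.5 * df["x"] - 7.0)
        r2 = BinaryGAM.from_dataframe(df2, "presence", smooths=["x"]).fit()
        assert np.allclose(r1.fitted, r2.fitted, atol=1e-8)

    def test_informative_covariate_lowers_aic(self):
        """On strong-signal data, adding the true covariate always helps."""
        for seed in range(20):
            df = _signal_frame(1200, seed, slope=1.5)
            base = BinaryGAM.from_dataframe(df, "presence").fit()
            full = BinaryGAM.from_dataframe(df, "presence", smooths=["x"]).fit()
            assert full.aic < base.aic

    def test_deviance_explained_null_is_zero(self, presence_frame):
        res = BinaryGAM.from_dataframe(presence_frame, "presence").fit()
        assert res.deviance_explained == pytest.approx(0.0, abs=1e-8)

    def test_deviance_matches_hand_computation(self):
        """Six-row worked example against the binomial deviance formula."""
        df = pd.DataFrame({"presence": [1.0, 0, 1, 0, 0, 1],
                           "z": [0.2, 0.5, 1.4, -0.3, -2.0, -0.1]})
        res = BinaryGAM.from_dataframe(df, "presence", parametric=["z"]).fit()
        mu = res.fitted
        y = df["presence"].to_numpy()
        hand = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
        assert res.deviance == pytest.approx(hand, abs=1e-10)
        pbar = y.mean()
        hand_null = -2.0 * 6 * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar))
        assert res.deviance_explained == pytest.approx(
            100 * (1 - hand / hand_null), abs=1e-8)


class TestPartialEffects:
    def test_effect_centred_over_data(self):
        df = _signal_frame(1000, 3)
        res = BinaryGAM.from_dataframe(df, "presence", smooths=["x"]).fit()
        pe = res.partial_effect("x", grid=df["x"].to_numpy())
        assert abs(pe["effect"].mean()) < 1e-8

    def test_linear_truth_coverage(self):
        """95% band covers a linear truth at >=90% of grid points on average
        over replicates (across-the-function Bayesian coverage)."""
        covs = []
        for seed in range(15):
            rng = np.random.default_rng(100 + seed)
            n = 2000
            x = rng.uniform(-2, 2, size=n)
            y = (rng.uniform(size=n) < expit(-1.0 + 0.8 * x)).astype(float)
            df = pd.DataFrame({"presence": y, "x": x})
            res = BinaryGAM.from_dataframe(df, "presence", smooths=["x"]).fit()
            pe = res.partial_effect("x")
            truth = 0.8 * pe["x"]
            truth = truth - truth.mean()       # effects are centred
            covs.append(((pe["lo"] <= truth) & (truth <= pe["hi"])).mean())
        assert np.mean(covs) >= 0.9

    def test_fully_shrunk_term_is_flat_zero(self):
        df = _signal_frame(500, 5)
        gam = BinaryGAM.from_dataframe(df, "presence", smooths=["x"])
        res = gam.fit(lam=[1e12, 1e12])
        pe = res.partial_effect("x")
        assert np.max(np.abs(pe["effect"])) < 1e-6

    def test_unknown_term_error(self, presence_frame):
        res = BinaryGAM.from_dataframe(presence_frame, "presence",
                                       smooths=["x"]).fit()
        with pytest.raises(KeyError):
            res.partial_effect("nope")


class TestShrinkageSelection:
    def test_noise_smooth_mostly_shrunk(self):
        """Pure-noise smooth: EDF below 0.5 in most replicates (the
        operating rate of the gamma-inflated UBRE criterion is ~80%,
        matching mgcv's ts smooths on identical data)."""
        small = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({
                "presence": (rng.uniform(size=2000) < 0.25).astype(float),
                "x": rng.normal(size=2000),
            })
            res = BinaryGAM.from_dataframe(df, "presence", smooths=["x"],
                                           gamma=1.4).fit()
            if res.edf_by_term()["s(x)"] < 0.5:
                small += 1
        assert small >= 14

    def test_smooth_pvalue_small_for_real_signal(self):
        df = _signal_frame(2000, 6, f=lambda x: np.sin(1.5 * x))
        res = BinaryGAM.from_dataframe(df, "presence", smooths=["x"]).fit()
        assert res.smooth_pvalues()["s(x)"] < 1e-4
        assert res.edf_by_term()["s(x)"] > 1.5


class TestAgainstMgcv:
    def test_matches_mgcv_on_signal_data(self, tmp_path):
        """Independent oracle: mgcv's shrinkage GAM on the same data gives
        near-identical fitted probabilities and deviance explained."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        df = _signal_frame(1500, 8, f=lambda x: 1.2 * np.tanh(2 * x))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "out.csv"
        r_code = f"""
        library(mgcv)
        d <- read.csv("{csv}")
        m <- gam(presence ~ s(x, bs="ts", k=10), family=binomial,
                 gamma=1.4, data=d, method="GCV.Cp")
        write.csv(data.frame(fitted=fitted(m),
                             dev_expl=summary(m)$dev.expl), "{out}",
                  row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", r_code], check=True,
                       capture_output=True)
        ref = pd.read_csv(out)
        res = BinaryGAM.from_dataframe(df, "presence", smooths=["x"],
                                       gamma=1.4).fit()
        corr = np.corrcoef(res.fitted, ref["fitted"])[0, 1]
        assert corr > 0.995
        assert res.deviance_explained == pytest.approx(
            100 * ref["dev_expl"].iloc[0], abs=1.0)
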