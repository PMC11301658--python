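"""Scale selection: enumerate the 9 scale combinations per covariate.

For each oceanographic variable a base model (year + smooths of effort and
depth, shrinkage splines, gamma = 1.4) is fitted on that variable's dataset,
then the variable enters as a third smooth at each of the 9 spatial x
temporal scale combinations.  Candidates are ranked by AIC; every candidate
within 2 AIC units of the best is reported as a tie (the field convention is
to discuss ties rather than resolve them — the single "best" label breaks
exact ties deterministically towards the coarser temporal, then coarser
spatial, scale).  Multicollinearity (VIF >= 2) and concurvity (> 0.8) are
flagged per term.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import SPATIAL_SCALES, TEMPORAL_SCALES, scale_label
from .gam import BinaryGAM, BinaryGAMResults, SmoothSpec

__all__ = [
    "CandidateResult",
    "SelectionReport",
    "fit_base_model",
    "enumerate_scales",
    "rank_and_tie",
    "run_scale_selection",
    "vif",
    "concurvity",
]

logger = logging.getLogger(__name__)

_TEMPORAL_RANK = {"daily": 0, "monthly": 1, "period": 2}


def fit_base_model(
    data: pd.DataFrame,
    effort_col: str = "effort_km2",
    depth_col: str = "depth_m",
    k: int = 10,
    gamma: float = 1.4,
) -> BinaryGAMResults:
    """Base habitat model: year (parametric) + smooths of effort and depth."""
    model = BinaryGAM.from_dataframe(
        data,
        response="presence",
        parametric=["year"],
        smooths=[SmoothSpec(effort_col, k=k), SmoothSpec(depth_col, k=k)],
        gamma=gamma,
    )
    return model.fit()


@dataclasses.dataclass(eq=False)
class CandidateResult:
    """One covariate x scale combination: fit, AIC and diagnostics."""

    var: str
    spatial_km: int
    temporal: str
    label: str
    fit: BinaryGAMResults
    aic: float
    delta_aic: float = np.nan
    vif: dict[str, float] = dataclasses.field(default_factory=dict)
    concurvity: dict[str, float] = dataclasses.field(default_factory=dict)

    @property
    def flags(self) -> list[str]:
        out = []
        for term, v in self.vif.items():
            if v >= 2.0:
                out.append(f"VIF>=2: {term} ({v:.2f})")
        for term, v in self.concurvity.items():
            if v > 0.8:
                out.append(f"concurvity>0.8: {term} ({v:.2f})")
        return out


@dataclasses.dataclass(eq=False)
class SelectionReport:
    """Ranked candidates for one covariate, with its base-model comparison."""

    var: str
    base: BinaryGAMResults
    candidates: list[CandidateResult]
    best: CandidateResult
    tie_set: list[CandidateResult]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append({
                "covariate": self.var,
                "label": c.label,
                "spatial_km": c.spatial_km,
                "temporal": c.temporal,
                "aic": c.aic,
                "delta_aic": c.delta_aic,
                "edf": c.fit.edf,
                "deviance_explained_pct": c.fit.deviance_explained,
                "in_tie_set": c in self.tie_set,
                "flags": "; ".join(c.flags),
            })
        rows.append({
            "covariate": self.var, "label": "base", "spatial_km": np.nan,
            "temporal": "", "aic": self.base.aic,
            "delta_aic": self.base.aic - self.best.aic,
            "edf": self.base.edf,
            "deviance_explained_pct": self.base.deviance_explained,
            "in_tie_set": False, "flags": "",
        })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [f"Scale selection for '{self.var}' "
                 f"(n = {self.base.model.n} rows)"]
        lines.append(df.to_string(index=False,
                                  float_format=lambda v: f"{v:.2f}"))
        ties = ", ".join(c.label for c in self.tie_set)
        lines.append(f"best: {self.best.label}; tie set (dAIC < 2): {ties}")
        return "\n".join(lines)


def enumerate_scales(
    data: pd.DataFrame,
    var: str,
    effort_col: str = "effort_km2",
    depth_col: str = "depth_m",
    k: int = 10,
    gamma: float = 1.4,
) -> list[CandidateResult]:
    """Fit base + f(covariate at scale) for all available scale combinations."""
    out = []
    for s in SPATIAL_SCALES:
        for t in TEMPORAL_SCALES:
            col = scale_label(var, s, t)
            if col not in data.columns or data[col].isna().any():
                warnings.warn(f"scale slot '{col}' missing; candidate skipped")
                continue
            model = BinaryGAM.from_dataframe(
                data,
                response="presence",
                parametric=["year"],
                smooths=[SmoothSpec(effort_col, k=k), SmoothSpec(depth_col, k=k),
                         SmoothSpec(col, k=k)],
                gamma=gamma,
            )
            fit = model.fit()
            out.append(
                CandidateResult(
                    var=var, spatial_km=s, temporal=t, label=col,
                    fit=fit, aic=fit.aic,
                )
            )
    return out


def rank_and_tie(
    candidates: list[CandidateResult], base: BinaryGAMResults, var: str
) -> SelectionReport:
    """Sort candidates by AIC; tie set = all within 2 AIC units of the best."""
    if not candidates:
        raise ValueError("no candidates to rank")
    ranked = sorted(
        candidates,
        key=lambda c: (
            round(c.aic, 10),
            -_TEMPORAL_RANK[c.temporal],
            -c.spatial_km,
        ),
    )
    best = ranked[0]
    for c in ranked:
        c.delta_aic = c.aic - best.aic
    tie = [c for c in ranked if c.delta_aic < 2.0]
    return SelectionReport(var=var, base=base, candidates=ranked,
                           best=best, tie_set=tie)


def vif(data: pd.DataFrame, columns: list[str]) -> dict[str, float]:
    """Variance inflation factors, 1/(1 - R^2), on observed covariate values."""
    if len(columns) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    out = {}
    for col in columns:
        others = [c for c in columns if c != col]
        X = sm.add_constant(data[others].to_numpy(dtype=float))
        r2 = sm.OLS(data[col].to_numpy(dtype=float), X).fit().rsquared
        out[col] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def concurvity(fit: BinaryGAMResults) -> dict[str, float]:
    """Per-smooth concurvity in [0, 1].

    For each smooth, the proportion of its fitted-component variance that
    projection onto the column space of all other model terms can explain
    (an "observed"-style measure; 1 means the term is fully reproducible
    from the rest of the model, the nonlinear analogue of collinearity).
    A model with a single smooth scores 0 by convention.
    """
    model = fit.model
    smooth_names = [f"s({t.name})" for t in model.smooth_terms]
    if len(smooth_names) < 2:
        return {name: 0.0 for name in smooth_names}
    out = {}
    for name in smooth_names:
        sl = model.term_slices[name]
        f_j = model.X[:, sl] @ fit.params[sl]
        other_cols = np.concatenate(
            [model.X[:, : sl.start], model.X[:, sl.stop :]], axis=1
        )
        denom = float(f_j @ f_j)
        if denom < 1e-12:
            out[name] = 0.0
            continue
        coef, *_ = np.linalg.lstsq(other_cols, f_j, rcond=None)
        proj = other_cols @ coef
        out[name] = float(np.clip((proj @ proj) / denom, 0.0, 1.0))
    return out


def run_scale_selection(
    data: pd.DataFrame,
    var: str,
    effort_col: str = "effort_km2",
    depth_col: str = "depth_m",
    k: int = 10,
    gamma: float = 1.4,
) -> SelectionReport:
    """Base fit, 9-candidate enumeration, ranking and diagnostics on the best.

    ``data`` must be the variable's own prepared dataset (rows with missing
    values for this variable already excluded, covariates standardised) —
    the base model is recomputed on it so base and candidates share rows.
    """
    base = fit_base_model(data, effort_col=effort_col, depth_col=depth_col,
                          k=k, gamma=gamma)
    candidates = enumerate_scales(data, var, effort_col=effort_col,
                                  depth_col=depth_col, k=k, gamma=gamma)
    report = rank_and_tie(candidates, base, var)
    best = report.best
    best.vif = vif(data, [effort_col, depth_col, best.label])
    best.concurvity = concurvity(best.fit)
    return report
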