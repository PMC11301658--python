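"""Binary (logit) generalised additive models with shrinkage smooths.

The presence-absence habitat model has the structure::

    logit P(Y = 1) = b0 + b1*year + f(effort) + f(depth) [+ f(oceanographic)]

with each ``f`` a penalised regression spline.  Smooths use a low-rank
thin-plate-style basis (cubic radial basis functions at quantile knots with
the linear/constant polynomial space, side conditions absorbed, columns
centred over the data for identifiability).  Each smooth carries two
penalties:

* a wiggliness penalty (the thin-plate bending energy on the radial part),
* a shrinkage ridge on the penalty null space (the leftover linear trend),

so that smoothing-parameter selection can shrink an irrelevant term all the
way to zero — its effective degrees of freedom (EDF) then approach 0 and the
term drops out of the model in practice (Marra & Wood's double-penalty
construction).

Fitting is penalised IRLS.  Smoothing parameters are chosen by minimising a
UBRE/AIC-type prediction-error criterion on the working model,

    V(lambda) = ||sqrt(W)(z - X b)||^2 / n + 2 * gamma * tau / n,

where ``tau`` is the model EDF (trace of the influence matrix) and ``gamma``
(default 1.4) inflates the degrees-of-freedom charge to discourage overfit
wiggliness.  The search is a per-penalty golden-section on log(lambda),
nested in two outer performance-iteration cycles, which makes fits fast and
deterministic.  AIC is the conditional ``-2*loglik + 2*EDF``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit, logit

__all__ = ["SmoothSpec", "SmoothTerm", "BinaryGAM", "BinaryGAMResults", "GamFitError"]

_MU_EPS = 1e-10


class GamFitError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class SmoothSpec:
    """Specification of one 1-D smooth term.

    k is the basis dimension (>= 3); shrinkage adds the null-space ridge that
    lets model selection remove the whole term.
    """

    name: str
    k: int = 10
    shrinkage: bool = True

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("basis dimension k must be >= 3")


class SmoothTerm:
    """A fitted-to-data spline basis for one covariate.

    Construction: knots at quantiles of the distinct covariate values;
    radial columns ``|x - knot_j|^3`` with the thin-plate side conditions
    (sum and first moment of the radial coefficients vanish) absorbed by a QR
    null-space reparameterisation; plus the linear column.  All columns are
    centred over the training data (sum-to-zero identifiability) and scaled
    to unit RMS for conditioning; penalties are transformed accordingly and
    the wiggliness penalty is Frobenius-normalised so smoothing parameters
    are comparable across terms.
    """

    def __init__(self, x: np.ndarray, spec: SmoothSpec):
        x = np.asarray(x, dtype=float)
        ux = np.unique(x)
        k = spec.k
        if ux.size < k:
            warnings.warn(
                f"smooth '{spec.name}': only {ux.size} distinct values; "
                f"k reduced from {k} to {ux.size}"
            )
            k = ux.size
            if k < 3:
                raise GamFitError(f"smooth '{spec.name}': fewer than 3 distinct values")
        self.spec = spec
        self.name = spec.name
        self.k = k
        # quantile knots over the distinct values, end points included
        qs = np.linspace(0.0, 1.0, k)
        self.knots = np.quantile(ux, qs)
        self.knots = np.unique(self.knots)
        if self.knots.size < k:  # heavy ties; fall back to unique knots
            k = self.knots.size
            self.k = k
        kn = self.knots
        E_k = np.abs(kn[:, None] - kn[None, :]) ** 3
        T_k = np.column_stack([np.ones_like(kn), kn])
        Q, _ = np.linalg.qr(T_k, mode="complete")
        Z = Q[:, 2:]                                    # k x (k-2)
        S_r = Z.T @ E_k @ Z                             # wiggliness on radial part
        S_r = 0.5 * (S_r + S_r.T)
        # columns: [E Z  (k-2 radial), x (null space)]
        B = np.column_stack([(np.abs(x[:, None] - kn[None, :]) ** 3) @ Z, x])
        self._Z = Z
        self.col_center = B.mean(axis=0)
        B = B - self.col_center
        scale = B.std(axis=0)
        scale[scale < 1e-12] = 1.0
        self.col_scale = scale
        p = B.shape[1]
        Dinv = np.diag(1.0 / scale)
        S_w = np.zeros((p, p))
        S_w[:-1, :-1] = S_r
        # columns divided by scale => coefficients multiplied by scale, so the
        # penalty transforms by the inverse scaling on each side
        S_w = Dinv @ S_w @ Dinv
        fro = np.linalg.norm(S_w)
        if fro > 0:
            S_w /= fro
        self.S_wiggle = S_w
        S_n = np.zeros((p, p))
        S_n[-1, -1] = 1.0
        self.S_null = S_n
        self.n_cols = p

    def basis(self, xnew: np.ndarray) -> np.ndarray:
        """Evaluate the (centred, scaled) basis at new covariate values."""
        xnew = np.asarray(xnew, dtype=float)
        B = np.column_stack(
            [(np.abs(xnew[:, None] - self.knots[None, :]) ** 3) @ self._Z, xnew]
        )
        return (B - self.col_center) / self.col_scale


class BinaryGAM:
    """Binary logit GAM: parametric terms plus shrinkage smooths.

    Build from arrays or with :meth:`from_dataframe`.  ``fit()`` selects
    smoothing parameters by the gamma-inflated UBRE criterion; pass
    ``lam=`` to fit at fixed smoothing parameters instead.
    """

    def __init__(
        self,
        y: np.ndarray,
        data: pd.DataFrame,
        parametric: Sequence[str] = (),
        smooths: Sequence[SmoothSpec | str] = (),
        gamma: float = 1.4,
    ):
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if y.min() == y.max():
            raise GamFitError("response has a single class; cannot fit")
        if gamma < 1.0:
            raise ValueError("gamma must be >= 1")
        self.y = y
        self.gamma = float(gamma)
        self.data = data.reset_index(drop=True)
        self.n = y.size

        specs = [s if isinstance(s, SmoothSpec) else SmoothSpec(s) for s in smooths]
        cols: list[np.ndarray] = [np.ones((self.n, 1))]
        names: list[str] = ["(Intercept)"]
        self.term_slices: dict[str, slice] = {"(Intercept)": slice(0, 1)}
        start = 1
        self.parametric_info: list[tuple[str, list | None]] = []
        for name in parametric:
            col = self.data[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                levels = sorted(pd.unique(col.astype(str)))
                dummies = np.column_stack(
                    [(col.astype(str) == lv).astype(float) for lv in levels[1:]]
                ) if len(levels) > 1 else np.zeros((self.n, 0))
                cols.append(dummies)
                names += [f"{name}[{lv}]" for lv in levels[1:]]
                self.parametric_info.append((name, levels))
                width = len(levels) - 1
            else:
                cols.append(np.asarray(col, float)[:, None])
                names.append(name)
                self.parametric_info.append((name, None))
                width = 1
            self.term_slices[name] = slice(start, start + width)
            start += width

        self.smooth_terms: list[SmoothTerm] = []
        self.penalties: list[tuple[slice, np.ndarray, str, str]] = []
        for spec in specs:
            term = SmoothTerm(np.asarray(self.data[spec.name], float), spec)
            B = term.basis(np.asarray(self.data[spec.name], float))
            # re-centre exactly over this sample (basis() uses stored centres)
            sl = slice(start, start + term.n_cols)
            cols.append(B)
            names += [f"s({spec.name}).{j}" for j in range(term.n_cols)]
            self.term_slices[f"s({spec.name})"] = sl
            self.penalties.append((sl, term.S_wiggle, "wiggle", spec.name))
            if spec.shrinkage:
                self.penalties.append((sl, term.S_null, "null", spec.name))
            self.smooth_terms.append(term)
            start += term.n_cols

        self.X = np.concatenate(cols, axis=1)
        self.coef_names = names
        self.p = self.X.shape[1]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str,
        parametric: Sequence[str] = (),
        smooths: Sequence[SmoothSpec | str] = (),
        gamma: float = 1.4,
    ) -> "BinaryGAM":
        return cls(
            np.asarray(df[response], float), df,
            parametric=parametric, smooths=smooths, gamma=gamma,
        )

    # -- internals ----------------------------------------------------------
    def _S_lambda(self, lam: np.ndarray) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for lv, (sl, Sj, _, _) in zip(lam, self.penalties):
            S[sl, sl] += lv * Sj
        return S

    def _pirls(self, lam, beta0=None, maxiter=200, tol=1e-8):
        """Penalised IRLS at fixed smoothing parameters."""
        X, y, n = self.X, self.y, self.n
        S = self._S_lambda(np.asarray(lam, float))
        if beta0 is None:
            beta = np.zeros(self.p)
            beta[0] = logit(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        else:
            beta = beta0.copy()
        dev_old = np.inf
        pen_dev_old = np.inf
        mu = None
        for it in range(maxiter):
            eta = X @ beta
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            WX = X * w[:, None]
            A = X.T @ WX + S
            b = WX.T @ z
            try:
                beta_new = linalg.solve(A, b, assume_a="pos")
            except linalg.LinAlgError:
                beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
            # step-halving on the penalised deviance
            step = beta_new - beta
            for _ in range(30):
                cand = beta + step
                eta_c = X @ cand
                mu_c = np.clip(expit(eta_c), _MU_EPS, 1 - _MU_EPS)
                dev_c = -2.0 * np.sum(y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c))
                pen_c = dev_c + cand @ S @ cand
                if pen_c <= pen_dev_old * (1 + 1e-12) or not np.isfinite(pen_dev_old):
                    break
                step *= 0.5
            beta = beta + step
            dev = dev_c
            if np.isfinite(dev_old) and abs(dev_old - dev) < tol * (abs(dev) + 0.1):
                dev_old = dev
                pen_dev_old = pen_c
                break
            dev_old = dev
            pen_dev_old = pen_c
        else:
            raise GamFitError(
                f"penalised IRLS did not converge in {maxiter} iterations "
                f"(last deviance {dev_old:.6g})"
            )
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        w = mu * (1 - mu)
        return beta, float(dev_old), w, eta

    def _working_criterion(self, lam, XtWX, XtWz, zWz):
        """gamma-inflated UBRE of the working penalised least-squares problem."""
        S = self._S_lambda(lam)
        A = XtWX + S
        try:
            c = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return np.inf, None
        beta = linalg.cho_solve(c, XtWz)
        tau = float(np.trace(linalg.cho_solve(c, XtWX)))
        rss = zWz - 2.0 * beta @ XtWz + beta @ XtWX @ beta
        return (rss + 2.0 * self.gamma * tau) / self.n, beta

    def _exact_criterion(self, lam, beta0):
        """Deviance-based gamma-inflated UBRE at converged PIRLS for lam."""
        try:
            beta, dev, w, _ = self._pirls(lam, beta0=beta0, maxiter=100, tol=1e-6)
        except GamFitError:
            return np.inf, beta0
        WX = self.X * w[:, None]
        XtWX = self.X.T @ WX
        A = XtWX + self._S_lambda(lam)
        try:
            tau = float(np.trace(linalg.cho_solve(linalg.cho_factor(A), XtWX)))
        except linalg.LinAlgError:
            return np.inf, beta0
        return (dev + 2.0 * self.gamma * tau) / self.n, beta

    def _coordinate_pass(self, log_lam, crit, log_lo, log_hi, grid_pts=9):
        """One golden-section sweep over every log-lambda coordinate."""
        gr = (math.sqrt(5) - 1) / 2
        for j in range(len(log_lam)):
            grid = np.linspace(log_lo, log_hi, grid_pts)
            vals = [crit(j, g) for g in grid]
            i0 = int(np.argmin(vals))
            a = grid[max(i0 - 1, 0)]
            b = grid[min(i0 + 1, len(grid) - 1)]
            c1 = b - gr * (b - a)
            c2 = a + gr * (b - a)
            f1, f2 = crit(j, c1), crit(j, c2)
            while b - a > 0.2:
                if f1 <= f2:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - gr * (b - a)
                    f1 = crit(j, c1)
                else:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + gr * (b - a)
                    f2 = crit(j, c2)
            log_lam[j] = 0.5 * (a + b)
        return log_lam

    def _optimise_lambda(self, log_lo=-8.0, log_hi=18.0, cycles=2):
        m = len(self.penalties)
        log_lam = np.zeros(m)
        beta, dev, w, eta = self._pirls(np.exp(log_lam))
        for _cycle in range(cycles):
            mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
            w = mu * (1 - mu)
            z = eta + (self.y - mu) / w
            WX = self.X * w[:, None]
            XtWX = self.X.T @ WX
            XtWz = WX.T @ z
            zWz = float(z @ (w * z))

            def crit(j, lg):
                trial = log_lam.copy()
                trial[j] = lg
                return self._working_criterion(np.exp(trial), XtWX, XtWz, zWz)[0]

            log_lam = self._coordinate_pass(log_lam, crit, log_lo, log_hi)
            beta, dev, w, eta = self._pirls(np.exp(log_lam), beta0=beta)

        # final refinement against the exact (converged-fit) criterion: the
        # working-model approximation can under-shrink terms near EDF 0
        state = {"beta": beta}

        def crit_exact(j, lg):
            trial = log_lam.copy()
            trial[j] = lg
            val, b_new = self._exact_criterion(np.exp(trial), state["beta"])
            if np.isfinite(val):
                state["beta"] = b_new
            return val

        log_lam = self._coordinate_pass(log_lam, crit_exact, log_lo, log_hi)
        beta, dev, w, eta = self._pirls(np.exp(log_lam), beta0=state["beta"])
        return np.exp(log_lam), beta, eta

    # -- public -------------------------------------------------------------
    def fit(self, lam=None) -> "BinaryGAMResults":
        """Fit the model; optimises smoothing parameters unless ``lam`` given."""
        if lam is None:
            if self.penalties:
                lam, beta0, _ = self._optimise_lambda()
            else:
                lam, beta0 = np.zeros(0), None
        else:
            lam = np.asarray(lam, dtype=float)
            if lam.size != len(self.penalties):
                raise ValueError(
                    f"expected {len(self.penalties)} smoothing parameters, "
                    f"got {lam.size}"
                )
            beta0 = None
        beta, dev, w, eta = self._pirls(lam, beta0=beta0)
        WX = self.X * w[:, None]
        XtWX = self.X.T @ WX
        A = XtWX + self._S_lambda(lam)
        Ainv = linalg.inv(A)
        F = Ainv @ XtWX                      # influence map on coefficients
        edf = np.diag(F)
        mu = np.clip(expit(eta), _MU_EPS, 1 - _MU_EPS)
        loglik = float(np.sum(self.y * np.log(mu) + (1 - self.y) * np.log(1 - mu)))
        pbar = np.clip(self.y.mean(), _MU_EPS, 1 - _MU_EPS)
        null_dev = -2.0 * float(
            np.sum(self.y * np.log(pbar) + (1 - self.y) * np.log(1 - pbar))
        )
        return BinaryGAMResults(
            model=self,
            params=beta,
            lam=np.asarray(lam, float),
            cov_params=Ainv,                  # Bayesian posterior covariance
            edf_per_coef=edf,
            loglik=loglik,
            deviance=dev,
            null_deviance=null_dev,
            fitted=expit(eta),
            weights=w,
        )


@dataclasses.dataclass(eq=False)
class BinaryGAMResults:
    """Results of a penalised binary GAM fit."""

    model: BinaryGAM
    params: np.ndarray
    lam: np.ndarray
    cov_params: np.ndarray
    edf_per_coef: np.ndarray
    loglik: float
    deviance: float
    null_deviance: float
    fitted: np.ndarray
    weights: np.ndarray

    # -- scalar summaries ---------------------------------------------------
    @property
    def edf(self) -> float:
        """Total effective degrees of freedom (trace of the influence matrix)."""
        return float(np.sum(self.edf_per_coef))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.edf

    @property
    def deviance_explained(self) -> float:
        """Percent deviance explained: 100 * (1 - residual/null deviance)."""
        return 100.0 * (1.0 - self.deviance / self.null_deviance)

    def edf_by_term(self) -> dict[str, float]:
        out = {}
        for name, sl in self.model.term_slices.items():
            if name.startswith("s("):
                out[name] = float(np.sum(self.edf_per_coef[sl]))
        return out

    # -- smooth evaluation --------------------------------------------------
    def _smooth_index(self, name: str) -> int:
        for i, t in enumerate(self.model.smooth_terms):
            if t.name == name:
                return i
        raise KeyError(f"no smooth term '{name}' in model")

    def partial_effect(self, name: str, grid=None, n_grid: int = 100) -> pd.DataFrame:
        """Centred smooth effect on a grid with pointwise 95% intervals."""
        i = self._smooth_index(name)
        term = self.model.smooth_terms[i]
        x = np.asarray(self.model.data[name], float)
        if grid is None:
            grid = np.linspace(x.min(), x.max(), n_grid)
        grid = np.asarray(grid, float)
        B = term.basis(grid)
        sl = self.model.term_slices[f"s({name})"]
        beta_j = self.params[sl]
        V_j = self.cov_params[sl, sl]
        eff = B @ beta_j
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, V_j, B), 0.0))
        return pd.DataFrame(
            {"x": grid, "effect": eff, "lo": eff - 1.96 * se, "hi": eff + 1.96 * se}
        )

    def smooth_pvalues(self) -> dict[str, float]:
        """Approximate Wald-type p-values for each smooth term.

        Uses the penalised-coefficient covariance with the reference degrees
        of freedom set to the rounded per-term EDF (at least 1); treat as
        approximate, as always for penalised smooths.
        """
        out = {}
        for name, edf_j in self.edf_by_term().items():
            sl = self.model.term_slices[name]
            beta_j = self.params[sl]
            V_j = self.cov_params[sl, sl]
            r = max(1, int(round(edf_j)))
            # Wald statistic with the (pseudo-)inverted posterior covariance;
            # the reference df is the rounded per-term EDF
            T = float(beta_j @ np.linalg.pinv(V_j, rcond=1e-10) @ beta_j)
            out[name] = float(stats.chi2.sf(T, r))
        return out

    # -- prediction ---------------------------------------------------------
    def design_for(self, df: pd.DataFrame) -> np.ndarray:
        m = self.model
        cols = [np.ones((len(df), 1))]
        for name, levels in m.parametric_info:
            col = df[name]
            if levels is not None:
                cols.append(
                    np.column_stack(
                        [(col.astype(str) == lv).astype(float) for lv in levels[1:]]
                    ) if len(levels) > 1 else np.zeros((len(df), 0))
                )
            else:
                cols.append(np.asarray(col, float)[:, None])
        for term in m.smooth_terms:
            cols.append(term.basis(np.asarray(df[term.name], float)))
        return np.concatenate(cols, axis=1)

    def predict(self, df: pd.DataFrame | None = None) -> np.ndarray:
        """Fitted probabilities for new data (or the training data)."""
        if df is None:
            return self.fitted.copy()
        return expit(self.design_for(df) @ self.params)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Binary GAM (logit link, shrinkage smooths)",
            "------------------------------------------",
            f"n = {self.model.n}, gamma = {self.model.gamma}",
            f"log-likelihood  {self.loglik:.3f}",
            f"total EDF       {self.edf:.3f}",
            f"AIC             {self.aic:.2f}",
            f"deviance expl.  {self.deviance_explained:.1f}%",
            "",
            "Parametric coefficients:",
        ]
        for name, sl in self.model.term_slices.items():
            if name.startswith("s("):
                continue
            for j in range(sl.start, sl.stop):
                se = math.sqrt(max(self.cov_params[j, j], 0.0))
                lines.append(
                    f"  {self.model.coef_names[j]:<20s} {self.params[j]: .4f}"
                    f"  (se {se:.4f})"
                )
        pvals = self.smooth_pvalues()
        if pvals:
            lines += ["", "Smooth terms (EDF, approx p):"]
            for name, edf_j in self.edf_by_term().items():
                lines.append(f"  {name:<20s} EDF {edf_j:6.3f}   p = {pvals[name]:.4g}")
        return "\n".join(lines)

    def plot_partial(self, name: str, ax=None):
        """Plot one partial-effect curve with its 95% band."""
        import matplotlib.pyplot as plt

        pe = self.partial_effect(name)
        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(pe["x"], pe["lo"], pe["hi"], alpha=0.3)
        ax.plot(pe["x"], pe["effect"])
        ax.set_xlabel(name)
        ax.set_ylabel(f"s({name})")
        return ax
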