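"""Random-intercept linear mixed models with type III F tests.

All models in this package share one structure: a Gaussian LMM with
categorical fixed effects and a between-subject random intercept, fitted by
restricted maximum likelihood (REML). Because the random structure is a
single intercept, the REML criterion can be profiled down to one dimension
(the variance ratio lambda = sigma_b^2 / sigma_w^2) and solved by scalar
minimization with block-wise Woodbury algebra; this gives
machine-precision, deterministic estimates that agree with the closed-form
ANOVA method of moments on balanced data. Factors are sum-to-zero coded so
that marginal (type III) Wald F tests of each term are obtained directly
from the joint covariance of its coefficients.

Denominator degrees of freedom use the between-within (containment)
approximation: terms that vary within subjects are tested against
``n_obs - n_subjects - p_within`` and between-subject terms against
``n_subjects - rank(between design)``. p-values may therefore differ in the
second decimal from Kenward-Roger-based software on unbalanced data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats as st
from scipy.optimize import brentq, minimize_scalar


class FitError(RuntimeError):
    """A model could not be fitted on the supplied data."""


@dataclass(frozen=True)
class FTestResult:
    """Marginal (type III) F test of one fixed-effect term."""

    term: str
    statistic: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class LmmFit:
    """A fitted random-intercept model.

    ``sigma2_b`` is the between-subject (random intercept) variance and
    ``sigma2_w`` the residual within-subject variance, both on the squared
    scale of the response. Negative variance-component estimates are
    truncated at zero (boundary REML).
    """

    params: pd.Series
    cov_fe: pd.DataFrame
    sigma2_b: float
    sigma2_w: float
    n_subjects: int
    n_obs: int
    converged: bool
    fit_method: str
    design_info: Any
    term_cols: Mapping[str, np.ndarray] = field(repr=False, default_factory=dict)
    term_within: Mapping[str, bool] = field(repr=False, default_factory=dict)
    df_within: float = float("nan")
    df_between: float = float("nan")

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_b + self.sigma2_w

    def require_converged(self) -> "LmmFit":
        if not self.converged:
            raise FitError("model did not converge; refusing downstream use")
        return self


def _classify_terms(X: np.ndarray, groups: np.ndarray, design_info) -> tuple[dict, dict, float, float]:
    """Term -> column indices; term -> varies-within-subject; containment df."""
    term_cols = {
        name: np.arange(sl.start, sl.stop) for name, sl in design_info.term_name_slices.items()
    }
    n_obs, p = X.shape
    subj = pd.Series(np.arange(n_obs)).groupby(pd.Series(groups))
    within_col = np.zeros(p, dtype=bool)
    for _, idx in subj.groups.items():
        sub = X[np.asarray(idx)]
        within_col |= np.ptp(sub, axis=0) > 1e-12
    term_within = {name: bool(within_col[cols].any()) for name, cols in term_cols.items()}
    n_subjects = len(subj.groups)
    between_X = np.column_stack(
        [X[:, j] for j in range(p) if not within_col[j]] or [np.ones(n_obs)]
    )
    rank_between = np.linalg.matrix_rank(between_X)
    p_within = int(within_col.sum())
    df_within = float(n_obs - n_subjects - p_within)
    df_between = float(n_subjects - rank_between)
    return term_cols, term_within, df_within, df_between


def _degenerate_fit(
    data: pd.DataFrame, formula: str, subject_col: str, design_info, X, y, groups
) -> LmmFit:
    # Noiseless (or numerically noiseless) data: REML machinery is singular.
    # Solve the fixed effects exactly by least squares with sum-to-zero
    # subject dummies and read the variance components off the residuals.
    subjects = pd.unique(groups)
    n, p = X.shape
    D = np.zeros((n, len(subjects) - 1))
    smap = {s: i for i, s in enumerate(subjects)}
    for r, s in enumerate(groups):
        i = smap[s]
        if i < len(subjects) - 1:
            D[r, i] = 1.0
        else:
            D[r, :] = -1.0
    full = np.column_stack([X, D])
    coef, *_ = np.linalg.lstsq(full, y, rcond=None)
    resid = y - full @ coef
    dof = max(n - full.shape[1], 1)
    sigma2_w = float(resid @ resid / dof)
    eff = coef[p:]
    eff = np.append(eff, -eff.sum())
    sigma2_b = float(np.var(eff, ddof=1)) if len(eff) > 1 else 0.0
    names = design_info.column_names
    term_cols, term_within, df_w, df_b = _classify_terms(X, groups, design_info)
    return LmmFit(
        params=pd.Series(coef[:p], index=names),
        cov_fe=pd.DataFrame(np.zeros((p, p)), index=names, columns=names),
        sigma2_b=max(sigma2_b, 0.0),
        sigma2_w=max(sigma2_w, 0.0),
        n_subjects=len(subjects),
        n_obs=n,
        converged=True,
        fit_method="exact-ls (degenerate noiseless data)",
        design_info=design_info,
        term_cols=term_cols,
        term_within=term_within,
        df_within=df_w,
        df_between=df_b,
    )


class _ProfiledREML:
    """Profiled REML criterion for the random-intercept model.

    For V_i = I + lambda * J (per-subject blocks), Woodbury gives
    V_i^{-1} = I - c_i J with c_i = lambda / (1 + lambda * n_i), so all
    quantities reduce to cached cross-products and per-subject totals; each
    criterion evaluation is O(groups * p^2).
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        idx = pd.Series(np.arange(self.n)).groupby(pd.Series(groups), sort=False)
        self.Xsums, self.ysums, self.sizes = [], [], []
        for _, rows in idx.groups.items():
            r = np.asarray(rows)
            self.Xsums.append(X[r].sum(axis=0))
            self.ysums.append(float(y[r].sum()))
            self.sizes.append(len(r))
        self.Xsums = np.stack(self.Xsums)  # (G, p)
        self.ysums = np.asarray(self.ysums)
        self.sizes = np.asarray(self.sizes, dtype=float)

    def _solve(self, lam: float):
        c = lam / (1.0 + lam * self.sizes)  # (G,)
        XtVX = self.XtX - (self.Xsums * c[:, None]).T @ self.Xsums
        XtVy = self.Xty - self.Xsums.T @ (c * self.ysums)
        yVy = self.yty - float(c @ self.ysums**2)
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - float(beta @ XtVy)
        return beta, XtVX, max(rss, 0.0)

    def criterion(self, lam: float) -> float:
        _, XtVX, rss = self._solve(lam)
        dof = self.n - self.p
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0 or rss <= 0:
            return np.inf
        logdet_v = float(np.log1p(lam * self.sizes).sum())
        return dof * np.log(rss / dof) + logdet_v + logdet_xvx

    def gradient(self, lam: float) -> float:
        """d criterion / d lambda; the RSS term uses the envelope theorem."""
        beta, XtVX, rss = self._solve(lam)
        dc = 1.0 / (1.0 + lam * self.sizes) ** 2  # (G,)
        resid_sums = self.ysums - self.Xsums @ beta
        drss = -float(dc @ resid_sums**2)
        dlogdet_v = float((self.sizes / (1.0 + lam * self.sizes)).sum())
        sol = np.linalg.solve(XtVX, self.Xsums.T)  # (p, G)
        dlogdet_xvx = -float(dc @ np.einsum("gp,pg->g", self.Xsums, sol))
        return (self.n - self.p) * drss / rss + dlogdet_v + dlogdet_xvx

    def fit(self, lam_max: float = 1e6) -> tuple[np.ndarray, np.ndarray, float, float]:
        if self.gradient(0.0) >= 0.0:
            lam = 0.0  # boundary REML: non-positive between-subject variance
        else:
            res = minimize_scalar(
                self.criterion, bounds=(0.0, lam_max), method="bounded",
                options={"xatol": 1e-10},
            )
            lam = float(res.x)
            # polish: the criterion is flat near the optimum, so locate the
            # root of its analytic gradient to machine precision instead
            lo, hi = max(lam / 2, 1e-12), lam * 2 + 1e-9
            for _ in range(60):
                if self.gradient(lo) < 0:
                    break
                lo /= 4
            for _ in range(60):
                if self.gradient(hi) > 0:
                    break
                hi *= 4
            if self.gradient(lo) < 0 < self.gradient(hi):
                lam = float(brentq(self.gradient, lo, hi, xtol=1e-14))
        beta, XtVX, rss = self._solve(lam)
        sigma2_w = rss / (self.n - self.p)
        cov_fe = np.linalg.inv(XtVX) * sigma2_w
        return beta, cov_fe, lam * sigma2_w, sigma2_w


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    subject_col: str = "subject_id",
) -> LmmFit:
    """REML fit of ``formula`` with a per-subject random intercept.

    Requires at least two subjects (a single subject leaves the
    between-subject variance unidentifiable) and at least two distinct
    values of every factor in the formula. Negative between-subject variance
    estimates are truncated at the lambda = 0 boundary.
    """
    data = data.reset_index(drop=True)
    subjects = data[subject_col].unique()
    if len(subjects) < 2:
        raise FitError("at least two subjects are required to separate variance components")

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    design_info = X.design_info
    groups = data.loc[X.index, subject_col].to_numpy()
    Xv = np.asarray(X)
    yv = np.asarray(y).ravel()
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise FitError("fixed-effect design is rank deficient")

    # Degenerate data guard: the REML surface has no interior optimum when
    # the residual variance is (numerically) zero.
    dummies = pd.get_dummies(pd.Series(groups), dtype=float).to_numpy()
    full = np.column_stack([Xv, dummies])
    coef0, *_ = np.linalg.lstsq(full, yv, rcond=None)
    ss = yv - full @ coef0
    if float(ss @ ss) / len(yv) < 1e-10 * max(1.0, float(np.var(yv))):
        return _degenerate_fit(data, formula, subject_col, design_info, Xv, yv, groups)

    try:
        beta, cov_fe, sigma2_b, sigma2_w = _ProfiledREML(Xv, yv, groups).fit()
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FitError(f"REML optimization failed: {exc}") from exc
    converged = bool(np.isfinite(beta).all() and np.isfinite(sigma2_w) and sigma2_w > 0)

    names = design_info.column_names
    term_cols, term_within, df_w, df_b = _classify_terms(Xv, groups, design_info)
    return LmmFit(
        params=pd.Series(beta, index=names),
        cov_fe=pd.DataFrame(cov_fe, index=names, columns=names),
        sigma2_b=max(float(sigma2_b), 0.0),
        sigma2_w=float(sigma2_w),
        n_subjects=len(subjects),
        n_obs=len(yv),
        converged=converged,
        fit_method="reml-profiled",
        design_info=design_info,
        term_cols=term_cols,
        term_within=term_within,
        df_within=df_w,
        df_between=df_b,
    )


def type3_f_test(fit: LmmFit, term: str) -> FTestResult:
    """Marginal Wald F test of ``term`` with containment denominator df."""
    fit.require_converged()
    if term not in fit.term_cols:
        raise KeyError(f"term {term!r} not in model (have {list(fit.term_cols)})")
    idx = fit.term_cols[term]
    q = len(idx)
    if q == 0:
        raise FitError(f"term {term!r} has no estimable coefficients")
    beta = fit.params.to_numpy()[idx]
    V = fit.cov_fe.to_numpy()[np.ix_(idx, idx)]
    try:
        stat = float(beta @ np.linalg.solve(V, beta)) / q
    except np.linalg.LinAlgError as exc:
        raise FitError(f"singular coefficient covariance for term {term!r}") from exc
    df_den = fit.df_within if fit.term_within[term] else fit.df_between
    p = float(st.f.sf(stat, q, df_den))
    return FTestResult(term, stat, q, df_den, p)


def design_row(fit: LmmFit, factors: Mapping[str, Sequence]) -> np.ndarray:
    """Fixed-effect design rows for the factor combinations in ``factors``."""
    (mat,) = patsy.build_design_matrices([fit.design_info], pd.DataFrame(factors))
    return np.asarray(mat)


def estimate_contrast(fit: LmmFit, c: np.ndarray) -> tuple[float, float]:
    """Point estimate and standard error of the linear combination c'beta."""
    est = float(c @ fit.params.to_numpy())
    se = float(np.sqrt(c @ fit.cov_fe.to_numpy() @ c))
    return est, se
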