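"""Linear and linear mixed models with a single random intercept.

The models used throughout are Gaussian fixed-effect factorials, optionally
with one random intercept (strain/community identity). With a single
variance component the REML problem reduces to a one-dimensional profiled
likelihood in the variance ratio lambda = sigma_u^2 / sigma_e^2:

    V = sigma_e^2 (I + lambda Z Z'),   Z = group indicator matrix,

where (I + lambda Z Z')^-1 is block diagonal with an explicit Woodbury form
per group. The profiled criterion is minimised by a bounded search on
log(lambda), with the boundary lambda = 0 (pure OLS) always compared, so the
zero-variance limit is exact. Fixed effects use sum-to-zero coding so Wald
type-III tests are the conventional ones and type-II follows the
marginality-respecting construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist


class EstimabilityError(ValueError):
    """The design cannot support the requested model term or comparison."""


@dataclass
class ModelFit:
    """A fitted (mixed) linear model on sum-coded factorial design.

    ``params``/``cov_params`` refer to the fixed effects; ``sigma2_group`` is
    the random-intercept variance (0 for pure fixed-effects fits) and
    ``sigma2_resid`` the residual variance. ``factor_levels`` records the
    observed level order of every factor, which drives marginal-mean grids.
    """

    formula: str
    params: np.ndarray
    cov_params: np.ndarray
    design_info: object
    factor_levels: Mapping[str, Sequence[str]]
    sigma2_resid: float
    sigma2_group: float
    lam: float
    group_col: str | None
    n_obs: int
    df_resid: int
    loglik_reml: float
    converged: bool
    r2_marginal: float
    r2_conditional: float
    method: str = "reml"
    warnings: list[str] = field(default_factory=list)

    # -- structure helpers ---------------------------------------------------
    @property
    def term_names(self) -> list[str]:
        return list(self.design_info.term_names)

    def term_columns(self, term_name: str) -> list[int]:
        sl = self.design_info.term_name_slices[term_name]
        return list(range(sl.start, sl.stop))

    def term_factors(self, term_name: str) -> frozenset[str]:
        """Raw factor names entering a term, e.g. {'entity', 'history'}."""
        if term_name == "Intercept":
            return frozenset()
        out = set()
        for part in term_name.split(":"):
            m = re.match(r"C\((\w+)", part.strip())
            out.add(m.group(1) if m else part.strip())
        return frozenset(out)

    def design_rows(self, grid: pd.DataFrame) -> np.ndarray:
        """Fixed-effect design rows for new factor combinations."""
        g = grid.copy()
        for col, levels in self.factor_levels.items():
            if col in g.columns:
                g[col] = pd.Categorical(g[col], categories=levels)
        (mat,) = build_design_matrices([self.design_info], g)
        return np.asarray(mat)

    def summary(self) -> str:
        lines = [f"formula: {self.formula}",
                 f"method: {self.method}  converged: {self.converged}",
                 f"n = {self.n_obs}, residual df = {self.df_resid}"]
        if self.group_col:
            lines.append(f"random intercept on {self.group_col}: "
                         f"var = {self.sigma2_group:.6g}")
        lines.append(f"residual var = {self.sigma2_resid:.6g}")
        lines.append(f"R2 marginal = {self.r2_marginal:.4f}, "
                     f"conditional = {self.r2_conditional:.4f}")
        names = self.design_info.column_names
        for name, b, se in zip(names, self.params,
                               np.sqrt(np.diag(self.cov_params))):
            lines.append(f"  {name:55s} {b:+.6f}  (se {se:.6f})")
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


def factorial_formula(df: pd.DataFrame, factors: Sequence[str]) -> str:
    """Full-factorial sum-coded formula over factors with >= 2 levels."""
    kept = [f for f in factors if df[f].nunique() >= 2]
    if not kept:
        return "1"
    return " * ".join(f"C({f}, Sum)" for f in kept)


def _prepare(df: pd.DataFrame, factors: Sequence[str],
             level_order: Mapping[str, Sequence[str]] | None = None):
    """Set categorical orderings and return (frame, factor_levels)."""
    df = df.copy()
    levels = {}
    order = level_order or {}
    for f in factors:
        present = list(pd.unique(df[f]))
        if f in order:
            cats = [lv for lv in order[f] if lv in present]
        else:
            cats = sorted(present)
        df[f] = pd.Categorical(df[f], categories=cats)
        levels[f] = cats
    return df, levels


def fit_lmm(df: pd.DataFrame, factors: Sequence[str],
            response: str = "od", group_col: str | None = None,
            level_order: Mapping[str, Sequence[str]] | None = None,
            warnings: Sequence[str] = ()) -> ModelFit:
    """REML fit of ``response ~ full factorial(factors) (+ 1 | group_col)``.

    With ``group_col=None`` this is an ordinary least-squares fit (the
    lambda = 0 boundary of the same machinery).
    """
    work, factor_levels = _prepare(df, factors, level_order)
    formula = factorial_formula(work, [f for f in factors])
    mat = dmatrix(formula, work, return_type="matrix")
    design_info = mat.design_info
    X = np.asarray(mat, dtype=float)
    y = work[response].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise EstimabilityError(
            f"{n} observations cannot identify {p} fixed-effect columns")
    if np.linalg.matrix_rank(X) < p:
        raise EstimabilityError(
            "rank-deficient fixed-effect design (empty cell makes a term "
            "inestimable)")

    if group_col is None:
        groups = None
    else:
        codes, uniques = pd.factorize(work[group_col])
        if len(uniques) < 2:
            raise EstimabilityError(
                f"random intercept on {group_col!r} needs >= 2 levels, "
                f"found {len(uniques)}")
        groups = codes

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    if groups is not None:
        q = groups.max() + 1
        n_g = np.bincount(groups, minlength=q).astype(float)
        sx = np.zeros((q, p))
        np.add.at(sx, groups, X)
        sy = np.bincount(groups, weights=y, minlength=q)
    else:
        n_g = sx = sy = None

    def pieces(lam: float):
        if groups is None or lam == 0.0:
            XtViX, XtViy, logdetV = XtX, Xty, 0.0
        else:
            c = lam / (1.0 + lam * n_g)
            XtViX = XtX - (sx * c[:, None]).T @ sx
            XtViy = Xty - sx.T @ (c * sy)
            logdetV = float(np.sum(np.log1p(lam * n_g)))
        beta = np.linalg.solve(XtViX, XtViy)
        quad = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
        if groups is not None and lam != 0.0:
            resid_sums = sy - sx @ beta
            quad -= float(np.sum(c * resid_sums ** 2))
        quad = max(float(quad), 0.0)
        return beta, quad, logdetV, XtViX

    def criterion(lam: float) -> float:
        _, quad, logdetV, XtViX = pieces(lam)
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf
        return ((n - p) * np.log(max(quad, 1e-300) / (n - p))
                + logdetV + logdetXtViX)

    converged = True
    if groups is None:
        lam_hat = 0.0
    else:
        # coarse log-grid, then a bounded refinement around the best point;
        # the lambda = 0 boundary is always a candidate
        grid = np.concatenate([[0.0], np.logspace(-6, 6, 49)])
        vals = np.array([criterion(l) for l in grid])
        best = int(np.argmin(vals))
        lam_hat = grid[best]
        if best > 0:
            lo = np.log(grid[max(best - 1, 1)])
            hi = np.log(grid[min(best + 1, len(grid) - 1)])
            if hi > lo:
                res = minimize_scalar(lambda t: criterion(np.exp(t)),
                                      bounds=(lo, hi), method="bounded",
                                      options={"xatol": 1e-10})
                converged = bool(res.success)
                if res.fun <= vals[best]:
                    lam_hat = float(np.exp(res.x))
            if criterion(0.0) <= criterion(lam_hat):
                lam_hat = 0.0

    beta, quad, logdetV, XtViX = pieces(lam_hat)
    sigma2_resid = quad / (n - p)
    sigma2_group = lam_hat * sigma2_resid
    cov = sigma2_resid * np.linalg.inv(XtViX)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    loglik = -0.5 * ((n - p) * (np.log(2.0 * np.pi *
                                       max(sigma2_resid, 1e-300)) + 1.0)
                     + logdetV + logdetXtViX)

    fitted = X @ beta
    var_f = float(np.var(fitted))
    denom = var_f + sigma2_group + sigma2_resid
    r2m = var_f / denom if denom > 0 else np.nan
    r2c = (var_f + sigma2_group) / denom if denom > 0 else np.nan

    return ModelFit(formula=formula, params=beta, cov_params=cov,
                    design_info=design_info, factor_levels=factor_levels,
                    sigma2_resid=float(sigma2_resid),
                    sigma2_group=float(sigma2_group), lam=float(lam_hat),
                    group_col=group_col, n_obs=n, df_resid=n - p,
                    loglik_reml=float(loglik), converged=converged,
                    r2_marginal=r2m, r2_conditional=r2c,
                    method="reml" if group_col else "ols",
                    warnings=list(warnings))


# ---------------------------------------------------------------------------
# Wald ANOVA (types II and III)
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    rows: pd.DataFrame  # term, df, chi_squared, p_value
    type: int

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def __repr__(self) -> str:
        return f"AnovaTable(type {self.type})\n{self.rows.to_string(index=False)}"


def _type2_contrast(fit: ModelFit, term: str) -> np.ndarray:
    """Marginality-respecting hypothesis rows for one term.

    The term's columns are tested after orthogonalising, in the metric of the
    coefficient covariance, against the columns of every term that contains
    it (the classical type-II construction).
    """
    p = len(fit.params)
    eye = np.eye(p)
    fac = fit.term_factors(term)
    term_cols = fit.term_columns(term)
    rel_cols: list[int] = []
    for other in fit.term_names:
        if other == term or other == "Intercept":
            continue
        if fac < fit.term_factors(other):
            rel_cols.extend(fit.term_columns(other))
    if not rel_cols:
        return eye[term_cols]
    X1 = eye[:, rel_cols]
    X2 = eye[:, rel_cols + term_cols]
    M = X2.T @ fit.cov_params @ X1
    Q, _ = np.linalg.qr(M, mode="complete")
    rank = np.linalg.matrix_rank(M)
    return (X2 @ Q[:, rank:]).T


def anova_wald(fit: ModelFit, type: int = 2) -> AnovaTable:
    """Term-wise Wald chi-square table (type II by default).

    Type III tests each term's sum-coded coefficients directly; type II
    respects marginality. On balanced designs the two coincide.
    """
    if not fit.converged:
        raise RuntimeError("refusing ANOVA on a non-converged fit")
    rows = []
    for term in fit.term_names:
        if term == "Intercept":
            continue
        if type == 3:
            L = np.eye(len(fit.params))[fit.term_columns(term)]
        elif type == 2:
            L = _type2_contrast(fit, term)
        else:
            raise ValueError("type must be 2 or 3")
        lb = L @ fit.params
        lvl = L @ fit.cov_params @ L.T
        rank = np.linalg.matrix_rank(lvl)
        if rank < L.shape[0]:
            rows.append({"term": term, "df": L.shape[0],
                         "chi_squared": np.nan, "p_value": np.nan,
                         "estimable": False})
            continue
        stat = float(lb @ np.linalg.solve(lvl, lb))
        df = L.shape[0]
        rows.append({"term": term, "df": df, "chi_squared": stat,
                     "p_value": float(chi2_dist.sf(stat, df)),
                     "estimable": True})
    return AnovaTable(rows=pd.DataFrame(rows), type=type)


def anova_type2_wald(fit: ModelFit) -> AnovaTable:
    return anova_wald(fit, type=2)
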