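"""OLS fitting, AIC, variance-inflation diagnostics, and backward elimination
with a forced covariate set.

The elimination rule: starting from the global model (all candidates plus the
forced covariates), repeatedly remove the non-forced term whose removal yields
the largest AIC decrease, stopping when no removal decreases AIC.  Forced
covariates are never eligible.  Categorical variables enter and leave as whole
indicator blocks.  For a single-parameter removal this AIC rule is equivalent
to a likelihood-ratio test at p = 0.157 (the chi-square(1) upper tail at 2).

Reported model fits (global and selected) go through statsmodels OLS; the
elimination loop itself runs on precomputed Gram matrices so that it can be
repeated across a thousand bootstrap resamples in seconds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .cohort import CohortTable

_AIC_TIE_TOL = 1e-9


@dataclass
class ModelSpec:
    """Which variable is the outcome, which covariates are forced (exempt from
    elimination), and which are candidates."""

    outcome: str
    forced: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = set(self.forced) & set(self.candidates)
        if overlap:
            raise ValueError(f"variables both forced and candidate: {sorted(overlap)}")
        if self.outcome in set(self.forced) | set(self.candidates):
            raise ValueError(f"outcome {self.outcome!r} cannot also be a covariate")

    @classmethod
    def from_meta(cls, meta) -> "ModelSpec":
        """Derive the model specification from cohort metadata roles."""
        outcome = [m.name for m in meta if m.role == "outcome"]
        if len(outcome) != 1:
            raise ValueError("metadata must declare exactly one outcome")
        return cls(
            outcome=outcome[0],
            forced=[m.name for m in meta if m.role == "forced"],
            candidates=[m.name for m in meta if m.role == "candidate"],
        )


@dataclass(frozen=True)
class Term:
    """One model term: a variable and the design columns it occupies
    (categorical variables occupy one indicator column per non-reference level)."""

    name: str
    columns: tuple[int, ...]


@dataclass
class FitResult:
    """One fitted linear model: coefficients with classical standard errors
    and t-based 95% limits, AIC, fit statistics, residuals and VIFs."""

    params: pd.Series
    bse: pd.Series
    conf_low: pd.Series
    conf_high: pd.Series
    aic: float
    r2: float
    adj_r2: float
    residuals: np.ndarray
    vif: pd.Series
    n: int
    k: int
    rss: float


@dataclass
class SelectionResult:
    """Outcome of backward elimination: the surviving variables (a superset of
    the forced set), the refitted model, and the ordered removal path."""

    selected: list[str]
    fit: FitResult
    elimination_path: list[tuple[str, float, float]]


# ---------------------------------------------------------------------------
# design construction


def expand_design(X: pd.DataFrame) -> tuple[np.ndarray, list[str], list[Term]]:
    """Expand a covariate frame into a design matrix with leading intercept.

    Numeric columns map to themselves; pandas-categorical columns map to one
    0/1 indicator per non-reference level (the first declared category is the
    reference), named ``var[level]`` and grouped into a single :class:`Term`.
    """
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"design requires complete cases; missing values in {bad}")
    n = len(X)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]
    terms: list[Term] = []
    for name in X.columns:
        s = X[name]
        if isinstance(s.dtype, pd.CategoricalDtype):
            levels = list(s.cat.categories)
            idxs = []
            for lev in levels[1:]:
                idxs.append(len(cols))
                cols.append((s == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
            terms.append(Term(name, tuple(idxs)))
        else:
            terms.append(Term(name, (len(cols),)))
            cols.append(s.to_numpy(dtype=float))
            names.append(name)
    return np.column_stack(cols), names, terms


def build_design(table: CohortTable, variables: list[str]) -> tuple[np.ndarray, list[str], list[Term]]:
    """Design matrix for the given cohort variables (complete cases assumed)."""
    return expand_design(table.df[list(variables)])


def _check_full_rank(Xmat: np.ndarray, names: list[str]) -> None:
    _, r, piv = scipy.linalg.qr(Xmat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = (diag.max() if diag.size else 0.0) * max(Xmat.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if Xmat.shape[1] > len(diag):
        bad += [names[j] for j in piv[len(diag):]]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear terms: {sorted(bad)}")


# ---------------------------------------------------------------------------
# AIC


def aic_from_rss(n: int, k: int, rss: float) -> float:
    """Gaussian AIC with constants: n*ln(RSS/n) + 2k + n*ln(2*pi) + n.

    ``k`` counts estimated mean parameters including the intercept.
    """
    if rss <= 0:
        raise ValueError("RSS must be positive (perfect fit has no finite Gaussian AIC)")
    return n * math.log(rss / n) + 2 * k + n * (math.log(2 * math.pi) + 1)


def aic(fit: FitResult) -> float:
    """AIC of a fitted model (same convention as :func:`aic_from_rss`)."""
    return aic_from_rss(fit.n, fit.k, fit.rss)


# ---------------------------------------------------------------------------
# fast Gram-matrix path used by elimination and the bootstrap


class _GramData:
    """Precomputed X'X, X'y and y'y; solves least squares for any column subset."""

    def __init__(self, Xmat: np.ndarray, y: np.ndarray):
        self.G = Xmat.T @ Xmat
        self.c = Xmat.T @ y
        self.yty = float(y @ y)
        self.n = len(y)

    def solve(self, cols: np.ndarray) -> tuple[np.ndarray | None, float]:
        G = self.G[np.ix_(cols, cols)]
        try:
            cf = scipy.linalg.cho_factor(G, lower=True, check_finite=False)
        except scipy.linalg.LinAlgError:
            return None, float("nan")
        beta = scipy.linalg.cho_solve(cf, self.c[cols], check_finite=False)
        rss = self.yty - float(self.c[cols] @ beta)
        return beta, max(rss, 0.0)

    def tstats(self, cols: np.ndarray) -> np.ndarray:
        beta, rss = self.solve(cols)
        if beta is None:
            return np.full(len(cols), np.nan)
        dof = self.n - len(cols)
        sigma2 = rss / dof if dof > 0 else np.nan
        cov = sigma2 * scipy.linalg.inv(self.G[np.ix_(cols, cols)])
        return beta / np.sqrt(np.diag(cov))


def _eliminate(
    gram: _GramData, terms: list[Term], forced: set[str]
) -> tuple[list[str], list[tuple[str, float, float]], np.ndarray, float]:
    """Run AIC backward elimination on precomputed Gram matrices.

    Returns (selected variable names, removal path, final column indices,
    final AIC).  Raises if the starting design is rank deficient.
    """
    def _aic_safe(k: int, rss: float) -> float:
        # a perfect fit dominates every comparison; removals cannot improve it
        return float("-inf") if rss <= 0 else aic_from_rss(gram.n, k, rss)

    active: dict[str, Term] = {t.name: t for t in terms}
    current = np.array(sorted({0} | {c for t in terms for c in t.columns}), dtype=int)
    beta, rss = gram.solve(current)
    if beta is None:
        raise np.linalg.LinAlgError("rank-deficient design in elimination")
    aic_cur = _aic_safe(len(current), rss)
    path: list[tuple[str, float, float]] = []
    while True:
        candidates = [t for name, t in sorted(active.items()) if name not in forced]
        if not candidates:
            break
        trial: list[tuple[float, Term]] = []
        for t in candidates:
            cols = current[~np.isin(current, t.columns)]
            _, rss_t = gram.solve(cols)
            if math.isnan(rss_t):
                continue
            trial.append((_aic_safe(len(cols), rss_t), t))
        if not trial:
            break
        best_aic = min(a for a, _ in trial)
        if not best_aic < aic_cur:
            break
        tied = [t for a, t in trial if a <= best_aic + _AIC_TIE_TOL]
        if len(tied) > 1:
            # remove the term whose (block-max) |t| statistic is smallest;
            # remaining ties broken lexicographically by name
            tvals = gram.tstats(current)
            pos = {c: i for i, c in enumerate(current)}
            tied.sort(key=lambda t: (max(abs(tvals[pos[c]]) for c in t.columns), t.name))
        chosen = tied[0]
        current = current[~np.isin(current, chosen.columns)]
        path.append((chosen.name, aic_cur, best_aic))
        aic_cur = best_aic
        del active[chosen.name]
    return sorted(active), path, current, aic_cur


# ---------------------------------------------------------------------------
# public fitting operations


def _fit_statsmodels(Xmat: np.ndarray, names: list[str], y: np.ndarray) -> FitResult:
    n, k = Xmat.shape
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    _check_full_rank(Xmat, names)
    res = sm.OLS(y, pd.DataFrame(Xmat, columns=names)).fit()
    ci = res.conf_int(alpha=0.05)
    non_const = [j for j, nm in enumerate(names) if nm != "const"]
    if len(non_const) >= 2:
        with np.errstate(divide="ignore"):
            vifs = pd.Series(
                [variance_inflation_factor(Xmat, j) for j in non_const],
                index=[names[j] for j in non_const],
            )
        vifs[vifs > 1e12] = np.inf
    else:
        vifs = pd.Series(dtype=float)
    rss = float(res.ssr)
    # a perfect fit has no finite Gaussian AIC; the standalone aic() op raises
    return FitResult(
        params=res.params,
        bse=res.bse,
        conf_low=ci[0],
        conf_high=ci[1],
        aic=aic_from_rss(n, k, rss) if rss > 0 else float("-inf"),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        residuals=np.asarray(res.resid),
        vif=vifs,
        n=n,
        k=k,
        rss=float(res.ssr),
    )


def fit_ols(table: CohortTable, terms: list[str], outcome: str) -> FitResult:
    """Fit OLS of *outcome* on *terms* (complete cases on the used columns)."""
    cc = table.complete_cases([outcome] + list(terms))
    Xmat, names, _ = build_design(cc, list(terms))
    y = cc.df[outcome].to_numpy(dtype=float)
    return _fit_statsmodels(Xmat, names, y)


def vif(table: CohortTable, terms: list[str]) -> pd.Series:
    """Variance inflation factor per design column: 1/(1-R2_j) from regressing
    column j on the remaining columns (intercept included).  Perfectly
    collinear columns report ``inf``."""
    if len(terms) < 2:
        raise ValueError("VIF needs at least 2 terms")
    cc = table.complete_cases(list(terms))
    Xmat, names, _ = build_design(cc, list(terms))
    non_const = [j for j, nm in enumerate(names) if nm != "const"]
    with np.errstate(divide="ignore"):
        vals = [variance_inflation_factor(Xmat, j) for j in non_const]
    out = pd.Series(vals, index=[names[j] for j in non_const])
    out[out > 1e12] = np.inf
    return out


class BackwardEliminationOLS(RegressorMixin, BaseEstimator):
    """Ordinary least squares with AIC backward elimination of non-forced terms.

    Parameters
    ----------
    forced : sequence of str, default ()
        Covariate column names exempt from elimination; all other columns of
        ``X`` are candidates.

    Attributes
    ----------
    selected_ : list of str
        Variable names surviving elimination (superset of ``forced``).
    elimination_path_ : list of (name, aic_before, aic_after)
        Removals in order; AIC is strictly decreasing along the path.
    fit_result_ : FitResult
        The refitted selected model.
    coef_, intercept_ : fitted coefficients of the selected model.
    """

    def __init__(self, forced: tuple[str, ...] = ()):
        self.forced = forced

    def fit(self, X: pd.DataFrame, y) -> "BackwardEliminationOLS":
        X = pd.DataFrame(X)
        yarr = np.asarray(y, dtype=float)
        unknown = [f for f in self.forced if f not in X.columns]
        if unknown:
            raise ValueError(f"forced variables not in X: {unknown}")
        Xmat, names, terms = expand_design(X)
        _check_full_rank(Xmat, names)
        gram = _GramData(Xmat, yarr)
        selected, path, cols, _ = _eliminate(gram, terms, set(self.forced))
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.categories_ = {
            c: list(X[c].cat.categories)
            for c in X.columns
            if isinstance(X[c].dtype, pd.CategoricalDtype)
        }
        self.selected_ = selected
        self.elimination_path_ = path
        self.design_columns_ = [names[j] for j in cols]
        self.fit_result_ = _fit_statsmodels(Xmat[:, cols], self.design_columns_, yarr)
        params = self.fit_result_.params
        self.intercept_ = float(params["const"])
        self.coef_ = params.drop("const").to_numpy()
        return self

    def _expanded(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        for c, cats in self.categories_.items():
            X[c] = pd.Series(pd.Categorical(X[c], categories=cats), index=X.index)
        Xmat, names, _ = expand_design(X[list(self.feature_names_in_)])
        return pd.DataFrame(Xmat, columns=names, index=X.index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = self._expanded(X)[self.design_columns_]
        return D.to_numpy() @ self.fit_result_.params.to_numpy()


def backward_eliminate(table: CohortTable, spec: ModelSpec) -> SelectionResult:
    """Backward elimination on a cohort, per the model spec's forced set."""
    variables = list(spec.forced) + list(spec.candidates)
    cc = table.complete_cases([spec.outcome] + variables)
    est = BackwardEliminationOLS(forced=tuple(spec.forced)).fit(
        cc.df[variables], cc.df[spec.outcome].to_numpy(dtype=float)
    )
    return SelectionResult(
        selected=est.selected_,
        fit=est.fit_result_,
        elimination_path=est.elimination_path_,
    )
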