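"""Dietary pattern derivation from food-frequency data.

Pipeline: group-level intake frequencies are adjusted for total energy intake
by the residual method (Willett), the group correlation matrix is decomposed
by the principal-component method, the leading components (default three) are
varimax-rotated, and participants are scored by the regression method with
scores standardised to mean 0 / SD 1 on the fitting sample.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


def energy_adjust(intake: pd.DataFrame, energy: pd.Series) -> pd.DataFrame:
    """Residual-method energy adjustment of group intakes.

    For each food group, intake is regressed on total energy; the adjusted
    value is the residual plus the predicted intake at the sample-mean energy,
    i.e. ``x - b * (e - mean(e))``.  Adjusted intakes are exactly uncorrelated
    with energy and keep the original group means.
    """
    e = np.asarray(energy, dtype=float)
    if len(e) < 3:
        raise ValueError("residual-method adjustment needs at least 3 participants")
    if np.any(e <= 0):
        raise ValueError("total energy intake must be positive for all participants")
    ec = e - e.mean()
    sse = float(ec @ ec)
    if sse == 0.0:
        raise ValueError("energy has zero variance; residual method undefined")
    X = intake.to_numpy(dtype=float)
    slopes = (ec @ X) / sse
    adjusted = X - np.outer(ec, slopes)
    return pd.DataFrame(adjusted, index=intake.index, columns=intake.columns)


class EnergyAdjuster(BaseEstimator, TransformerMixin):
    """Residual-method adjuster that freezes the intake-on-energy regressions
    learned on the fitting sample (``slope_``, ``intercept_``, ``mean_energy_``)
    so new participants can be adjusted consistently."""

    def fit(self, X: pd.DataFrame, energy: pd.Series) -> "EnergyAdjuster":
        e = np.asarray(energy, dtype=float)
        if len(e) < 3:
            raise ValueError("residual-method adjustment needs at least 3 participants")
        if np.any(e <= 0):
            raise ValueError("total energy intake must be positive for all participants")
        ec = e - e.mean()
        sse = float(ec @ ec)
        if sse == 0.0:
            raise ValueError("energy has zero variance; residual method undefined")
        Xm = X.to_numpy(dtype=float)
        self.mean_energy_ = float(e.mean())
        self.slope_ = pd.Series((ec @ Xm) / sse, index=X.columns)
        self.intercept_ = pd.Series(Xm.mean(axis=0), index=X.columns) - self.slope_ * self.mean_energy_
        self.groups_ = list(X.columns)
        return self

    def transform(self, X: pd.DataFrame, energy: pd.Series) -> pd.DataFrame:
        e = np.asarray(energy, dtype=float)
        resid = X[self.groups_].to_numpy(dtype=float) - (
            self.intercept_.to_numpy() + np.outer(e, self.slope_.to_numpy())
        )
        at_mean = self.intercept_.to_numpy() + self.mean_energy_ * self.slope_.to_numpy()
        return pd.DataFrame(resid + at_mean, index=X.index, columns=self.groups_)


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a p x k loading matrix."""
    p, k = loadings.shape
    if k == 1:
        return np.eye(1)
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        L = loadings @ R
        u, s, vt = np.linalg.svd(loadings.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p))
        R = u @ vt
        d_new = s.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return R


class DietaryPatternAnalysis(BaseEstimator, TransformerMixin):
    """Principal-component dietary pattern model with orthogonal rotation.

    Parameters
    ----------
    n_factors : int, default 3
        Number of retained components (the study design retains three,
        chosen from scree plot, eigenvalues and variance explained).
    rotation : {"varimax", "none"}, default "varimax"
        Orthogonal rotation criterion applied to the retained loadings.

    Attributes
    ----------
    loadings_ : pandas.DataFrame, groups x factors
        Rotated loadings, sign-fixed so each factor's largest-magnitude
        loading is positive.
    eigenvalues_ : numpy.ndarray
        All eigenvalues of the group correlation matrix, non-increasing;
        they sum to the number of groups.
    explained_variance_ratio_ : numpy.ndarray
        Per-component share of total variance.
    rotation_ : numpy.ndarray
        Orthonormal k x k rotation (including sign flips).
    """

    def __init__(self, n_factors: int = 3, rotation: str = "varimax"):
        self.n_factors = n_factors
        self.rotation = rotation

    def fit(self, X: pd.DataFrame, y=None) -> "DietaryPatternAnalysis":
        if X.isna().any().any():
            raise ValueError("adjusted intake table must have no missing cells")
        n, p = X.shape
        if n <= p:
            raise ValueError(f"need more participants ({n}) than food groups ({p})")
        if self.rotation not in {"varimax", "none"}:
            raise ValueError(f"unknown rotation {self.rotation!r}")
        self.groups_ = list(X.columns)
        Xm = X.to_numpy(dtype=float)
        self.mean_ = Xm.mean(axis=0)
        self.std_ = Xm.std(axis=0, ddof=1)
        if np.any(self.std_ == 0):
            flat = [g for g, s in zip(self.groups_, self.std_) if s == 0]
            raise ValueError(f"groups with zero variance: {flat}")
        corr = np.corrcoef(Xm, rowvar=False)
        w, V = np.linalg.eigh(corr)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        self.eigenvalues_ = w
        self.explained_variance_ratio_ = w / p
        rank = int((w > 1e-10).sum())
        if self.n_factors > rank:
            raise ValueError(f"n_factors={self.n_factors} exceeds rank {rank} of the correlation matrix")
        k = self.n_factors
        L = V[:, :k] * np.sqrt(w[:k])
        R = _varimax(L) if self.rotation == "varimax" else np.eye(k)
        Lr = L @ R
        # sign convention: dominant loading of each factor positive
        signs = np.sign(Lr[np.abs(Lr).argmax(axis=0), np.arange(k)])
        signs[signs == 0] = 1.0
        R = R @ np.diag(signs)
        Lr = L @ R
        self.rotation_ = R
        self.loadings_ = pd.DataFrame(Lr, index=self.groups_,
                                      columns=[f"factor{i + 1}" for i in range(k)])
        # regression-method scoring weights: W = corr^{-1} L
        self.weights_ = np.linalg.solve(corr, Lr)
        Z = (Xm - self.mean_) / self.std_
        raw = Z @ self.weights_
        self.score_mean_ = raw.mean(axis=0)
        self.score_std_ = raw.std(axis=0, ddof=1)
        if np.any(self.score_std_ == 0):
            raise ValueError("degenerate factor scores (zero variance)")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [g for g in self.groups_ if g not in X.columns]
        if missing:
            raise ValueError(f"adjusted intake table lacks fitted groups: {missing}")
        Z = (X[self.groups_].to_numpy(dtype=float) - self.mean_) / self.std_
        raw = Z @ self.weights_
        scores = (raw - self.score_mean_) / self.score_std_
        return pd.DataFrame(scores, index=X.index, columns=self.loadings_.columns)


def extract_patterns(adjusted_table: pd.DataFrame, n_factors: int = 3,
                     rotation: str = "varimax") -> DietaryPatternAnalysis:
    """Fit a :class:`DietaryPatternAnalysis` on an energy-adjusted intake table."""
    return DietaryPatternAnalysis(n_factors=n_factors, rotation=rotation).fit(adjusted_table)


def score_patterns(model: DietaryPatternAnalysis, adjusted_table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant factor scores (mean 0 / SD 1 on the fitting sample)."""
    return model.transform(adjusted_table)
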