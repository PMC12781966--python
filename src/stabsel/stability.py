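"""Bootstrap stability investigation of backward-eliminated linear models.

The selection procedure (AIC backward elimination with a forced covariate
set) is repeated on ``B`` nonparametric bootstrap resamples of the data.  For
every design column the run reports:

* **inclusion frequency** — percent of resamples in which the variable
  survives elimination (forced covariates are at 100 by construction);
* **final bootstrap estimate** ``beta_b`` — the median across *all* resamples
  of the coefficient, with 0 substituted whenever the variable was eliminated,
  together with 2.5th/97.5th percentile limits of the same vector;
* **standardised** ``beta_b`` — scaled by SD(x)/SD(y) on the full sample;
* **RMSD ratio** — root-mean-squared difference of the per-resample
  coefficients (zeros included) about the global-model estimate, divided by
  the global-model standard error (> 1 flags selection-added variability);
* **relative conditional bias** — percent deviation of the mean coefficient,
  conditional on selection, from the global-model estimate.

Globally the run reports the selected-model frequency (percent of resamples
choosing exactly the original selected set) and a shrinkage factor (the
cross-validated calibration slope of the selected model; < 1 means overfit).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import CohortTable
from .regression import (
    FitResult,
    ModelSpec,
    SelectionResult,
    Term,
    _eliminate,
    _fit_statsmodels,
    _GramData,
    build_design,
    expand_design,
)


@dataclass
class StabilityResult:
    """Per-variable and global outputs of one bootstrap stability run."""

    summary: pd.DataFrame
    B: int
    seed: int | None
    shrinkage_factor: float
    selected_model_frequency_pct: float
    n_redraws: int
    selected: list[str]
    r2_global: float
    adj_r2_global: float
    r2_selected: float
    adj_r2_selected: float
    boot_coefs: np.ndarray = field(repr=False, default=None)
    resample_indices: np.ndarray = field(repr=False, default=None)
    warnings: list[str] = field(default_factory=list)

    def identical(self, other: "StabilityResult") -> bool:
        """Bitwise equality of every numeric output (reproducibility check)."""
        return (
            self.summary.equals(other.summary)
            and self.B == other.B
            and self.shrinkage_factor == other.shrinkage_factor
            and self.selected_model_frequency_pct == other.selected_model_frequency_pct
            and self.n_redraws == other.n_redraws
            and self.selected == other.selected
            and np.array_equal(self.boot_coefs, other.boot_coefs)
            and np.array_equal(self.resample_indices, other.resample_indices)
        )


# ---------------------------------------------------------------------------
# elementary stability statistics


def rmsd_ratio(boot_coeffs: Sequence[float], beta_global: float, se_global: float) -> float:
    """sqrt(mean((b_i - beta_global)^2)) / se_global, zeros included."""
    b = np.asarray(boot_coeffs, dtype=float)
    if b.size == 0:
        raise ValueError("empty bootstrap coefficient vector")
    if not se_global > 0:
        raise ValueError("global standard error must be positive")
    return float(np.sqrt(np.mean((b - beta_global) ** 2)) / se_global)


def rc_bias(boot_coeffs_selected_only: Sequence[float], beta_global: float) -> float:
    """Relative conditional bias in percent: 100*(mean(selected b)/beta_global - 1).

    Undefined (NaN) when the global estimate is exactly 0 or the variable was
    never selected.
    """
    b = np.asarray(boot_coeffs_selected_only, dtype=float)
    if b.size == 0 or beta_global == 0:
        return float("nan")
    return float(100.0 * (b.mean() / beta_global - 1.0))


def standardized_beta(beta: float, sd_x: float, sd_y: float) -> float:
    """beta * SD(x) / SD(y)."""
    if not (sd_x > 0 and sd_y > 0):
        raise ValueError("standard deviations must be positive")
    return float(beta * sd_x / sd_y)


def selected_model_frequency(resample_selections: Sequence[frozenset], reference) -> float:
    """Percent of resamples whose selected variable set equals the reference."""
    sels = list(resample_selections)
    if not sels:
        raise ValueError("empty selection list")
    ref = frozenset(reference)
    return float(100.0 * sum(frozenset(s) == ref for s in sels) / len(sels))


# ---------------------------------------------------------------------------
# shrinkage (cross-validated calibration slope)


def _cv_linear_predictor(
    Xmat: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(y)
    if folds < 2 or folds > n:
        raise ValueError(f"folds must be in [2, n]; got {folds} with n={n}")
    order = rng.permutation(n)
    lp = np.empty(n)
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test, assume_unique=True)
        beta, *_ = np.linalg.lstsq(Xmat[train], y[train], rcond=None)
        # covariate part only: the training-fold intercept tracks the fold
        # mean and would bias the slope; the second-stage regression has its
        # own intercept, so the predictor's location is irrelevant
        lp[test] = Xmat[test, 1:] @ beta[1:]
    return lp


def _calibration_slope(lp: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(lp) == 0:
        raise ValueError("cross-validated linear predictor is constant; slope undefined")
    lc = lp - lp.mean()
    return float((lc @ (y - y.mean())) / (lc @ lc))


def global_shrinkage(
    table: CohortTable,
    selection: SelectionResult,
    folds: int = 10,
    random_state: int | None = 0,
) -> float:
    """Calibration slope of the selected model under K-fold cross-validation:
    the slope from regressing the outcome on the out-of-fold linear predictor
    (covariate part; the slope is location-invariant).  Values below 1
    indicate overfitting."""
    cc = table.complete_cases([table.outcome] + list(selection.selected))
    Xmat, _, _ = build_design(cc, list(selection.selected))
    y = cc.df[table.outcome].to_numpy(dtype=float)
    rng = np.random.default_rng(random_state)
    lp = _cv_linear_predictor(Xmat, y, folds, rng)
    return _calibration_slope(lp, y)


# ---------------------------------------------------------------------------
# the bootstrap selector


class BootstrapStabilitySelector(BaseEstimator):
    """Repeat AIC backward elimination over bootstrap resamples and summarise
    selection stability.

    Parameters
    ----------
    forced : sequence of str
        Covariates retained in every model and every resample.
    B : int, default 1000
        Number of bootstrap resamples (each of size n, drawn with replacement).
    random_state : int or None
        Seed; identical seeds give bit-identical results.
    shrinkage_folds : int, default 10
        Folds for the cross-validated calibration slope.
    max_redraw_rate : float, default 0.05
        Warn when more than this fraction of resamples had to be redrawn
        (degenerate designs are redrawn so that B stays exact).

    Attributes (after ``fit``)
    --------------------------
    result_ : StabilityResult
    summary_ : pandas.DataFrame indexed by design column
    global_fit_, selected_fit_ : FitResult
    inclusion_frequency_, beta_b_ : pandas.Series
    """

    def __init__(
        self,
        forced: tuple[str, ...] = (),
        B: int = 1000,
        random_state: int | None = None,
        shrinkage_folds: int = 10,
        max_redraw_rate: float = 0.05,
    ):
        self.forced = forced
        self.B = B
        self.random_state = random_state
        self.shrinkage_folds = shrinkage_folds
        self.max_redraw_rate = max_redraw_rate

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _draw_valid_resample(
        rng: np.random.Generator, Xmat: np.ndarray, n: int
    ) -> tuple[np.ndarray, np.ndarray, int]:
        """Draw resample indices until the resampled design has no constant
        column and a positive-definite Gram matrix; count redraws."""
        redraws = 0
        while True:
            idx = rng.integers(0, n, n)
            Xb = Xmat[idx]
            if Xb.shape[1] > 1 and np.any(np.ptp(Xb[:, 1:], axis=0) == 0):
                redraws += 1
                continue
            return idx, Xb, redraws

    def fit(self, X: pd.DataFrame, y) -> "BootstrapStabilitySelector":
        if self.B < 2:
            raise ValueError("B must be at least 2")
        X = pd.DataFrame(X)
        yarr = np.asarray(y, dtype=float)
        n = len(yarr)
        Xmat, names, terms = expand_design(X)
        p = Xmat.shape[1]
        col_of_var: dict[str, tuple[int, ...]] = {t.name: t.columns for t in terms}
        forced = set(self.forced)
        unknown = forced - set(X.columns)
        if unknown:
            raise ValueError(f"forced variables not in X: {sorted(unknown)}")

        self.global_fit_ = _fit_statsmodels(Xmat, names, yarr)
        gram_full = _GramData(Xmat, yarr)
        sel_vars, sel_path, sel_cols, _ = _eliminate(gram_full, terms, forced)
        self.selected_ = sel_vars
        self.elimination_path_ = sel_path
        self.selected_fit_ = _fit_statsmodels(
            Xmat[:, sel_cols], [names[j] for j in sel_cols], yarr
        )

        ss = np.random.SeedSequence(self.random_state)
        boot_ss, fold_ss = ss.spawn(2)
        rng = np.random.default_rng(boot_ss)

        boot_coefs = np.zeros((self.B, p))
        col_selected = np.zeros((self.B, p), dtype=bool)
        selections: list[frozenset] = []
        indices = np.empty((self.B, n), dtype=np.int64)
        total_redraws = 0
        for b in range(self.B):
            while True:
                idx, Xb, redraws = self._draw_valid_resample(rng, Xmat, n)
                total_redraws += redraws
                gram = _GramData(Xb, yarr[idx])
                try:
                    vars_b, _, cols_b, _ = _eliminate(gram, terms, forced)
                except np.linalg.LinAlgError:
                    total_redraws += 1
                    continue
                break
            indices[b] = idx
            beta_b, _ = gram.solve(cols_b)
            boot_coefs[b, cols_b] = beta_b
            col_selected[b, cols_b] = True
            selections.append(frozenset(vars_b))

        self.warnings_: list[str] = []
        if total_redraws > self.max_redraw_rate * self.B:
            msg = (
                f"{total_redraws} degenerate resamples redrawn out of B={self.B} "
                f"(> {self.max_redraw_rate:.0%})"
            )
            self.warnings_.append(msg)
            warnings.warn(msg)

        sd_y = float(np.std(yarr, ddof=1))
        rows = []
        gparams = self.global_fit_.params
        gbse = self.global_fit_.bse
        sparams = self.selected_fit_.params
        s_low, s_high = self.selected_fit_.conf_low, self.selected_fit_.conf_high
        for j, name in enumerate(names):
            coefs = boot_coefs[:, j]
            sel_mask = col_selected[:, j]
            bif = 100.0 * sel_mask.mean()
            med = float(np.median(coefs))
            lo, hi = np.percentile(coefs, [2.5, 97.5])
            bg, seg = float(gparams[name]), float(gbse[name])
            if name == "const":
                std_b = float("nan")
            else:
                sd_x = float(np.std(Xmat[:, j], ddof=1))
                std_b = standardized_beta(med, sd_x, sd_y) if sd_x > 0 else float("nan")
            rows.append({
                "variable": name,
                "beta_global": bg,
                "global_low": float(self.global_fit_.conf_low[name]),
                "global_high": float(self.global_fit_.conf_high[name]),
                "inclusion_frequency": bif,
                "beta_selected": float(sparams[name]) if name in sparams.index else float("nan"),
                "selected_low": float(s_low[name]) if name in sparams.index else float("nan"),
                "selected_high": float(s_high[name]) if name in sparams.index else float("nan"),
                "rmsd_ratio": rmsd_ratio(coefs, bg, seg),
                "rc_bias_pct": rc_bias(coefs[sel_mask], bg),
                "beta_b": med,
                "pct_2_5": float(lo),
                "pct_97_5": float(hi),
                "std_beta_b": std_b,
            })
        summary = pd.DataFrame(rows).set_index("variable")

        fold_rng = np.random.default_rng(fold_ss)
        folds = min(self.shrinkage_folds, n)
        lp = _cv_linear_predictor(Xmat[:, sel_cols], yarr, folds, fold_rng)
        shrink = _calibration_slope(lp, yarr)

        smf = selected_model_frequency(selections, frozenset(sel_vars))

        self.boot_coefs_ = boot_coefs
        self.resample_indices_ = indices
        self.selections_ = selections
        self.design_columns_ = names
        self.summary_ = summary
        self.inclusion_frequency_ = summary["inclusion_frequency"]
        self.beta_b_ = summary["beta_b"]
        self.shrinkage_factor_ = shrink
        self.selected_model_frequency_ = smf
        self.n_redraws_ = total_redraws
        self.result_ = StabilityResult(
            summary=summary,
            B=self.B,
            seed=self.random_state,
            shrinkage_factor=shrink,
            selected_model_frequency_pct=smf,
            n_redraws=total_redraws,
            selected=sel_vars,
            r2_global=self.global_fit_.r2,
            adj_r2_global=self.global_fit_.adj_r2,
            r2_selected=self.selected_fit_.r2,
            adj_r2_selected=self.selected_fit_.adj_r2,
            boot_coefs=boot_coefs,
            resample_indices=indices,
            warnings=list(self.warnings_),
        )
        return self


def bootstrap_stability(
    table: CohortTable,
    spec: ModelSpec,
    B: int = 1000,
    seed: int | None = None,
    shrinkage_folds: int = 10,
) -> StabilityResult:
    """Run the full stability investigation on a cohort (complete cases)."""
    variables = list(spec.forced) + list(spec.candidates)
    cc = table.complete_cases([spec.outcome] + variables)
    sel = BootstrapStabilitySelector(
        forced=tuple(spec.forced), B=B, random_state=seed, shrinkage_folds=shrinkage_folds
    ).fit(cc.df[variables], cc.df[spec.outcome].to_numpy(dtype=float))
    return sel.result_
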