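"""Scoring of multi-item psychosocial instruments and within-domain imputation.

Instruments such as the Perceived Stress Scale, the Rosenberg self-esteem scale
or the MSPSS are scored by summing (or averaging) Likert item responses after
reverse-coding negatively worded items.  Scores left incomplete by item
non-response are handled by *within-domain imputation*: a respondent's missing
item is filled with the mean of their observed items on the same instrument,
but only when the instrument's cohort-level missingness falls inside a
configurable band (default 5-10%) and the respondent answered at least half of
the items.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class ScaleDefinition:
    """One multi-item instrument: items, response range, reverse-coded items,
    attainable score range, and aggregation rule (sum or mean)."""

    name: str
    items: list[str]
    response_min: int
    response_max: int
    score_min: float
    score_max: float
    reverse_items: list[str] = field(default_factory=list)
    aggregation: str = "sum"

    def __post_init__(self) -> None:
        if self.aggregation not in {"sum", "mean"}:
            raise ValueError(f"aggregation must be 'sum' or 'mean', got {self.aggregation!r}")
        if not set(self.reverse_items) <= set(self.items):
            extra = sorted(set(self.reverse_items) - set(self.items))
            raise ValueError(f"reverse items not in item list for {self.name!r}: {extra}")
        if self.response_min >= self.response_max:
            raise ValueError(f"response range of {self.name!r} is empty")
        k = len(self.items)
        lo = k * self.response_min if self.aggregation == "sum" else self.response_min
        hi = k * self.response_max if self.aggregation == "sum" else self.response_max
        if not (np.isclose(self.score_min, lo) and np.isclose(self.score_max, hi)):
            raise ValueError(
                f"declared score range [{self.score_min}, {self.score_max}] of "
                f"{self.name!r} inconsistent with {k} items on "
                f"[{self.response_min}, {self.response_max}] under {self.aggregation!r} "
                f"(expected [{lo}, {hi}])"
            )


@dataclass
class ImputationPolicy:
    """Band of cohort-level missingness inside which imputation is applied,
    and the minimum fraction of a respondent's items that must be observed."""

    min_band: float = 0.05
    max_band: float = 0.10
    min_observed_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_band <= self.max_band < 1):
            raise ValueError("need 0 < min_band <= max_band < 1")
        if not (0 < self.min_observed_fraction <= 1):
            raise ValueError("min_observed_fraction must be in (0, 1]")


def _reverse_code(items: pd.DataFrame, sdef: ScaleDefinition) -> pd.DataFrame:
    """Map reverse-coded items r -> response_min + response_max - r; validate range."""
    x = items[sdef.items].astype(float).copy()
    for item in sdef.items:
        col = x[item]
        bad = col.notna() & ((col < sdef.response_min) | (col > sdef.response_max))
        if bad.any():
            i = bad[bad].index[0]
            raise ValueError(
                f"response {col[i]!r} to item {item!r} of scale {sdef.name!r} "
                f"outside [{sdef.response_min}, {sdef.response_max}]"
            )
    for item in sdef.reverse_items:
        x[item] = sdef.response_min + sdef.response_max - x[item]
    return x


def score_scale(responses: Mapping[str, float] | pd.Series, sdef: ScaleDefinition) -> float:
    """Score one respondent; missing (NaN) if any item is unanswered."""
    row = pd.DataFrame([dict(responses)])
    rc = _reverse_code(row, sdef).iloc[0]
    if rc.isna().any():
        return float("nan")
    return float(rc.sum() if sdef.aggregation == "sum" else rc.mean())


def score_scale_table(items: pd.DataFrame, sdef: ScaleDefinition) -> pd.Series:
    """Score every respondent in an item table; incomplete rows score NaN."""
    rc = _reverse_code(items, sdef)
    agg = rc.sum(axis=1, min_count=len(sdef.items)) if sdef.aggregation == "sum" else rc.mean(axis=1)
    if sdef.aggregation == "mean":
        agg[rc.isna().any(axis=1)] = np.nan
    return agg.rename(sdef.name)


class WithinDomainImputer(BaseEstimator, TransformerMixin):
    """Person-mean (within-instrument) imputation of Likert item tables.

    ``fit`` measures the instrument's cohort-level missingness rate on the
    analysis sample; ``transform`` fills a respondent's missing items with the
    mean of their observed items (in reverse-coded space) only when that rate
    lies inside ``policy``'s band and the respondent observed at least
    ``policy.min_observed_fraction`` of the items.  Rows that remain
    incomplete pass through untouched and score as missing.

    Attributes
    ----------
    cohort_missing_rate_ : float
        Fraction of respondents with at least one missing item at fit time.
    active_ : bool
        Whether the rate fell inside the imputation band.
    log_ : pandas.DataFrame
        One row per imputed cell (respondent index, item, imputed value)
        from the most recent ``transform``.
    """

    def __init__(self, scale: ScaleDefinition, policy: ImputationPolicy | None = None):
        self.scale = scale
        self.policy = policy

    def _policy(self) -> ImputationPolicy:
        return self.policy if self.policy is not None else ImputationPolicy()

    def fit(self, X: pd.DataFrame, y=None) -> "WithinDomainImputer":
        items = X[self.scale.items]
        self.n_fit_ = len(items)
        self.cohort_missing_rate_ = float(items.isna().any(axis=1).mean()) if len(items) else 0.0
        pol = self._policy()
        self.active_ = bool(pol.min_band <= self.cohort_missing_rate_ <= pol.max_band)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        pol = self._policy()
        rc = _reverse_code(X, self.scale)
        out = X.copy()
        log_rows = []
        if self.active_:
            obs_frac = rc.notna().mean(axis=1)
            person_mean = rc.mean(axis=1)
            for idx in rc.index[rc.isna().any(axis=1) & (obs_frac >= pol.min_observed_fraction)]:
                for item in self.scale.items:
                    if pd.isna(rc.at[idx, item]):
                        v = person_mean[idx]
                        if item in self.scale.reverse_items:
                            # store in original coding so re-scoring round-trips
                            v_orig = self.scale.response_min + self.scale.response_max - v
                        else:
                            v_orig = v
                        out.at[idx, item] = v_orig
                        log_rows.append({"respondent": idx, "item": item, "value": float(v_orig)})
        self.log_ = pd.DataFrame(log_rows, columns=["respondent", "item", "value"])
        return out

    def score(self, X: pd.DataFrame) -> pd.Series:
        """Impute then score; rows still incomplete score NaN."""
        return score_scale_table(self.transform(X), self.scale)


def within_domain_impute(
    item_table: pd.DataFrame,
    sdef: ScaleDefinition,
    policy: ImputationPolicy | None = None,
    cohort_missing_rate: float | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Complete an item table and return ``(score column, imputation log)``.

    ``cohort_missing_rate`` defaults to the rate measured on ``item_table``
    itself; pass it explicitly when the analysis sample differs.
    """
    imp = WithinDomainImputer(sdef, policy).fit(item_table)
    if cohort_missing_rate is not None:
        pol = imp._policy()
        imp.cohort_missing_rate_ = float(cohort_missing_rate)
        imp.active_ = bool(pol.min_band <= cohort_missing_rate <= pol.max_band)
    scores = imp.score(item_table)
    return scores, imp.log_
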