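"""Participant-table I/O, glycemic categorisation, and descriptive summaries.

A cohort is a plain rectangular table (one row per participant) plus a list of
:class:`VariableMeta` records declaring, for every column, its analysis role
(outcome / forced covariate / candidate covariate / id / stratum) and its type
(continuous / binary / categorical).  The metadata file is what turns a CSV
into an analysable cohort: it is the single source of truth for the model
specification downstream.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = {"outcome", "forced", "candidate", "id", "stratum"}
VTYPES = {"continuous", "binary", "categorical"}

#: Strings treated as an explicit missing marker when reading CSV cells.
MISSING_MARKERS = {"", "NA", "NaN", "nan", "na"}

#: Glycemic category labels, in increasing order of HbA1c.
GLYCEMIC_CATEGORIES = ("normal", "prediabetes", "diabetes")

#: American Diabetes Association HbA1c cut points (percent units).
PREDIABETES_THRESHOLD = 5.7
DIABETES_THRESHOLD = 6.5


@dataclass
class VariableMeta:
    """Declaration of one cohort column.

    Parameters
    ----------
    name
        Column name; unique within a cohort.
    role
        One of ``outcome``, ``forced``, ``candidate``, ``id``, ``stratum``.
    vtype
        One of ``continuous``, ``binary``, ``categorical``.
    levels
        Ordered category labels (categorical), or the two labels mapped to
        0/1 in order (binary, optional — numeric 0/1 input also accepted).
    reference_level
        Reference category for indicator coding (categorical only).
    recode
        Optional string->numeric map applied on read, e.g. genotype strings
        ``{"GG": 0, "AG": 1, "AA": 2}`` to an additive allele dose.
    summary
        Which location statistic :func:`summarize_cohort` reports for a
        continuous variable: ``"mean"`` (mean/SD) or ``"median"`` (median/IQR).
    """

    name: str
    role: str
    vtype: str
    levels: list[str] | None = None
    reference_level: str | None = None
    recode: dict[str, float] | None = None
    summary: str = "mean"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.vtype not in VTYPES:
            raise ValueError(f"unknown vtype {self.vtype!r} for variable {self.name!r}")
        if self.vtype == "categorical":
            if not self.levels:
                raise ValueError(f"categorical variable {self.name!r} needs levels")
            if self.reference_level is None:
                self.reference_level = self.levels[0]
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"reference level {self.reference_level!r} of {self.name!r} "
                    f"not among declared levels {self.levels}"
                )
        if self.summary not in {"mean", "median"}:
            raise ValueError(f"summary must be 'mean' or 'median', got {self.summary!r}")


@dataclass
class CohortTable:
    """A typed participant table with variable metadata."""

    df: pd.DataFrame
    meta: list[VariableMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [m.name for m in self.meta]
        if len(set(names)) != len(names):
            raise ValueError("variable names in metadata are not unique")
        outcomes = [m for m in self.meta if m.role == "outcome"]
        if len(outcomes) != 1:
            raise ValueError(f"exactly one outcome variable required, found {len(outcomes)}")
        missing_cols = set(names) - set(self.df.columns)
        if missing_cols:
            raise ValueError(f"columns declared in metadata but absent from data: {sorted(missing_cols)}")
        out = outcomes[0].name
        vals = pd.to_numeric(self.df[out], errors="coerce")
        if (vals.dropna() <= 0).any():
            raise ValueError(f"outcome {out!r} must be positive where present")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def outcome(self) -> str:
        return next(m.name for m in self.meta if m.role == "outcome")

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def variables(self, role: str) -> list[str]:
        return [m.name for m in self.meta if m.role == role]

    def complete_cases(self, columns: Sequence[str] | None = None) -> "CohortTable":
        """Rows with no missing value in *columns* (default: all declared)."""
        cols = list(columns) if columns is not None else [m.name for m in self.meta]
        keep = self.df[cols].notna().all(axis=1)
        return CohortTable(self.df.loc[keep].reset_index(drop=True), self.meta)


def _unbool(v):
    # YAML 1.1 reads bare Yes/No as booleans; level labels must stay strings
    return {True: "Yes", False: "No"}.get(v, v)


def _load_meta_file(meta_path: str | Path) -> list[VariableMeta]:
    raw = yaml.safe_load(Path(meta_path).read_text())
    entries = raw["variables"] if isinstance(raw, Mapping) else raw
    for e in entries:
        if e.get("levels"):
            e["levels"] = [_unbool(x) for x in e["levels"]]
        if "reference_level" in e:
            e["reference_level"] = _unbool(e["reference_level"])
        if e.get("recode"):
            e["recode"] = {_unbool(k): v for k, v in e["recode"].items()}
    return [VariableMeta(**e) for e in entries]


def _coerce_column(series: pd.Series, m: VariableMeta) -> pd.Series:
    s = series.copy()
    if m.recode:
        s = s.map(lambda v: m.recode.get(v, v) if isinstance(v, str) else v)
    if m.vtype == "continuous":
        return pd.to_numeric(s, errors="raise").astype(float)
    if m.vtype == "binary":
        if m.levels:
            mapping = {m.levels[0]: 0.0, m.levels[1]: 1.0,
                       "0": 0.0, "1": 1.0, "0.0": 0.0, "1.0": 1.0, 0: 0.0, 1: 1.0}
            bad = s.dropna().map(lambda v: v not in mapping)
            if bad.any():
                i = int(bad[bad].index[0])
                raise ValueError(
                    f"value {s[i]!r} of binary variable {m.name!r} at row {i} "
                    f"not among levels {m.levels}"
                )
            return s.map(lambda v: mapping.get(v, v)).astype(float)
        return pd.to_numeric(s, errors="raise").astype(float)
    # categorical
    bad = s.dropna().map(lambda v: v not in m.levels)
    if bad.any():
        i = int(bad[bad].index[0])
        raise ValueError(
            f"value {s[i]!r} of categorical variable {m.name!r} at row {i} "
            f"not among declared levels {m.levels}"
        )
    return pd.Series(pd.Categorical(s, categories=m.levels), index=s.index)


def read_cohort(path: str | Path, meta_path: str | Path) -> CohortTable:
    """Read a cohort CSV together with its variable-metadata file.

    Every CSV column must be declared in the metadata (unknown columns are
    rejected); empty cells and ``NA`` are normalised to a single missing
    sentinel; typed columns are produced according to each declaration.
    """
    meta = _load_meta_file(meta_path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    declared = {m.name for m in meta}
    unknown = [c for c in df.columns if c not in declared]
    if unknown:
        raise ValueError(f"columns present in data but absent from metadata: {unknown}")
    outcome = [m.name for m in meta if m.role == "outcome"]
    if outcome and outcome[0] not in df.columns:
        raise ValueError(f"outcome column {outcome[0]!r} missing from data file")
    df = df.apply(lambda col: col.map(lambda v: np.nan if v in MISSING_MARKERS else v))
    cols = {}
    for m in meta:
        if m.name in df.columns:
            cols[m.name] = _coerce_column(df[m.name], m)
        else:
            raise ValueError(f"column {m.name!r} declared in metadata but absent from data")
    return CohortTable(pd.DataFrame(cols), meta)


def write_cohort(table: CohortTable, path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the data CSV (missing as empty cells) and, optionally, metadata YAML."""
    table.df.to_csv(path, index=False, na_rep="")
    if meta_path is not None:
        entries = []
        for m in table.meta:
            e = {"name": m.name, "role": m.role, "vtype": m.vtype}
            if m.levels:
                e["levels"] = list(m.levels)
            if m.vtype == "categorical":
                e["reference_level"] = m.reference_level
            if m.recode:
                e["recode"] = dict(m.recode)
            if m.summary != "mean":
                e["summary"] = m.summary
            entries.append(e)
        Path(meta_path).write_text(yaml.safe_dump({"variables": entries}, sort_keys=False))


def classify_hba1c(value: float) -> str:
    """Glycemic category of one HbA1c value (percent units).

    ``>= 6.5`` -> diabetes; ``5.7 to < 6.5`` -> prediabetes; ``< 5.7`` -> normal.
    """
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise ValueError(f"HbA1c must be a positive number, got {value!r}")
    if v >= DIABETES_THRESHOLD:
        return "diabetes"
    if v >= PREDIABETES_THRESHOLD:
        return "prediabetes"
    return "normal"


def classify_hba1c_series(values: Iterable[float]) -> pd.Series:
    """Vectorised :func:`classify_hba1c`; missing values stay missing."""
    s = pd.Series(list(values), dtype=float)
    out = pd.Series(pd.NA, index=s.index, dtype="object")
    ok = s.notna()
    if (s[ok] <= 0).any():
        raise ValueError("HbA1c values must be positive")
    out[ok & (s < PREDIABETES_THRESHOLD)] = "normal"
    out[ok & (s >= PREDIABETES_THRESHOLD) & (s < DIABETES_THRESHOLD)] = "prediabetes"
    out[ok & (s >= DIABETES_THRESHOLD)] = "diabetes"
    return out


def format_percent(count: int, total: int) -> str:
    """Percentage rounded to the nearest whole percent, printed with one decimal.

    207 of 349 renders as ``"59.0%"``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return f"{math.floor(pct + 0.5):.1f}%"


def _summarize_continuous(s: pd.Series, how: str) -> list[tuple[str, str]]:
    v = s.dropna().astype(float)
    if v.empty:
        return [("n", "0")]
    rows = []
    if how == "median":
        iqr = v.quantile(0.75) - v.quantile(0.25)
        rows.append(("Median (IQR)", f"{v.median():.1f} ({iqr:.1f})"))
    else:
        rows.append(("Mean (SD)", f"{v.mean():.1f} ({v.std(ddof=1):.1f})" if len(v) > 1 else f"{v.mean():.1f} (—)"))
    rows.append(("Range", f"{v.min():.1f}–{v.max():.1f}"))
    return rows


def _summarize_categorical(s: pd.Series, levels: Sequence[str]) -> list[tuple[str, str]]:
    v = s.dropna()
    total = len(v)
    rows = []
    for lev in levels:
        cnt = int((v == lev).sum())
        if total == 0:
            rows.append((str(lev), "0"))
        else:
            rows.append((str(lev), f"{cnt} ({format_percent(cnt, total)})"))
    return rows


def summarize_cohort(table: CohortTable, stratum: str | None = None) -> pd.DataFrame:
    """Descriptive table: mean/SD + range or median/IQR for continuous
    variables, counts and whole-percent shares for categorical/binary ones,
    overall and per stratum level.
    """
    if table.n == 0:
        raise ValueError("cannot summarize an empty cohort")
    groups: list[tuple[str, pd.DataFrame]] = [("Total", table.df)]
    if stratum is not None:
        m = table.meta_for(stratum)
        levels = m.levels if m.levels else sorted(table.df[stratum].dropna().unique())
        for lev in levels:
            key = lev
            if m.vtype == "binary" and m.levels:
                key = float(m.levels.index(lev))
            groups.append((str(lev), table.df[table.df[stratum] == key]))
    records = []
    for m in table.meta:
        if m.role == "id" or m.name == stratum:
            continue
        for gname, gdf in groups:
            s = gdf[m.name]
            if m.vtype == "continuous":
                rows = _summarize_continuous(s, m.summary) if len(gdf) else [("n", "0")]
            else:
                levels = m.levels or ["0", "1"]
                if m.vtype == "binary" and m.levels:
                    s = s.map({0.0: m.levels[0], 1.0: m.levels[1]})
                rows = _summarize_categorical(s, levels) if len(gdf) else [("n", "0")]
            for stat, value in rows:
                records.append({"variable": m.name, "statistic": stat, "group": gname,
                                "value": value, "n": int(s.notna().sum())})
    long = pd.DataFrame.from_records(records)
    wide = long.pivot_table(index=["variable", "statistic"], columns="group",
                            values="value", aggfunc="first", sort=False)
    wide.columns.name = None
    return wide.reset_index()
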