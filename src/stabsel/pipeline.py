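"""Pipeline orchestration: impute scale scores, model, stabilise, and render
report tables shaped like the study's descriptive and stability tables."""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import CohortTable
from .regression import FitResult, ModelSpec, SelectionResult, backward_eliminate, fit_ols
from .scales import ImputationPolicy, ScaleDefinition, within_domain_impute
from .stability import StabilityResult, bootstrap_stability

#: Inclusion-frequency threshold (percent) above which a variable is flagged
#: as meaningful in the run manifest.
MEANINGFUL_BIF_PCT = 60.0


@dataclass
class RunManifest:
    """Everything needed to re-execute a run and audit what it did."""

    config_hash: str
    seed: int | None
    B: int
    n_analyzed: int
    imputed_variables: list[str]
    flagged_meaningful: list[str]
    warnings: list[str]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


@dataclass
class PipelineResult:
    global_fit: FitResult
    selection: SelectionResult
    stability: StabilityResult
    manifest: RunManifest
    table: CohortTable = field(repr=False, default=None)


def _config_hash(**params) -> str:
    payload = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def flagged_meaningful(stability: StabilityResult) -> list[str]:
    """Design columns with bootstrap inclusion frequency above 60 percent."""
    s = stability.summary
    keep = (s.index != "const") & (s["inclusion_frequency"] > MEANINGFUL_BIF_PCT)
    return list(s.index[keep])


def run_pipeline(
    table: CohortTable,
    spec: ModelSpec | None = None,
    B: int = 1000,
    seed: int | None = None,
    shrinkage_folds: int = 10,
    item_tables: dict[str, tuple[pd.DataFrame, ScaleDefinition]] | None = None,
    impute: bool = True,
    imputation_policy: ImputationPolicy | None = None,
) -> PipelineResult:
    """Run impute -> model -> stabilise on one cohort.

    ``item_tables`` optionally maps a score column name to its raw item table
    and scale definition; when present (and ``impute`` is true) the score
    column is recomputed with within-domain imputation before modeling.  The
    three model products (global, selected, bootstrap-stability) are computed
    on the same complete-case sample.
    """
    if spec is None:
        spec = ModelSpec.from_meta(table.meta)
    imputed_vars: list[str] = []
    run_warnings: list[str] = []
    if item_tables:
        df = table.df.copy()
        for name, (items, sdef) in item_tables.items():
            if impute:
                scores, log = within_domain_impute(items, sdef, imputation_policy)
                if len(log):
                    imputed_vars.append(name)
            else:
                from .scales import score_scale_table

                scores = score_scale_table(items, sdef)
            df[name] = scores.to_numpy()
        table = CohortTable(df, table.meta)

    variables = list(spec.forced) + list(spec.candidates)
    cc = table.complete_cases([spec.outcome] + variables)
    n_params = 1 + len(variables)  # lower bound; categoricals add more
    if cc.n <= n_params:
        raise ValueError(
            f"complete-case n={cc.n} does not exceed the parameter count "
            f"(>= {n_params}); cannot fit the global model"
        )
    global_fit = fit_ols(cc, variables, spec.outcome)
    selection = backward_eliminate(cc, spec)
    stability = bootstrap_stability(cc, spec, B=B, seed=seed, shrinkage_folds=shrinkage_folds)
    run_warnings.extend(stability.warnings)
    manifest = RunManifest(
        config_hash=_config_hash(
            outcome=spec.outcome, forced=spec.forced, candidates=spec.candidates,
            B=B, seed=seed, folds=shrinkage_folds, n=cc.n, impute=impute,
        ),
        seed=seed,
        B=B,
        n_analyzed=cc.n,
        imputed_variables=imputed_vars,
        flagged_meaningful=flagged_meaningful(stability),
        warnings=run_warnings,
    )
    return PipelineResult(global_fit, selection, stability, manifest, cc)


def run_stratified(
    table: CohortTable,
    spec: ModelSpec | None = None,
    stratum: str = "sex",
    **options,
) -> dict[str, PipelineResult]:
    """Run the pipeline independently within each level of *stratum*.

    The stratum variable is dropped from the forced and candidate sets inside
    each level (it is constant there).  Undersized levels are skipped with a
    warning rather than failing the whole run.
    """
    if spec is None:
        spec = ModelSpec.from_meta(table.meta)
    m = table.meta_for(stratum)
    if m.vtype == "continuous":
        raise ValueError(f"stratum {stratum!r} must be binary or categorical")
    observed = table.df[stratum].dropna().unique()
    if len(observed) < 2:
        raise ValueError(f"stratum {stratum!r} is constant; cannot stratify")
    sub_spec = ModelSpec(
        outcome=spec.outcome,
        forced=[v for v in spec.forced if v != stratum],
        candidates=[v for v in spec.candidates if v != stratum],
    )
    levels = m.levels if m.levels else sorted(observed)
    results: dict[str, PipelineResult] = {}
    for lev in levels:
        key = lev
        if m.vtype == "binary" and m.levels:
            key = float(m.levels.index(lev))
        sub_df = table.df[table.df[stratum] == key].reset_index(drop=True)
        sub = CohortTable(sub_df, table.meta)
        try:
            results[str(lev)] = run_pipeline(sub, sub_spec, **options)
        except ValueError as e:
            warnings.warn(f"stratum level {lev!r} skipped: {e}")
    return results


#: Column order of the rendered stability table.
_REPORT_COLUMNS = [
    "beta_global", "global_low", "global_high", "inclusion_frequency",
    "beta_selected", "selected_low", "selected_high",
    "rmsd_ratio", "rc_bias_pct", "beta_b", "pct_2_5", "pct_97_5", "std_beta_b",
]


def render_stability_table(stability: StabilityResult) -> tuple[pd.DataFrame, str]:
    """Rounded (3 decimals) report table plus a markdown rendering.

    Selected-model cells are blank for variables eliminated from the selected
    model; full-precision numbers live in the result object, not here.
    """
    out = stability.summary[_REPORT_COLUMNS].round(3)
    md_df = out.reset_index().fillna("")
    md = md_df.to_markdown(index=False)
    return out, md


def compare_stability(a: StabilityResult, b: StabilityResult) -> pd.DataFrame:
    """Per-variable inclusion-frequency comparison (sensitivity report)."""
    joined = pd.DataFrame({
        "bif_a": a.summary["inclusion_frequency"],
        "bif_b": b.summary["inclusion_frequency"],
    })
    joined["bif_diff"] = joined["bif_a"] - joined["bif_b"]
    return joined


def serialize_result(result: PipelineResult) -> dict:
    """Full-precision JSON-ready payload (the rounded CSV is presentation only)."""
    st = result.stability
    return {
        "summary": st.summary.reset_index().to_dict(orient="records"),
        "globals": {
            "B": st.B,
            "seed": st.seed,
            "shrinkage_factor": st.shrinkage_factor,
            "selected_model_frequency_pct": st.selected_model_frequency_pct,
            "n_redraws": st.n_redraws,
            "selected": st.selected,
            "r2_global": st.r2_global,
            "adj_r2_global": st.adj_r2_global,
            "r2_selected": st.r2_selected,
            "adj_r2_selected": st.adj_r2_selected,
        },
        "manifest": result.manifest.__dict__,
    }


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the report CSV + markdown, full-precision JSON, and manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, md = render_stability_table(result.stability)
    table.to_csv(out / "stability_table.csv")
    (out / "stability_table.md").write_text(md + "\n")
    (out / "results.json").write_text(json.dumps(serialize_result(result), indent=2))
    (out / "manifest.json").write_text(result.manifest.to_json())
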