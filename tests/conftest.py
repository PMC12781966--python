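import numpy as np
import pandas as pd
import pytest

import stabsel as ss


@pytest.fixture(scope="session")
def small_cohort() -> ss.CohortTable:
    """A modest synthetic cohort for fast pipeline-level tests."""
    return ss.generate_cohort(ss.default_config(n=200, seed=42))


@pytest.fixture(scope="session")
def small_spec(small_cohort) -> ss.ModelSpec:
    return ss.ModelSpec.from_meta(small_cohort.meta)


def make_simple_cohort(n: int, n_candidates: int, seed: int,
                       beta_forced: float = 1.0,
                       beta_cand: tuple[float, ...] = ()) -> ss.CohortTable:
    """Tiny cohort: one forced continuous predictor plus noise candidates."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 1 + n_candidates))
    beta = np.zeros(1 + n_candidates)
    beta[0] = beta_forced
    beta[1:1 + len(beta_cand)] = beta_cand
    y = 6.0 + x @ beta + rng.normal(0, 0.5, n)
    cols = {"y": y, "xf": x[:, 0]}
    meta = [ss.VariableMeta("y", "outcome", "continuous"),
            ss.VariableMeta("xf", "forced", "continuous")]
    for j in range(n_candidates):
        cols[f"c{j}"] = x[:, 1 + j]
        meta.append(ss.VariableMeta(f"c{j}", "candidate", "continuous"))
    return ss.CohortTable(pd.DataFrame(cols), meta)
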