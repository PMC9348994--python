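import numpy as np
import pandas as pd
import pytest

from vitdmr import simulate


@pytest.fixture(scope="session")
def default_params():
    return simulate.SimParams(n_individuals=4000, seed=7)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    panel = simulate.simulate_panel(default_params)
    cohort = simulate.simulate_cohort(panel, default_params)
    return panel, cohort


@pytest.fixture(scope="session")
def medium_cohort():
    """Cohort large enough for survival-model checks (shared, read-only)."""
    params = simulate.SimParams(n_individuals=50_000, seed=3)
    panel = simulate.simulate_panel(params)
    cohort = simulate.simulate_cohort(panel, params)
    return params, panel, cohort


def make_summary_table(rows):
    """Summary-statistics frame from (id, ea, oa, eaf, beta, se, pval) tuples."""
    return pd.DataFrame(
        rows,
        columns=["variant_id", "effect_allele", "other_allele", "eaf", "beta",
                 "se", "pval"],
    )


def make_harmonized(bx, sx, by, sy):
    """Harmonized-statistics frame straight from per-variant arrays."""
    return pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(len(bx))],
            "beta_exposure": np.asarray(bx, float),
            "se_exposure": np.asarray(sx, float),
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float),
        }
    )
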