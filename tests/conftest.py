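import numpy as np
import pandas as pd
import pytest

from sibmr import SimParams, simulate_cohort
from sibmr.simcohort import true_weight_table, variant_info


@pytest.fixture(scope="session")
def null_cohort():
    """A mid-size cohort with every bias channel off (pure causal model)."""
    params = SimParams(n_families=2000, n_snps=40, theta=-0.2, seed=11)
    return params, simulate_cohort(params)


@pytest.fixture(scope="session")
def biased_cohort():
    """A cohort with dynastic effects, assortative mating and confounding on."""
    params = SimParams(
        n_families=4000, n_snps=40, theta=-0.2, delta=0.2, eta=0.1,
        lambda_=0.1, rho_am=0.3, conf_edu=0.3, conf_out=0.3, seed=7,
    )
    return params, simulate_cohort(params)


def instrument_of(params: SimParams, cohort: pd.DataFrame) -> pd.Series:
    """Standardized polygenic score built from the generating weights."""
    from sibmr import compute_pgs

    return compute_pgs(cohort, true_weight_table(params),
                       variant_info(params.n_snps))


@pytest.fixture(scope="session")
def three_cluster_fixture():
    """6 observations in 3 clusters with a fixed design, for sandwich oracles."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame({"x": [0.5, -1.2, 0.3, 2.0, -0.7, 1.1]})
    y = 1.0 + 2.0 * X["x"].to_numpy() + rng.normal(0, 0.5, 6)
    clusters = np.array([0, 0, 1, 1, 2, 2])
    return y, X, clusters
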