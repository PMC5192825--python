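import numpy as np
import pandas as pd
import pytest

from evomark import (LabeledMatrix, RunConfig, SyntheticCohortSpec,
                     parse_newick, simulate_cohort)

# ((A,B),(C,D)) ultrametric, every branch 50 Myr: total length 300
FOUR_TAXON_NEWICK = "((A:50,B:50):50,(C:50,D:50):50);"


@pytest.fixture
def four_taxon_tree():
    return parse_newick(FOUR_TAXON_NEWICK)


@pytest.fixture
def small_config():
    """Reduced-scale config keeping every pipeline stage exercised."""
    return RunConfig(n_submodels=4, n_inner_bootstraps=10, n_trees=10,
                     lambda_grid_size=5, lambda_grid_ratio=0.1)


@pytest.fixture
def tiny_cohort():
    spec = SyntheticCohortSpec(m=80, p=25, n_informative=3, effect_size=1.5,
                               class_balance=0.4, conservation_coupling=1.0,
                               seed=42)
    return simulate_cohort(spec)


@pytest.fixture
def toy_matrix():
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.normal(size=(20, 4)),
                     index=[f"s{i}" for i in range(20)],
                     columns=["f1", "f2", "f3", "f4"])
    y = pd.Series([1] * 10 + [0] * 10, index=X.index)
    return LabeledMatrix(X=X, y=y)
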