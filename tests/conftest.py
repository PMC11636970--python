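import numpy as np
import pandas as pd
import pytest

import keloidomics as k


@pytest.fixture(scope="session")
def small_cohort():
    """Small two-group microbiome with planted signal and modules."""
    tab, meta, truth = k.generate_microbiome(
        n_mk=20, n_ns=20, n_taxa=60, n_diff=6, effect_log2fc=2.0,
        n_modules=3, module_size=5, module_rho=0.8, seed=11)
    return tab, meta, truth


@pytest.fixture(scope="session")
def study_cohort():
    """Cohort-scale dataset (56/60 samples, 149 taxa)."""
    tab, meta, truth = k.generate_microbiome(seed=7)
    return tab, meta, truth


@pytest.fixture()
def toy_table():
    df = pd.DataFrame(
        {"A": [0.2, 0.4], "B": [0.8, 0.6]},
        index=["s1", "s2"])
    return k.AbundanceTable(df, normalized=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
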