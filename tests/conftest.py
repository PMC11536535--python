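import numpy as np
import pandas as pd
import pytest

import tcellomics as tc


@pytest.fixture(scope="session")
def metab_data():
    """Study-design metabolomics simulation with a few planted effects."""
    spec = tc.MetabSimSpec(
        n_metabolites=60, noise_sd=0.1, time_sd=0.05, mcar_rate=0.02,
        effect_table={0: (1.0, 0.0, 0.0), 1: (0.0, 0.0, 1.0)},
        groups_forced_missing={2: {"Naive/CTRL"}},
        seed=11)
    return tc.simulate_metabolomics(spec)


@pytest.fixture(scope="session")
def phospho_data():
    spec = tc.PhosphoSimSpec(n_proteins=500, n_diff=10, shift=2.0,
                             duplicate_cv=0.05, seed=11)
    return tc.simulate_phospho_array(spec)


@pytest.fixture(scope="session")
def interactome_data():
    spec = tc.NetSimSpec(n_nodes=200, module_size=6, module_density=1.0,
                         probe_size=3, directed_fraction=0.4, seed=11)
    return tc.simulate_interactome(spec)


@pytest.fixture
def tiny_matrix():
    """4 samples x 3 features, complete, positive."""
    return pd.DataFrame(
        np.array([[10.0, 100.0, 5.0],
                  [20.0, 200.0, 6.0],
                  [15.0, 150.0, 7.0],
                  [12.0, 120.0, 8.0]]),
        index=pd.Index([f"s{i}" for i in range(1, 5)], name="sample"),
        columns=["f1", "f2", "f3"])


@pytest.fixture
def tiny_design():
    return pd.DataFrame(
        {"CELL": ["Naive", "Naive", "PLP", "PLP"],
         "TREATMENT": ["CTRL", "PTTH", "CTRL", "PTTH"],
         "TIME": ["6h", "12h", "6h", "12h"],
         "group": ["Naive/CTRL", "Naive/PTTH", "PLP/CTRL", "PLP/PTTH"]},
        index=[f"s{i}" for i in range(1, 5)])
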