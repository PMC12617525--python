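import numpy as np
import pandas as pd
import pytest

import cofracnet as cf


def make_matrix(values, proteins=None, fractions=None, **meta):
    values = np.asarray(values, dtype=float)
    proteins = proteins or [f"P{i}" for i in range(1, values.shape[0] + 1)]
    fractions = fractions or [f"fraction_{j:03d}"
                              for j in range(1, values.shape[1] + 1)]
    return cf.ElutionMatrix(pd.DataFrame(values, index=proteins,
                                         columns=fractions), **meta)


@pytest.fixture(scope="session")
def small_config():
    return cf.SimulationConfig(n_complexes=10, n_background_proteins=20,
                               n_fractions=48, seed=7)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return cf.generate_truth(small_config)


@pytest.fixture(scope="session")
def noise_free_wt(small_truth, small_config):
    cfg = cf.SimulationConfig(n_complexes=10, n_background_proteins=20,
                              n_fractions=48, seed=7, count_noise=0.0,
                              dropout_prob=0.0)
    return cf.simulate_elution(small_truth, cfg, "WT")[0]
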