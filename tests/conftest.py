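import numpy as np
import pytest

from snpburden import (SimulationConfig, SnpAssociationModel, load_gwas_panel,
                       simulate_cohort)


@pytest.fixture(scope="session")
def panel():
    return load_gwas_panel()


@pytest.fixture(scope="session")
def small_study(panel):
    """Synthetic study of 300 cases / 400 controls at the packaged panel."""
    cfg = SimulationConfig(panel=panel, n_cases=300, n_controls=400, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def assoc_results(small_study):
    panel, matrix, cohort = small_study
    return SnpAssociationModel(matrix, cohort, panel).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
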