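import numpy as np
import pandas as pd
import pytest

from tdrscan.core_data import CellScreen, ExpressionMatrix, PatientCohort
from tdrscan.models import ModelParams
from tdrscan.synthetic_data import SimulationParams, generate_paired_datasets

#: Small forests so scans stay fast; forest size only shifts variance here.
FAST_MODELS = ModelParams(n_trees_rf=25, n_trees_ranger=50)


@pytest.fixture(scope="session")
def small_pair():
    """A modest screen/cohort pair with clear planted signal, no batch gap."""
    params = SimulationParams(
        n_genes=300,
        n_cell_lines=120,
        n_patients=24,
        effect_size=3.0,
        batch_shift_sd=0.0,
        batch_scale_sd=0.0,
        noise_sd=1.0,
        seed=11,
    )
    return generate_paired_datasets(params)


@pytest.fixture(scope="session")
def batched_pair():
    """Same structure but with a real train-vs-patient batch shift."""
    params = SimulationParams(
        n_genes=300,
        n_cell_lines=120,
        n_patients=24,
        effect_size=3.0,
        batch_shift_sd=1.0,
        batch_scale_sd=0.1,
        noise_sd=1.0,
        seed=13,
    )
    return generate_paired_datasets(params)


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(5, 1, (6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(values)
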