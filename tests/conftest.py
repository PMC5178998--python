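import numpy as np
import pandas as pd
import pytest

from metasig import ExpressionMatrix, SimulationConfig, simulate_expression


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 4 samples with one constant gene, single dataset."""
    values = pd.DataFrame(
        {
            "s1": [1.0, 0.0, 5.0, 2.0],
            "s2": [2.0, 2.0, 5.0, 4.0],
            "s3": [3.0, 4.0, 5.0, 6.0],
            "s4": [4.0, 6.0, 5.0, 8.0],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return ExpressionMatrix(values)


@pytest.fixture(scope="session")
def easy_cohort():
    """Two clean modules plus noise; shared by several recovery tests."""
    sim = SimulationConfig(
        n_samples=400,
        module_sizes=(12, 10),
        module_names=("immunity", "hormonal_survival"),
        within_module_rho=0.85,
        cross_module_rho=np.array([[1.0, -0.46], [-0.46, 1.0]]),
        n_noise_genes=20,
        seed=7,
    )
    m, truth = simulate_expression(sim)
    return sim, m, truth
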