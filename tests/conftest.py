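import warnings

import numpy as np
import pandas as pd
import pytest

import depmark as dm


@pytest.fixture(scope="session")
def small_mouse_config():
    return dm.MouseSimConfig(
        n_probes_blood=400, n_probes_brain=400,
        n_stress_genes=15, n_reversal_genes=12, n_flxonly_genes=8,
        n_concordant_genes=12, n_discordant_genes=8, seed=11,
    )


@pytest.fixture(scope="session")
def mouse_data(small_mouse_config):
    return dm.simulate_mouse_study(small_mouse_config)


@pytest.fixture(scope="session")
def human_data():
    return dm.simulate_human_cohort(dm.HumanSimConfig(seed=7))


@pytest.fixture(scope="session")
def mouse_result(mouse_data):
    matrices, behavior, _ = mouse_data
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return dm.mouse_discovery(matrices, behavior)


def toy_matrix(values, groups, tissue="blood"):
    """Build an ExpressionMatrix from a 2D array and group labels."""
    values = np.asarray(values, dtype=float)
    samples = [f"s{i}" for i in range(values.shape[1])]
    genes = [f"g{i}" for i in range(values.shape[0])]
    sheet = pd.DataFrame(
        {"tissue": tissue, "group": groups, "subject": samples},
        index=pd.Index(samples, name="sample"),
    )
    return dm.ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        samples=sheet,
    )
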