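import numpy as np
import pytest

from lipsite import default_dose_series, simulate_lip_experiment
from lipsite.differential import median_center


@pytest.fixture(scope="session")
def series():
    return default_dose_series()


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Small zero-noise LiP simulation: every responsive peptide lies exactly
    on its 4PL curve."""
    quant, structure, truth = simulate_lip_experiment(
        n_peptides=40, n_responsive=4, ec50=1e-6, effect_log2=1.5,
        noise_cv=0.0, seed=42,
    )
    return quant, structure, truth


@pytest.fixture(scope="session")
def noisy_experiment():
    """Mid-size CV-5% simulation used by several recovery tests."""
    quant, structure, truth = simulate_lip_experiment(
        n_peptides=120, n_responsive=8, ec50=1e-6, effect_log2=1.5,
        noise_cv=0.05, seed=7,
    )
    return median_center(quant), structure, truth
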