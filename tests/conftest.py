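import numpy as np
import pytest

from immunoquant import synthetic as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noisy_field():
    """One mixed hemocyte field reused by several cell-assay tests.

    noise_sd=11 is 5% of the rendered cell/bead intensity band (220).
    """
    truth = syn.FieldTruth(
        n_cells=400,
        spread_fraction=0.6,
        phagocytic_fraction=0.5,
        mean_spots=2.0,
        noise_sd=11.0,
        seed=2024,
    )
    dic, nuc, bact, table = syn.generate_hemocyte_field(truth)
    return truth, dic, nuc, bact, table
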