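import numpy as np
import pytest

from mlago.km_dataset import KmRecord, KmTable
from mlago.kinetics import generate_quasi_data
from mlago.synthetic import ToyPathwaySpec, make_toy_pathway

TOY_TIMEPOINTS = np.linspace(0.5, 10.0, 10)


@pytest.fixture
def small_table() -> KmTable:
    return KmTable(
        [
            KmRecord("1.1.1.1", "C00001", "T00001", 0.5),
            KmRecord("1.1.1.2", "C00002", "T00001", 2.0),
            KmRecord("2.1.1.1", "C00001", "T00002", 0.01),
            KmRecord("1.1.1.1", "C00002", "T00002", 1.0),
            KmRecord("6.3.1.2", "C00002", "T00003", 10.0),
        ]
    )


@pytest.fixture(scope="session")
def toy_chain():
    """3-reaction Michaelis-Menten chain with its true parameters."""
    model, p_true = make_toy_pathway(ToyPathwaySpec(n_reactions=3, seed=7))
    return model, p_true


@pytest.fixture(scope="session")
def toy_quasi_data(toy_chain):
    model, p_true = toy_chain
    return generate_quasi_data(model, p_true, TOY_TIMEPOINTS)
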