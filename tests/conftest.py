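import numpy as np
import pytest
from hypothesis import settings

from phenogate import SyntheticSpec, annotate, generate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

FIVE_TYPE_FRACTIONS = {
    "Tcell": 0.30, "Bcell": 0.25, "Macrophage": 0.20,
    "Endothelial": 0.15, "Fibroblast": 0.10,
}


@pytest.fixture(scope="session")
def five_type_data():
    """Well-separated 5-type proteomics fixture (seed 1)."""
    spec = SyntheticSpec(
        n_cells=800, cell_type_fractions=dict(FIVE_TYPE_FRACTIONS),
        n_markers=15, signal_shift=4.0, seed=1,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def five_type_annotated(five_type_data):
    mat, sig, truth = five_type_data
    assign, thresholds, mc = annotate(mat, sig, band=(0.01, 0.05), seed=1)
    return assign, thresholds, mc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
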