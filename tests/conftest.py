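import numpy as np
import pandas as pd
import pytest

from ricapanel.core import GenotypeMatrix, MarkerRecord
from ricapanel import synthetic_data as sd


@pytest.fixture
def tiny_markers():
    return [
        MarkerRecord("chr01:1000", "chr01", 1000, ("A", "G")),
        MarkerRecord("chr01:2000", "chr01", 2000, ("C", "T")),
        MarkerRecord("chr02:1500", "chr02", 1500, ("A", "C")),
    ]


@pytest.fixture
def tiny_matrix(tiny_markers):
    calls = np.array(
        [
            ["AA", "CC", "AA"],
            ["AG", "CT", "CC"],
            ["GG", "NN", "AC"],
        ]
    )
    return GenotypeMatrix(
        markers=tiny_markers, samples=["s1", "s2", "s3"], calls=calls
    )


@pytest.fixture(scope="session")
def small_panel():
    return sd.simulate_panel(200, seed=11)


@pytest.fixture(scope="session")
def clean_pop_matrix(small_panel):
    """60 inbreds from one population, no noise: exact ground truth."""
    model = sd.population_model(
        small_panel, n_subpops=1, divergence=0.0, residual_het_rate=0.0,
        missing_rate=0.0, seed=7,
    )
    return sd.simulate_inbreds(small_panel, model, 60)


@pytest.fixture(scope="session")
def structured_matrix(small_panel):
    """Three diverged subpopulations with realistic noise."""
    model = sd.population_model(
        small_panel, n_subpops=3, divergence=0.4, seed=5,
        subpop_names=("indica", "japonica", "aus"),
    )
    return sd.simulate_inbreds(small_panel, model, [40, 15, 5])
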