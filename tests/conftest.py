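import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from epifst import PeakMatrix, SampleMetadata, SimulationParams, simulate_peak_matrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["h1", "h2", "c1", "c2"],
                "species": ["human", "human", "chimp", "chimp"],
            }
        )
    )


@pytest.fixture
def toy_pm(toy_metadata) -> PeakMatrix:
    peaks = pd.DataFrame(
        {
            "peak_id": ["p1", "p2", "p3"],
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 5000, 200],
            "end": [600, 5400, 900],
        }
    )
    dens = np.array(
        [
            [0.0, 2.0, 4.0, 6.0],
            [1.0, 1.0, 1.0, 1.0],
            [0.0, 2.0, 1.0, 1.0],
        ]
    )
    return PeakMatrix(peaks, dens, toy_metadata)


@pytest.fixture(scope="session")
def primate_pm():
    """Small simulated three-species matrix with ground truth."""
    params = SimulationParams(n_peaks=300, fraction_divergent=0.3, seed=11)
    return simulate_peak_matrix(params)


def random_instance(rng, sizes=None, k_max=4):
    """A random small one-way design: (values, labels)."""
    if sizes is None:
        k = rng.integers(2, k_max + 1)
        sizes = rng.integers(2, 8, size=k)
    labels = np.repeat([f"sp{i}" for i in range(len(sizes))], sizes)
    values = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=len(labels))
    return values, labels
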