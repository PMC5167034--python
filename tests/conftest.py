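import numpy as np
import pytest

from estabkit import (
    InferenceParams,
    ObservationSeries,
    species_params_from_delta,
)
from estabkit.gillespie import default_observation_times


@pytest.fixture(scope="session")
def theta_d1_a05() -> InferenceParams:
    """Truth parameter vector at delta = 1, alpha = 0.5."""
    sp = species_params_from_delta(1.0)
    return InferenceParams.from_truth(sp, resident_K=10_000.0, alpha=0.5)


@pytest.fixture(scope="session")
def toy_obs() -> ObservationSeries:
    """A tiny hand-specified three-point observation series (delta = 1)."""
    return ObservationSeries(
        times=np.array([0.5, 1.0, 1.5]),
        latent=np.array([50.0, 62.0, 80.0]),
        counts=np.array([13, 15, 22]),
        f=0.25,
        n0=40,
    )


@pytest.fixture(scope="session")
def standard_times() -> np.ndarray:
    return default_observation_times()
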