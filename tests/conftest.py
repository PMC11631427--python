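import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from libramix import BcrTable, NBParams, UmiCountMatrix
from libramix.synthetic import generate_dataset, preset_scenarios

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def well_separated():
    """One well-separated synthetic sample (counts, bcr, truth)."""
    return generate_dataset(preset_scenarios()["well_separated"])


@pytest.fixture(scope="session")
def mixture_sample():
    """Seeded draw from the canonical well-separated mixture.

    Returns (counts, labels, truth_params) with noise weight 0.7,
    noise NB(2, 0.7), signal NB(20, 0.2).
    """
    rng = np.random.default_rng(12345)
    n = 2000
    labels = rng.random(n) < 0.3  # True = signal
    counts = rng.negative_binomial(2, 0.7, n)
    counts[labels] = rng.negative_binomial(20, 0.2, int(labels.sum()))
    return counts, labels, {"omega_noise": 0.7,
                            "noise": NBParams(2.0, 0.7),
                            "signal": NBParams(20.0, 0.2)}


@pytest.fixture
def small_bcr():
    """Hand-built BCR table: one multi-heavy cell, one light-only cell."""
    return BcrTable(pd.DataFrame({
        "cell_id": ["c1", "c1", "c2", "c2", "c3", "c4"],
        "chain": ["heavy", "heavy", "heavy", "light", "heavy", "light"],
        "cdr3_aa": ["ARDYW", "ARGGW", "ARDYW", "QQSYS", "CAKDW", "QQSYS"],
    }))


@pytest.fixture
def toy_matrix():
    return UmiCountMatrix(
        ["c1", "c2", "c3"], ["ag1", "ag2"],
        np.array([[0, 3], [12, 0], [7, 1]]))
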