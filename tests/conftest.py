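import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from utrxfer.data import ExpressionDataset
from utrxfer.synthetic import LibrarySpec, make_ground_truth, sample_library


@pytest.fixture(scope="session")
def ground_truth():
    # seed 1 is the calibrated study mapping (mu span that sits inside
    # the default sorter bin range)
    return make_ground_truth(["A", "B"], seed=1,
                             context_offsets={"B": 2.0})


@pytest.fixture(scope="session")
def small_library(ground_truth):
    return sample_library(ground_truth, LibrarySpec(n_variants=300), "A", seed=3)


@pytest.fixture()
def toy_dataset():
    import pandas as pd
    rng = np.random.default_rng(5)
    n = 100
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, 12)]) for _ in range(n)]
    frame = pd.DataFrame({
        "id": [f"t{i:03d}" for i in range(n)],
        "sequence": seqs,
        "context": "A",
        "mu": np.linspace(1.0, 10.0, n),
        "sigma": 0.4,
    })
    return ExpressionDataset(frame)
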