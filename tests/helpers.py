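"""Shared construction helpers for the test suite."""

import numpy as np
import pandas as pd

from utrxfer.data import ExpressionDataset


def make_dataset(mu_values, context="A", seq_len=8, seed=0):
    """Dataset with the given mu values and random unique sequences."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    n = len(mu_values)
    seqs = set()
    while len(seqs) < n:
        seqs.add("".join(bases[rng.integers(0, 4, seq_len)]))
    frame = pd.DataFrame({
        "id": [f"r{i:04d}" for i in range(n)],
        "sequence": sorted(seqs),
        "context": context,
        "mu": np.asarray(mu_values, dtype=float),
    })
    return ExpressionDataset(frame)
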