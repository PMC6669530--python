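import numpy as np
import pandas as pd
import pytest

from mixtox.synthetic import PeptideCountMatrix


@pytest.fixture
def toy_peptide_matrix():
    """Five proteins with 1..5 peptides, two conditions x three replicates.

    Counts are deterministic (value = 10 + peptide index) so filter and
    aggregation arithmetic can be checked by hand.
    """
    rows = []
    peptides, proteins = [], []
    p = 0
    for i, n_pep in enumerate([1, 2, 3, 4, 5], start=1):
        for _ in range(n_pep):
            peptides.append(f"pep{p:02d}")
            proteins.append(f"prot{i}")
            rows.append([10.0 + p] * 6)
            p += 1
    samples = [f"{c}_r{r}" for c in ("ctl", "trt") for r in (1, 2, 3)]
    counts = pd.DataFrame(rows, index=peptides, columns=samples)
    design = pd.DataFrame(
        {
            "sample": samples,
            "condition": ["ctl"] * 3 + ["trt"] * 3,
            "biorep": [1, 2, 3, 1, 2, 3],
        }
    )
    pmap = pd.Series(proteins, index=peptides, name="protein")
    return PeptideCountMatrix(counts, pmap, design)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
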