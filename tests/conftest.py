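import numpy as np
import pandas as pd
import pytest

import sedna
from sedna.tables import MarkerCountTable


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic survey shared across read-only tests."""
    cfg = sedna.default_config(seed=11, n_samples=24, n_taxa=15)
    return sedna.generate_dataset(cfg)


@pytest.fixture()
def toy_table():
    """Hand-built 4-ASV x (3 samples + 2 blanks) table."""
    counts = pd.DataFrame(
        {
            "S1": [100, 0, 5, 40],
            "S2": [80, 10, 0, 60],
            "S3": [120, 0, 0, 55],
            "EB1": [0, 0, 300, 1],
            "PB1": [0, 0, 250, 0],
        },
        index=["ASV1", "ASV2", "ASV3", "ASV4"],
    )
    roles = pd.Series(
        {"S1": "sample", "S2": "sample", "S3": "sample",
         "EB1": "extraction_blank", "PB1": "pcr_blank"})
    return MarkerCountTable(counts=counts, roles=roles, marker="toy")


def random_table(rng: np.random.Generator, n_asvs: int = 30, n_samples: int = 12,
                 n_blanks: int = 3) -> MarkerCountTable:
    """Random count table with blanks, used by brute-force oracle tests."""
    cols = [f"S{i}" for i in range(n_samples)] + [f"B{i}" for i in range(n_blanks)]
    counts = rng.integers(0, 500, size=(n_asvs, len(cols)))
    counts[rng.random(counts.shape) < 0.5] = 0
    roles = pd.Series(["sample"] * n_samples
                      + ["extraction_blank", "pcr_blank"][: min(2, n_blanks)]
                      + ["pcr_blank"] * max(0, n_blanks - 2),
                      index=cols)
    return MarkerCountTable(
        counts=pd.DataFrame(counts, index=[f"A{i:03d}" for i in range(n_asvs)], columns=cols),
        roles=roles, marker="rand")
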