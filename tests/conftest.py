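import logging

import numpy as np
import pandas as pd
import pytest

from rejuvenome import SimConfig, generate_dataset

logging.disable(logging.INFO)


TINY = SimConfig(n_chrom=2, chrom_length=2_000_000, n_genes=300,
                 n_peaks_per_mark=200, n_cpgs=5000, n_switch_domains=4,
                 n_bivalent_domains=6, n_proteins=100, n_islands=100, seed=7)


@pytest.fixture(scope="session")
def tiny_config():
    return TINY


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(TINY)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def two_group_sheet(n_per_group: int, age_levels=("young", "old")) -> pd.DataFrame:
    """Minimal two-cell sample sheet (ctrl env) for direct engine tests."""
    rows = []
    for age in age_levels:
        for r in range(1, n_per_group + 1):
            sid = f"{age[0].upper()}C{r}"
            rows.append((sid, age, "ctrl", r, sid))
    return pd.DataFrame(rows, columns=["sample", "age", "env", "replicate",
                                       "techrep_group"])
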