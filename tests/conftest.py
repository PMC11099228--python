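import numpy as np
import pandas as pd
import pytest

from axismr.instruments import HarmonizedSet
from axismr.io import COLUMNS, SummaryDataset


def make_dataset(trait_id, rows):
    """Build a SummaryDataset from a list of per-variant dicts, filling
    unspecified fields with innocuous defaults."""
    defaults = dict(chrom="1", pos=1000, effect_allele="A", other_allele="G",
                    eaf=0.3, beta=0.1, se=0.02, pvalue=1e-6, n=10_000)
    full = []
    for i, r in enumerate(rows):
        rec = {**defaults, "snp_id": f"rs{i}", "pos": 1000 + i * 1_000_000,
               **r}
        full.append(rec)
    return SummaryDataset(trait_id, pd.DataFrame(full, columns=COLUMNS))


def make_harmonized(gamma, Gamma, gamma_se=None, Gamma_se=None,
                    exposure_id="X", outcome_id="Y"):
    gamma = np.asarray(gamma, float)
    Gamma = np.asarray(Gamma, float)
    gamma_se = (np.full_like(gamma, 0.01) if gamma_se is None
                else np.asarray(gamma_se, float))
    Gamma_se = (np.full_like(Gamma, 0.1) if Gamma_se is None
                else np.asarray(Gamma_se, float))
    ids = [f"rs{i}" for i in range(len(gamma))]
    return HarmonizedSet(exposure_id, outcome_id, ids, gamma, gamma_se,
                         Gamma, Gamma_se)


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def harmonized_factory():
    return make_harmonized


@pytest.fixture
def rng():
    return np.random.default_rng(20240503)
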