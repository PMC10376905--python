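import numpy as np
import pytest
from hypothesis import settings

import myeloboost as mb

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-variant labeled synthetic cohort (heavy enough to train on,
    light enough for unit tests)."""
    cfg = mb.CohortConfig(n_snv=500, n_mnv=10, n_indel=90,
                          n_benign=520, n_pathogenic=80, seed=11)
    return mb.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return mb.build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def separable_table():
    """A 2-feature-driven, linearly separable labeled feature table:
    class 1 rows get Freq > 0.6 and MAFbin = -1, class 0 the reverse."""
    rng = np.random.default_rng(7)
    n = 500
    labels = (np.arange(n) < n // 2).astype(int)
    table = {
        "chr": rng.integers(1, 23, n).astype(float),
        "POS": rng.uniform(1e6, 2e8, n),
        "TypeBin": rng.integers(0, 3, n).astype(float),
        "Exon": rng.integers(0, 12, n).astype(float),
        "Freq": np.where(labels == 1, rng.uniform(0.65, 1.0, n),
                         rng.uniform(0.0, 0.55, n)),
        "MAFbin": np.where(labels == 1, -1.0, rng.uniform(0.01, 0.5, n)),
        "Coverage": rng.integers(300, 3000, n).astype(float),
        "Protbin": rng.integers(0, 3, n).astype(float),
        "aarefbin": rng.integers(1, 22, n).astype(float),
        "aamutbin": rng.integers(0, 23, n).astype(float),
        "aarefChemical": rng.choice([1.1, 2.5, 3.1, 4.2], n),
        "aamutChemicalVal": rng.choice([0.0, 1.4, 2.6, 4.3], n),
        "Grantham": rng.choice([-1.0, 5.0, 60.0, 215.0], n),
        "varEffectBin": rng.choice([-1.0, 0.0, 1.0, 2.0, 3.0], n),
        "isMut": labels.astype(float),
    }
    import pandas as pd
    return pd.DataFrame(table)
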