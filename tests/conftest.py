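import numpy as np
import pandas as pd
import pytest

from pretermbiome.core_data import TaxaTable
from pretermbiome.synthetic import CohortSpec, generate_cohort, generate_positive_controls


def make_meta(sample_ids, **overrides):
    """Minimal valid metadata frame for hand-built fixtures."""
    n = len(sample_ids)
    base = {
        "sample_id": sample_ids,
        "subject_id": [f"subj{i}" for i in range(n)],
        "visit": [1] * n,
        "race_group": ["AA"] * n,
        "ga_sample": [18.0] * n,
        "ga_delivery": [39.0] * n,
        "outcome": ["term"] * n,
        "nulliparous": [False] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


@pytest.fixture
def tiny_table():
    """3 samples x 4 taxa, hand-written."""
    ra = pd.DataFrame(
        [[0.5, 0.3, 0.15, 0.05], [0.9, 0.05, 0.03, 0.02], [0.25, 0.25, 0.25, 0.25]],
        index=["s1", "s2", "s3"],
        columns=["taxA", "taxB", "taxC", "taxD"],
    )
    return TaxaTable(ra, make_meta(["s1", "s2", "s3"]))


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded ~70-subject synthetic cohort with its ground truth."""
    spec = CohortSpec(n_subjects=70, seed=11)
    table, truth = generate_cohort(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def controls_table():
    spec = CohortSpec(seed=23)
    return spec, generate_positive_controls(spec, n_replicates=14, n_taxa=80)
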