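import numpy as np
import pandas as pd
import pytest

from evlong.quantify import PeptideQuantTable, SampleAnnotation
from evlong.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale cohort: 48 samples, ~360 peptides in 60 proteins."""
    cfg = SyntheticConfig(seed=7, n_proteins=60, peptides_per_protein_mean=6)
    return generate_cohort(cfg)


@pytest.fixture()
def toy_table():
    """4 samples x 3 peptides with a hand-placed missing mask."""
    q = pd.DataFrame(
        {
            "A__1": [1.0, 2.0, 3.0, 4.0],
            "A__2": [np.nan, 2.0, 3.0, np.nan],
            "B__1": [5.0, np.nan, 6.0, 7.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return PeptideQuantTable(q)


@pytest.fixture()
def toy_annotation():
    return SampleAnnotation(
        pd.DataFrame(
            {
                "group": ["long_lived", "long_lived", "short_lived", "short_lived"],
                "volume_for_20ug": [5.0, 5.0, 5.0, 5.0],
            },
            index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
        )
    )
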