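import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from vaxsig.datatypes import ExpressionMatrix, GeneSetCollection, SampleTable
from vaxsig.simulate import null_design, simulate_counts, study_design


@pytest.fixture(scope="session")
def study_sim():
    """One simulated dose-arm study with three activated sets."""
    return simulate_counts(study_design(seed=11))


@pytest.fixture(scope="session")
def null_sim():
    """Null study: no effects anywhere."""
    return simulate_counts(null_design(seed=23))


@pytest.fixture
def toy_matrix():
    """4 features x 3 samples RFU matrix with easy hand arithmetic."""
    return ExpressionMatrix(
        feature_ids=["f1", "f2", "f3", "f4"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array(
            [[8.0, 4.0, 2.0], [4.0, 8.0, 2.0], [2.0, 2.0, 8.0], [1.0, 1.0, 1.0]]
        ),
        assay_kind="soma_rfu",
    )


@pytest.fixture
def small_samples():
    return SampleTable(
        frame=pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "subject_id": ["u1", "u2", "u3"],
                "timepoint": ["D1", "D1", "D2"],
                "group": ["ad26_1e11"] * 3,
                "pair_key": [None, None, None],
            }
        )
    )


@pytest.fixture
def two_sets():
    return GeneSetCollection(
        sets={"A": frozenset({"f1", "f2"}), "B": frozenset({"f3", "f4"})}
    )
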