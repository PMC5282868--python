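import numpy as np
import pandas as pd
import pytest

from methylmark.io import BetaMatrix, SampleSheet
from methylmark.simulate import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact discovery-style cohort with planted markers and truth."""
    spec = CohortSpec(
        n_cancer=40,
        n_normal=15,
        n_blood=5,
        n_noncancer_urine=5,
        n_loci_marker=60,
        n_loci_background=400,
        seed=101,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def discovery_sheet(small_cohort):
    """Cancer + normal-urothelium subset used for classifier training."""
    _, sheet, _ = small_cohort
    keep = [
        s
        for s in sheet.sample_ids
        if sheet.group_of(s) in ("cancer", "normal_urothelium")
    ]
    return sheet.subset(keep)


@pytest.fixture
def toy_betas():
    values = pd.DataFrame(
        {
            "s1": [0.0, 0.5],
            "s2": [1.0, np.nan],
        },
        index=["L1", "L2"],
    )
    return BetaMatrix(values)


@pytest.fixture
def toy_sheet():
    table = pd.DataFrame(
        {"group": ["cancer", "cancer", "normal_urothelium", "blood", "noncancer_urine"]},
        index=["c1", "c2", "n1", "b1", "u1"],
    )
    return SampleSheet(table)
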