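import numpy as np
import pandas as pd
import pytest

import nfomics as nf


@pytest.fixture(scope="session")
def small_skeleton():
    return nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=12, seed=42))


@pytest.fixture(scope="session")
def signature_cohort():
    """~150 serum samples, 300 metabolites, 15 planted signature metabolites."""
    skeleton = nf.generate_cohort_skeleton(nf.CohortConfig(n_patients=17, seed=11))
    truth = nf.MetabolomeTruth(
        n_metabolites=300,
        signature_ids=tuple(range(15)),
        shift_log2fc=1.5,
        detection_floor_quantile=0.10,
    )
    values, _ = nf.generate_metabolome(skeleton, truth, seed=11)
    return skeleton, truth, values


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_counts():
    return pd.DataFrame(
        [[10, 5, 5], [8, 8, 4], [0, 12, 8]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3"],
    )
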