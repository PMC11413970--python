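import numpy as np
import pandas as pd
import pytest

from bcd import LabeledMatrix, run_study

STUDY_SEED = 0


@pytest.fixture(scope="session")
def full_study():
    """The full seven-scenario benchmark at standard size (1,000 trials,
    1,000 cases + 1,000 controls per trial, pooled winsorization)."""
    return run_study(seed=STUDY_SEED)


def make_matrix(values, labels, covariates=None, analyte_ids=None):
    """Small helper to build a LabeledMatrix from plain arrays."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_analytes, n_samples = values.shape
    sample_ids = [f"s{i}" for i in range(n_samples)]
    if analyte_ids is None:
        analyte_ids = [f"g{i}" for i in range(n_analytes)]
    cov = None
    if covariates is not None:
        cov = pd.DataFrame(covariates, index=sample_ids)
    return LabeledMatrix(
        values=pd.DataFrame(values, index=analyte_ids, columns=sample_ids),
        labels=pd.Series(list(labels), index=sample_ids),
        covariates=cov,
    )
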