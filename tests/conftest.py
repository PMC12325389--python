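import warnings

import pytest

from twinprs import make_fixture, residualize, standardize_prs

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def prepare(data, roi="roi", prs=("roi_prs", "sud_prs")):
    """Residualize the phenotype on all covariates and standardize the PRSs."""
    out = residualize(data, roi, list(data.schema.covariate_names))
    for p in prs:
        out = standardize_prs(out, p)
    return out


@pytest.fixture(scope="session")
def csl():
    """Paper-scale ACE + two-PRS fixture (cortical-surface-area-like truth)."""
    data, truth = make_fixture("cortical-surface-like")
    return prepare(data), truth


@pytest.fixture(scope="session")
def putamen_large():
    """AE-dominant fixture rerun at 5000 pairs/group for recovery checks."""
    data, truth = make_fixture("putamen-like", n_per_group=5000)
    return prepare(data), truth
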