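import numpy as np
import pytest

from niretain import TrialSummary

SEED = 20200609

# Published Xeloda analysis: summary inputs and the reported p-values
# (study label, mu_ni_hat, sigma_ni, mu_h_hat, sigma_h, p_rothmann, p_wang, p_ratio)
XELODA_TABLE = [
    ("S014695/10-trials", -0.0036, 0.0868, 0.2341, 0.0750, 0.1010, 0.1009, 0.0830),
    ("S014796/10-trials", -0.0844, 0.0867, 0.2341, 0.0750, 0.0165, 0.0164, 0.0140),
    ("Pooled/10-trials", -0.0432, 0.0613, 0.2341, 0.0750, 0.0129, 0.0128, 0.0062),
    ("S014695/8-trials", -0.0036, 0.0868, 0.2398, 0.0593, 0.0891, 0.0890, 0.0774),
    ("S014796/8-trials", -0.0844, 0.0867, 0.2398, 0.0593, 0.0129, 0.0128, 0.0110),
    ("Pooled/8-trials", -0.0432, 0.0613, 0.2398, 0.0593, 0.0083, 0.0083, 0.0044),
]


@pytest.fixture
def xeloda_summaries():
    return {row[0]: TrialSummary(*row[1:5]) for row in XELODA_TABLE}


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
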