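import numpy as np
import pytest

import opirescue as op


@pytest.fixture(scope="session")
def bundle():
    return op.default_bundle()


@pytest.fixture(scope="session")
def nalmefene_typical(bundle):
    return op.typical_parameters(bundle.pk_model("nalmefene"), 74.7, "intranasal")


@pytest.fixture(scope="session")
def naloxone_typical(bundle):
    return op.typical_parameters(bundle.pk_model("naloxone_in"), 74.7, "intranasal")


@pytest.fixture(scope="session")
def hour_grid():
    # 12 h at 60 s resolution
    return np.arange(0.0, 12 * 3600.0 + 1, 60.0)
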