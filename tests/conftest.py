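import warnings

import numpy as np
import pytest
from hypothesis import settings

import liouvex as lx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(autouse=True)
def _quiet_t1_warning():
    """Most tests add T1 without T2 deliberately; silence that warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*without T2.*")
        warnings.filterwarnings("ignore", message=".*qualitative.*")
        yield


@pytest.fixture
def single_carbon():
    return lx.SpinSystem(9.4, ["13C"], vr=0, powder="alpha0beta0")


@pytest.fixture
def hc_pair_mas():
    ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=10e3, n_gamma=10,
                       powder="alpha0beta0")
    ex.add_interaction("dipole", (0, 1), delta=44e3, euler=[(0.2, 0.7, 0.1)])
    ex.add_interaction("csa", 1, delta=5e3, eta=0.3)
    return ex


def two_site_shift_system(dnu=200.0, p1=0.5, kex=150.0, R2=20.0):
    """1-spin 13C with two exchanging isotropic shifts (BM reference case)."""
    s0 = lx.SpinSystem(9.4, ["13C"], vr=0, powder="alpha0beta0")
    s0.add_interaction("cs", 0, iso=-(1 - p1) * dnu)
    s1 = s0.modified_copy(0, iso=p1 * dnu)
    L = lx.Liouvillian([s0, s1], kex=lx.two_site_kex(1.0 / kex, p1))
    if R2:
        L.add_relax("T2", spin=0, value=1.0 / R2)
    return L
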