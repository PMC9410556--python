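import numpy as np
import pytest

import hetpattern as hp


@pytest.fixture(scope="session")
def wt_params():
    return hp.wild_type_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_filament(rng, n=7, n_het=2):
    """A filament with random positive concentrations and a few heterocysts."""
    conc = rng.uniform(0.0, 2.0, size=(n, 6))
    het = np.zeros(n, dtype=bool)
    if n_het:
        het[rng.choice(n, size=min(n_het, n), replace=False)] = True
    return hp.FilamentState(
        conc=conc,
        size=rng.uniform(2.0, 4.0, size=n),
        is_heterocyst=het,
        T_R_cell=np.full(n, 1.0),
        M_R_cell=np.full(n, 12.0),
        M_Lambda_cell=np.full(n, 4.0),
        commit_integral=np.zeros(n),
        commit_clock=np.zeros(n),
        time=0.0,
    )


def filament_from_pattern(pattern, conc=None):
    """Build a filament from a string like 'VHVVH' (V vegetative, H heterocyst)."""
    n = len(pattern)
    het = np.array([c == "H" for c in pattern])
    c = np.zeros((n, 6)) if conc is None else conc
    return hp.FilamentState(
        conc=c,
        size=np.full(n, 3.0),
        is_heterocyst=het,
        T_R_cell=np.full(n, 1.0),
        M_R_cell=np.full(n, 12.0),
        M_Lambda_cell=np.full(n, 4.0),
        commit_integral=np.zeros(n),
        commit_clock=np.zeros(n),
    )
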