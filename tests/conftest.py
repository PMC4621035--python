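import numpy as np
import pytest

import cabalign as cb


@pytest.fixture(scope="session")
def helix20():
    """Jittered 20-residue helix: realistic but fast."""
    return cb.make_ideal_helix(20, seed=3, jitter_sd=0.05)


@pytest.fixture(scope="session")
def cm20(helix20):
    return cb.contact_area_matrix(helix20)


@pytest.fixture(scope="session")
def helix40():
    return cb.make_ideal_helix(40, seed=11, jitter_sd=0.05)


@pytest.fixture(scope="session")
def cm40(helix40):
    return cb.contact_area_matrix(helix40)


@pytest.fixture(scope="session")
def hinge_pair():
    """Two-domain hinge pair bent by 90 degrees."""
    return cb.make_hinge_pair(n_per_domain=14, linker_length=6,
                              hinge_angle=90.0, seed=0)


@pytest.fixture(scope="session")
def hinge_matrices(hinge_pair):
    A, B = hinge_pair
    return cb.contact_area_matrix(A), cb.contact_area_matrix(B)


@pytest.fixture
def single_atom_residue():
    return cb.ResidueRecord(
        0, "GLY", [cb.AtomRecord("CA", "C", np.zeros(3), 1.7)])
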