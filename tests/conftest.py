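"""Shared fixtures: the toy two-state crystal and derived maps.

Everything is generated programmatically; session scope keeps the FFT work
from repeating across test modules.
"""

import numpy as np
import pytest

from xtalens.diffmap import fo_minus_fo_map
from xtalens.model import P1, Atom, Structure, UnitCell
from xtalens.synth import ToyCrystalSpec, make_observations, make_toy_pair

DMIN = 1.5


@pytest.fixture(scope="session")
def toy_spec():
    return ToyCrystalSpec()


@pytest.fixture(scope="session")
def toy_pair(toy_spec):
    return make_toy_pair(toy_spec)


@pytest.fixture(scope="session")
def clean_obs(toy_pair):
    """Noise-free amplitude observations for both states."""
    s0, s30 = toy_pair
    return (make_observations(s0, DMIN, 0.0, seed=1),
            make_observations(s30, DMIN, 0.0, seed=2))


@pytest.fixture(scope="session")
def diff_map(toy_pair, clean_obs):
    s0, _ = toy_pair
    obs0, obs30 = clean_obs
    return fo_minus_fo_map(obs30, obs0, phase_model=s0, dmin=DMIN)


@pytest.fixture()
def tiny_structure():
    """Three atoms in a small P1 box: fast direct/FFT comparisons."""
    cell = UnitCell(12.0, 10.0, 9.0)
    s = Structure(cell=cell, spacegroup=P1)
    for el, name, cart, b in (("C", "CA", (3.0, 4.0, 4.5), 8.0),
                              ("O", "O", (5.0, 5.5, 4.0), 12.0),
                              ("S", "SG", (6.5, 3.5, 5.0), 10.0)):
        s.atoms.append(Atom(element=el, name=name, chain="A", resnum=1,
                            resname="XXX", frac=cell.cart_to_frac(cart),
                            occ=1.0, biso=b))
    return s


def periodic_dist(cell, frac_a, frac_b):
    d = np.asarray(frac_a) - np.asarray(frac_b)
    d -= np.round(d)
    return float(np.linalg.norm(cell.frac_to_cart(d)))
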