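import math

import numpy as np
import pytest

from pdzmc.chain import ChainSystem, NativeReference, InternalState, build_chain, realize_coordinates
from pdzmc.energy import EnergyParams
from pdzmc.synthetic import (
    EnumerableSpec,
    ToyComplexSpec,
    make_enumerable_system,
    make_toy_complex,
)


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def toy_class1():
    return make_toy_complex(ToyComplexSpec(pattern="classI"))


@pytest.fixture(scope="session")
def toy_class2():
    return make_toy_complex(ToyComplexSpec(pattern="classII"))


@pytest.fixture(scope="session")
def enumerable():
    return make_enumerable_system(EnumerableSpec())


@pytest.fixture(scope="session")
def native_conformation(toy_class1):
    st = toy_class1.native_state
    return realize_coordinates(
        toy_class1, st.torsions, st.frame_rotation, st.frame_translation
    )


def random_conformation(system, rng, spread=12.0):
    """A random state of *system*: random torsions, frame and placement."""
    tors = rng.uniform(-math.pi, math.pi, size=(system.n_res, 3))
    if system.native_state is not None:
        n_rec = len(system.receptor)
        tors[:n_rec] = system.native_state.torsions[:n_rec]
        tors[:n_rec] += rng.normal(scale=0.1, size=tors[:n_rec].shape)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    center = np.full(3, system.box_side / 2.0)
    t = center + rng.uniform(-spread, spread, 3)
    return realize_coordinates(system, tors, rot, t)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_system():
    """A small unrestrained two-chain system for fast energy checks."""
    rec = build_chain("ASLVKDSTRF", "receptor")
    pep = build_chain("KAVAV", "peptide")
    return ChainSystem(receptor=rec, peptide=pep, box_side=60.0)
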