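import numpy as np
import pytest

from crydiscov.synthetic_data import (
    gen_ligand_library,
    gen_pocket_and_pose,
    gen_rotamer_trajectory,
)


@pytest.fixture(scope="session")
def all_pass_library():
    return gen_ligand_library(100, seed=1, profile="all-pass")


@pytest.fixture(scope="session")
def mixed_library():
    return gen_ligand_library(200, seed=7, profile="fail-one:0.25")


@pytest.fixture(scope="session")
def four_contact_pocket():
    """A pocket mirroring the published binding fingerprint's residue set:
    two TRP, one ARG, one SER."""
    return gen_pocket_and_pose(
        seed=2,
        contact_spec=[
            ("TRP", "pi-alkyl", 3.8),
            ("ARG", "hbond", 2.9),
            ("SER", "hbond", 2.9),
            ("TRP", "pi-pi", 4.0),
        ],
    )


@pytest.fixture(scope="session")
def vonmises_trajectory():
    """1000-frame single-state von Mises chi1 trajectory at -65 deg, kappa 20."""
    return gen_rotamer_trajectory(
        [("TRP", [-65.0], [20.0], [1.0])], n_frames=1000, dt=10.0, seed=3
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
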