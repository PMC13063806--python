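import numpy as np
import pandas as pd
import pytest

from memraft import synthetic as sy
from memraft.trajectory import Frame, Topology, Trajectory


@pytest.fixture(scope="session")
def ld_config():
    """Liquid-disordered bilayer: 40 POPC per leaflet at APL 0.651 nm^2."""
    return sy.build_bilayer_config(sy.ld_spec(seed=11))


@pytest.fixture(scope="session")
def lo_config():
    """Liquid-ordered bilayer: 40 PSM + 80 CHOL per leaflet."""
    return sy.build_bilayer_config(sy.lo_spec(seed=12))


@pytest.fixture(scope="session")
def ld_short_traj(ld_config):
    frame, top = ld_config
    spec = sy.DynamicsSpec({"POPC": 1.2e-7}, n_frames=100, dt=0.1, seed=21)
    return sy.simulate_lateral_diffusion(frame, top, spec)


def make_point_topology(n, species="LIG", subregion="ligand", radius=0.17, mass=12.0):
    """Minimal all-carbon topology for geometric tests (one atom per residue)."""
    return Topology(
        pd.DataFrame(
            {
                "atom_id": np.arange(1, n + 1),
                "atom_name": ["C"] * n,
                "residue_id": np.arange(1, n + 1),
                "species": [species] * n,
                "subregion": [subregion] * n,
                "element": ["C"] * n,
                "mass_amu": [mass] * n,
                "vdw_radius_nm": [radius] * n,
                "is_donor": False,
                "is_hydrogen": False,
                "is_acceptor": False,
                "donor_of": -1,
                "leaflet_hint": "",
            }
        )
    )


def single_frame_traj(coords, box, time=0.0):
    coords = np.asarray(coords, dtype=float)
    return Trajectory(coords[None], np.asarray(box, dtype=float)[None], np.array([time]))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
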