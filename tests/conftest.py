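import numpy as np
import pytest
from hypothesis import settings

from hyperbar import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from hyperbar.trajio import Atom, Frame, IndexGroup, Topology


@pytest.fixture(scope="session")
def small_spec():
    """Reduced system for fast structural tests."""
    return synth.SynthSpec(n_lipids=32, n_water=1200, n_gas=500, n_frames=8,
                           seed=7)


@pytest.fixture(scope="session")
def small_system(small_spec):
    return synth.build_system(small_spec)


@pytest.fixture(scope="session")
def default_system():
    """The generator's default study conditions, used for recovery tests."""
    spec = synth.SynthSpec(seed=2024, f_gap=0.9, tmd_dehydration=0.5)
    top, traj = synth.build_system(spec)
    return spec, top, traj


def make_topology(n, vdw=0.2, name="X", chain="A"):
    return Topology([
        Atom(serial=i + 1, name=name, residue_name="RES", residue_number=i + 1,
             chain_id=chain, element="C", mass=12.0, vdw_radius=vdw)
        for i in range(n)
    ])


def make_frame(coords, box=(10.0, 10.0, 10.0), time=0.0):
    return Frame(time, np.asarray(coords, dtype=float), np.asarray(box, float))


def full_group(topology, name="all"):
    return IndexGroup(name, tuple(range(1, topology.n_atoms + 1)))
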