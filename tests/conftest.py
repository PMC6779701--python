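import numpy as np
import pytest

import swishmc as sw
from swishmc.model import EnergyParameters


@pytest.fixture(scope="session")
def wt_seq():
    return sw.parse_modified_sequence(sw.HTT_N19, name="WT")


@pytest.fixture(scope="session")
def params():
    return EnergyParameters()


@pytest.fixture(scope="session")
def alpha_conf(wt_seq):
    return sw.make_ideal_structure(wt_seq, "alpha")


@pytest.fixture(scope="session")
def extended_conf(wt_seq):
    return sw.make_ideal_structure(wt_seq, "extended")


def to_mdtraj(confs, seq):
    """Build an mdtraj trajectory (nm) from backbone atoms of conformations."""
    import mdtraj as md
    from mdtraj.core import element as elem

    from swishmc.sequence import _ONE_TO_THREE

    top = md.Topology()
    chain = top.add_chain()
    for i, r in enumerate(seq.residues):
        res = top.add_residue(_ONE_TO_THREE[r.code].upper(), chain, resSeq=r.index)
        for name, e in (("N", elem.nitrogen), ("H", elem.hydrogen),
                        ("CA", elem.carbon), ("C", elem.carbon),
                        ("O", elem.oxygen)):
            if name == "H" and i == 0:
                continue
            top.add_atom(name, e, res)
    xyz = []
    for conf in confs:
        frame = []
        for i in range(1, len(seq) + 1):
            for name in ("N", "H", "CA", "C", "O"):
                if name == "H" and i == 1:
                    continue
                frame.append(conf.atom(i, name) / 10.0)
        xyz.append(frame)
    return md.Trajectory(np.array(xyz), top)


def random_rigid_transform(rng):
    """A uniformly random rotation matrix plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rot.as_matrix(), rng.normal(scale=20.0, size=3)
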