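import numpy as np
import pytest

from ksbind import Atom, Structure, Trajectory


def _atom(serial, pos, element="C", name=None, resname="ALA", resnum=None, chain="A"):
    return Atom(
        serial=serial,
        name=name or f"{element}{serial}",
        element=element,
        residue_name=resname,
        residue_number=resnum if resnum is not None else serial,
        chain_id=chain,
        position=np.asarray(pos, dtype=float),
    )


@pytest.fixture
def make_atom():
    return _atom


@pytest.fixture
def toy_five_atom_trajectory():
    """Receptor at (0,0,0),(5,0,0),(20,0,0); ligand at (0,3,0),(0,8,0).

    Native pairs at 7 A: (r0,l0) at 3.00 and (r1,l0) at 5.83. Frame 1
    moves the ligand to (0,6,0),(0,11,0): distances 6.00 (kept) and 7.81
    (lost), so the stability sequence is (1, 0.5).
    """
    atoms = [
        _atom(1, (0, 0, 0)),
        _atom(2, (5, 0, 0)),
        _atom(3, (20, 0, 0)),
        _atom(4, (0, 3, 0), resname="LIG", resnum=1, chain="B"),
        _atom(5, (0, 8, 0), resname="LIG", resnum=1, chain="B"),
    ]
    topology = Structure(atoms=atoms)
    frame0 = topology.coordinates
    frame1 = frame0.copy()
    frame1[3] = (0, 6, 0)
    frame1[4] = (0, 11, 0)
    traj = Trajectory(topology=topology, frames=[frame0, frame1])
    receptor = np.array([0, 1, 2])
    ligand = np.array([3, 4])
    return traj, receptor, ligand


def brute_force_ss(frames, pairs, cutoff):
    """Independent all-pairs oracle for the stability series."""
    values = []
    for frame in frames:
        kept = 0
        for i, j in pairs:
            d = np.sqrt(sum((frame[i][k] - frame[j][k]) ** 2 for k in range(3)))
            if d <= cutoff:
                kept += 1
        values.append(kept / len(pairs))
    return values


def brute_force_native_pairs(frame0, receptor, ligand, cutoff):
    pairs = []
    for i in receptor:
        for j in ligand:
            d = np.sqrt(sum((frame0[i][k] - frame0[j][k]) ** 2 for k in range(3)))
            if d <= cutoff:
                pairs.append((i, j))
    return pairs
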