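import math

import numpy as np
import pytest

from mgatp.structures import Atom, Frame, Trajectory
from mgatp.synthetic import build_site_trajectory, default_site_config


def make_frame(atom_specs, index=0, time=0.0):
    """Build a Frame from (name, element, resname, resnum, (x, y, z)) tuples."""
    atoms = [
        Atom(serial=i + 1, name=name, element=element, residue_name=resname,
             residue_number=resnum, chain="A", position=tuple(map(float, pos)))
        for i, (name, element, resname, resnum, pos) in enumerate(atom_specs)
    ]
    return Frame(index=index, time=time, atoms=atoms)


def random_polar_frame(seed, n_heavy=15, box=12.0):
    """A random frame of ~50 atoms: N/O/C heavies, hydrogens attached to a
    subset of the polar heavies at covalent distance."""
    rng = np.random.default_rng(seed)
    specs = []
    resnum = 0
    for i in range(n_heavy):
        resnum += 1
        element = rng.choice(["N", "O", "C"], p=[0.4, 0.4, 0.2])
        pos = rng.uniform(0, box, 3)
        specs.append((f"{element}X", element, "GLY", resnum, pos))
        if element in "NO" and rng.random() < 0.7:
            for j in range(rng.integers(1, 3)):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                hpos = pos + rng.uniform(0.95, 1.1) * direction
                specs.append((f"H{j + 1}", "H", "GLY", resnum, hpos))
    return make_frame(specs)


def brute_force_hbonds(frame, donors, acceptors, criteria):
    """Independent O(D x H x A) scan, pure-python math."""
    triples = set()
    for donor in donors:
        for hyd in frame.atoms:
            if hyd.element != "H" or hyd.residue_key() != donor.residue_key():
                continue
            if math.dist(hyd.position, donor.position) > 1.2:
                continue
            for acc in acceptors:
                if acc.serial in (donor.serial, hyd.serial):
                    continue
                d_ha = math.dist(hyd.position, acc.position)
                if d_ha > criteria.max_h_acceptor_distance:
                    continue
                v1 = [d - h for d, h in zip(donor.position, hyd.position)]
                v2 = [a - h for a, h in zip(acc.position, hyd.position)]
                dot = sum(x * y for x, y in zip(v1, v2))
                norm = math.hypot(*v1) * math.hypot(*v2)
                angle = math.degrees(math.acos(max(-1.0, min(1.0, dot / norm))))
                if 180.0 - angle <= criteria.max_angle_deviation:
                    triples.add((donor.serial, hyd.serial, acc.serial))
    return triples


@pytest.fixture(scope="session")
def wt_site():
    """Noiseless 5-frame wild-type binding site with its ground truth."""
    cfg = default_site_config("wild_type", n_frames=5)
    return build_site_trajectory(cfg)


@pytest.fixture()
def wt_trajectory(wt_site):
    return wt_site[0]


@pytest.fixture()
def wt_truth(wt_site):
    return wt_site[1]
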