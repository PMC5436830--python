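import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mgatp.errors import AnalysisError, SelectionError
from mgatp.hbonds import (
    HBondCriteria,
    acceptor_atoms,
    detect_hbonds,
    donor_atoms,
    helix_network_hbonds,
    helix_rest_hbonds,
    histogram,
    min_distance_series,
    protein_atp_hbonds,
)
from mgatp.structures import Atom, Frame, Trajectory
from mgatp.synthetic import build_site_trajectory, default_site_config

from conftest import brute_force_hbonds, make_frame, random_polar_frame


def dha_frame(acceptor_pos, donor_pos=(0, 0, 0), hydrogen_pos=(0, 0, 1.0)):
    return make_frame([
        ("N", "N", "ALA", 1, donor_pos),
        ("H1", "H", "ALA", 1, hydrogen_pos),
        ("O", "O", "GLY", 2, acceptor_pos),
    ])


class TestDetection:
    def test_collinear_geometry_inside_cutoffs(self):
        frame = dha_frame((0, 0, 3.0))
        records = detect_hbonds(frame, [frame.atoms[0]], [frame.atoms[2]])
        assert len(records) == 1
        assert records[0].d_ha == pytest.approx(2.0)
        assert records[0].angle_deviation == pytest.approx(0.0, abs=1e-9)

    def test_distance_cutoff_excludes(self):
        frame = dha_frame((0, 0, 3.8))  # d_HA = 2.8 > 2.7
        assert detect_hbonds(frame, [frame.atoms[0]], [frame.atoms[2]]) == []

    def test_angle_cutoff_excludes(self):
        theta = math.radians(35.0)
        acc = (2.0 * math.sin(theta), 0, 1.0 + 2.0 * math.cos(theta))
        frame = dha_frame(acc)
        assert detect_hbonds(frame, [frame.atoms[0]], [frame.atoms[2]]) == []
        # at 25 degrees the same construction is accepted
        theta = math.radians(25.0)
        acc = (2.0 * math.sin(theta), 0, 1.0 + 2.0 * math.cos(theta))
        frame = dha_frame(acc)
        records = detect_hbonds(frame, [frame.atoms[0]], [frame.atoms[2]])
        assert len(records) == 1
        assert records[0].angle_deviation == pytest.approx(25.0, abs=1e-9)

    def test_donor_without_hydrogen_skipped(self):
        frame = make_frame([
            ("NZ", "N", "LYS", 1, (0, 0, 0)),
            ("O", "O", "GLY", 2, (0, 0, 2.0)),
        ])
        assert detect_hbonds(frame, [frame.atoms[0]], [frame.atoms[1]]) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_on_random_frames(self, seed):
        frame = random_polar_frame(seed)
        donors = donor_atoms(frame)
        acceptors = acceptor_atoms(frame)
        criteria = HBondCriteria()
        got = {r.triple_key() for r in detect_hbonds(frame, donors, acceptors, criteria)}
        expected = brute_force_hbonds(frame, donors, acceptors, criteria)
        assert got == expected

    def test_rigid_transform_invariance(self):
        frame = random_polar_frame(3)
        rot = Rotation.from_euler("xyz", [31.0, -57.0, 112.0], degrees=True)
        shift = np.array([5.0, -3.0, 11.0])
        moved = Frame(index=0, time=0.0, atoms=[
            Atom(a.serial, a.name, a.element, a.residue_name, a.residue_number,
                 a.chain, tuple(rot.apply(a.xyz) + shift))
            for a in frame.atoms
        ])
        r0 = detect_hbonds(frame, donor_atoms(frame), acceptor_atoms(frame))
        r1 = detect_hbonds(moved, donor_atoms(moved), acceptor_atoms(moved))
        assert {r.triple_key() for r in r0} == {r.triple_key() for r in r1}
        for a, b in zip(sorted(r0, key=lambda r: r.triple_key()),
                        sorted(r1, key=lambda r: r.triple_key())):
            assert a.d_ha == pytest.approx(b.d_ha, abs=1e-6)
            assert a.angle_deviation == pytest.approx(b.angle_deviation, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_tightening_criteria_never_adds_bonds(self, seed):
        frame = random_polar_frame(seed + 100)
        donors, acceptors = donor_atoms(frame), acceptor_atoms(frame)
        loose = {r.triple_key() for r in detect_hbonds(
            frame, donors, acceptors, HBondCriteria(2.7, 30.0))}
        for d, a in [(2.2, 30.0), (2.7, 20.0), (2.0, 15.0)]:
            tight = {r.triple_key() for r in detect_hbonds(
                frame, donors, acceptors, HBondCriteria(d, a))}
            assert tight <= loose


class TestPlantedRecovery:
    def test_noiseless_detection_equals_planted_set(self, wt_trajectory, wt_truth):
        for frame in wt_trajectory.frames:
            assert len(protein_atp_hbonds(frame)) == wt_truth.n_protein_atp
            assert len(helix_rest_hbonds(frame)) == wt_truth.n_helix

    def test_jittered_recovery_rate(self):
        """At sigma = 0.05 Å, >= 99% of planted bonds are still detected.

        The dominant loss channel is the donor-hydrogen covalent pairing
        (planted at 1.0 Å, paired within 1.2 Å): under independent per-atom
        jitter each donor exceeds the pairing cutoff in ~0.2% of frames, so
        recovery is scored per planted bond."""
        cfg = default_site_config("wild_type", n_frames=200, jitter_sigma=0.05, seed=11)
        traj, truth = build_site_trajectory(cfg)
        planted = truth.n_protein_atp + truth.n_helix
        detected = sum(
            min(len(protein_atp_hbonds(f)), truth.n_protein_atp)
            + min(len(helix_rest_hbonds(f)), truth.n_helix)
            for f in traj.frames
        )
        assert detected >= 0.99 * planted * len(traj)


class TestSeriesAndSkip:
    def test_skip_discards_early_frames(self, wt_trajectory):
        counts = [len(protein_atp_hbonds(f)) for f in wt_trajectory.after(0.0)]
        assert len(counts) == 5
        late = wt_trajectory.after(20.0)  # spacing 10 ps: drops frames 0, 1
        assert len(late) == 3

    def test_all_frames_skipped_is_error(self, wt_trajectory):
        from mgatp.hbonds import protein_atp_count_series

        with pytest.raises(AnalysisError):
            protein_atp_count_series(wt_trajectory, skip_ps=1e6)


class TestHelixNetwork:
    def crossing_and_intra_frame(self):
        # one helix->rest bond (donor 120 -> acceptor 50) and one intra-helix
        # bond (donor 115 -> acceptor 116), in separate cells
        return make_frame([
            ("N", "N", "ALA", 120, (0, 0, 2.9)),
            ("H1", "H", "ALA", 120, (0, 0, 1.9)),
            ("O", "O", "ALA", 50, (0, 0, 0)),
            ("N", "N", "ALA", 115, (20, 0, 2.9)),
            ("H1", "H", "ALA", 115, (20, 0, 1.9)),
            ("O", "O", "ALA", 116, (20, 0, 0)),
        ])

    def test_crossing_bond_counted_intra_excluded(self):
        frame = self.crossing_and_intra_frame()
        records = helix_rest_hbonds(frame, (112, 133))
        assert len(records) == 1
        assert records[0].donor.residue_number == 120

    def test_inverted_range_normalized(self):
        frame = self.crossing_and_intra_frame()
        traj = Trajectory(frames=[frame])
        assert helix_network_hbonds(traj, (133, 112)) == helix_network_hbonds(traj, (112, 133))

    def test_empty_helix_selection_raises(self):
        frame = make_frame([("N", "N", "ALA", 5, (0, 0, 0))])
        with pytest.raises(SelectionError):
            helix_rest_hbonds(frame, (112, 133))

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_partition(self, seed):
        frame = random_polar_frame(seed + 50)
        # give residues numbers straddling the helix range
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_name,
                 110 + (a.residue_number % 10), a.chain, a.position)
            for a in frame.atoms
        ]
        frame = Frame(index=0, time=0.0, atoms=atoms)
        criteria = HBondCriteria()
        got = {r.triple_key() for r in helix_rest_hbonds(frame, (112, 133), criteria)}
        all_triples = brute_force_hbonds(
            frame, donor_atoms(frame), acceptor_atoms(frame), criteria)
        by_serial = {a.serial: a for a in frame.atoms}
        expected = {
            (d, h, a) for d, h, a in all_triples
            if (112 <= by_serial[d].residue_number <= 133)
            != (112 <= by_serial[a].residue_number <= 133)
        }
        assert got == expected


class TestMinDistance:
    def test_three_four_five_triangle(self):
        frame = make_frame([
            ("O1A", "O", "ATP", 1, (0, 0, 0)),
            ("MG", "MG", "MG", 2, (3, 4, 0)),
        ])
        series = min_distance_series(Trajectory(frames=[frame]), "ATP:O1A", "MG")
        assert series.per_frame_min[0] == pytest.approx(5.0)

    def test_min_semantics_over_group(self):
        frame = make_frame([
            ("O1A", "O", "ATP", 1, (2, 0, 0)),
            ("O2A", "O", "ATP", 1, (7, 0, 0)),
            ("MG", "MG", "MG", 2, (0, 0, 0)),
        ])
        series = min_distance_series(Trajectory(frames=[frame]), "ATP:Oα", "MG")
        assert series.per_frame_min[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_exhaustive_scan(self, seed, wt_trajectory):
        frame = wt_trajectory.frames[0]
        series = min_distance_series(wt_trajectory, "ATP:Oγ", "MG")
        from mgatp.structures import resolve_group

        for i, f in enumerate(wt_trajectory.frames):
            ga = resolve_group(f, "ATP:Oγ")
            gb = resolve_group(f, "MG")
            expected = min(math.dist(a.position, b.position) for a in ga for b in gb)
            assert series.per_frame_min[i] == pytest.approx(expected, abs=1e-12)


class TestHistogram:
    def test_constant_series_single_bin(self):
        edges, freq = histogram(np.full(50, 3.2), bin_width=0.1)
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.count_nonzero(freq) == 1
        assert freq.max() == pytest.approx(1.0)

    def test_uniform_values_roughly_flat(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(2.0, 3.0, 20000)
        edges, freq = histogram(values, bin_width=0.1, value_range=(2.0, 3.0))
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.abs(freq - 0.1) < 0.01)

    def test_empty_series_rejected(self):
        with pytest.raises(AnalysisError):
            histogram(np.array([]), bin_width=0.1)
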