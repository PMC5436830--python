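"""Geometric hydrogen-bond detection and minimal-distance series.

A hydrogen bond is accepted when the donor-hydrogen-to-acceptor distance
d(H···A) is at most 2.7 Å and the D-H···A arrangement deviates from
linearity by at most 30° (i.e. the angle at the hydrogen is >= 150°).
The angular convention is configurable but the deviation-from-linearity
reading of the 30° cutoff is the default, as it matches the standard
geometric criterion.

Donors are polar heavy atoms (N, O) carrying at least one covalently bound
hydrogen (same residue, within 1.2 Å); acceptors are N and O atoms.  One
hydrogen may satisfy the criteria with several acceptors: every qualifying
(donor, hydrogen, acceptor) triple is recorded, so counts are triple counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import AnalysisError, MgatpError, SelectionError
from .structures import (
    Atom,
    Frame,
    Selector,
    STANDARD_AMINO_ACIDS,
    Trajectory,
    resolve_group,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "DistanceSeries",
    "COVALENT_DH_MAX",
    "detect_hbonds",
    "donor_atoms",
    "acceptor_atoms",
    "hbond_count_series",
    "protein_atp_hbonds",
    "helix_network_hbonds",
    "min_distance_series",
    "histogram",
]

#: Maximum covalent donor-hydrogen distance (Å) used for donor pairing.
COVALENT_DH_MAX = 1.2

#: Elements accepted as polar donors/acceptors by the shipped chemistry table.
POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric acceptance thresholds.

    ``max_h_acceptor_distance`` is d(H···A) in Å; ``max_angle_deviation``
    is the allowed deviation of D-H···A from linearity in degrees.
    """

    max_h_acceptor_distance: float = 2.7
    max_angle_deviation: float = 30.0

    def __post_init__(self):
        if not (0 < self.max_h_acceptor_distance < 10):
            raise MgatpError("distance cutoff must be in (0, 10) Å")
        if not (0 < self.max_angle_deviation <= 90):
            raise MgatpError("angle cutoff must be in (0, 90] degrees")


@dataclass(frozen=True)
class HBondRecord:
    """One detected donor-H···acceptor contact with its measured geometry."""

    donor: Atom
    hydrogen: Atom
    acceptor: Atom
    d_ha: float
    angle_deviation: float
    frame_index: int

    def triple_key(self) -> tuple[int, int, int]:
        return (self.donor.serial, self.hydrogen.serial, self.acceptor.serial)


@dataclass
class DistanceSeries:
    """Per-frame minimal distance between two atom groups (Å)."""

    label: str
    per_frame_min: np.ndarray

    def __post_init__(self):
        self.per_frame_min = np.asarray(self.per_frame_min, dtype=float)
        if self.per_frame_min.size and np.any(self.per_frame_min <= 0):
            raise MgatpError("distances must be positive")


def _bonded_hydrogens(frame: Frame, donor: Atom) -> list[Atom]:
    out = []
    dpos = donor.xyz
    for atom in frame.atoms:
        if atom.element != "H":
            continue
        if atom.residue_key() != donor.residue_key():
            continue
        if np.linalg.norm(atom.xyz - dpos) <= COVALENT_DH_MAX:
            out.append(atom)
    return out


def donor_atoms(frame: Frame, residue_filter=None) -> list[Atom]:
    """Polar heavy atoms with >= 1 bonded hydrogen (the donor table)."""
    out = []
    for atom in frame.atoms:
        if atom.element not in POLAR_ELEMENTS:
            continue
        if residue_filter is not None and not residue_filter(atom):
            continue
        if _bonded_hydrogens(frame, atom):
            out.append(atom)
    return out


def acceptor_atoms(frame: Frame, residue_filter=None) -> list[Atom]:
    """N/O heavy atoms (the acceptor table)."""
    return [
        a for a in frame.atoms
        if a.element in POLAR_ELEMENTS
        and (residue_filter is None or residue_filter(a))
    ]


def detect_hbonds(
    frame: Frame,
    donor_set: Sequence[Atom],
    acceptor_set: Sequence[Atom],
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Every (D, H, A) triple satisfying the distance and angle criteria.

    Donors without any bonded hydrogen are skipped with a logged warning.
    Acceptors identical to the donor or its hydrogen are excluded.
    """
    if not donor_set or not acceptor_set:
        return []
    records: list[HBondRecord] = []
    skipped = 0
    acc_pos = np.array([a.xyz for a in acceptor_set])
    for donor in donor_set:
        hydrogens = _bonded_hydrogens(frame, donor)
        if not hydrogens:
            skipped += 1
            continue
        for hyd in hydrogens:
            hpos = hyd.xyz
            d_ha = np.linalg.norm(acc_pos - hpos, axis=1)
            for j, acceptor in enumerate(acceptor_set):
                if acceptor.serial in (donor.serial, hyd.serial):
                    continue
                if d_ha[j] > criteria.max_h_acceptor_distance:
                    continue
                deviation = _linearity_deviation(donor.xyz, hpos, acc_pos[j])
                if deviation <= criteria.max_angle_deviation:
                    records.append(HBondRecord(
                        donor=donor, hydrogen=hyd, acceptor=acceptor,
                        d_ha=float(d_ha[j]), angle_deviation=float(deviation),
                        frame_index=frame.index,
                    ))
    if skipped:
        logger.warning("%d donor atoms had no bonded hydrogen and were skipped", skipped)
    return records


def _linearity_deviation(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation (degrees) of the D-H···A arrangement from 180°."""
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def _is_protein(atom: Atom) -> bool:
    return atom.residue_name in STANDARD_AMINO_ACIDS


def _is_ligand(atom: Atom, ligand_resname: str) -> bool:
    return atom.residue_name == ligand_resname


def protein_atp_hbonds(
    frame: Frame,
    criteria: HBondCriteria = HBondCriteria(),
    ligand_resname: str = "ATP",
) -> list[HBondRecord]:
    """H-bonds with one partner in the protein and the other in the ligand
    (both donation directions)."""
    donors = donor_atoms(frame)
    acceptors = acceptor_atoms(frame)
    records = detect_hbonds(frame, donors, acceptors, criteria)
    out = []
    for r in records:
        pair = (r.donor, r.acceptor)
        if (_is_protein(pair[0]) and _is_ligand(pair[1], ligand_resname)) or (
            _is_ligand(pair[0], ligand_resname) and _is_protein(pair[1])
        ):
            out.append(r)
    return out


def helix_rest_hbonds(
    frame: Frame,
    helix_range: tuple[int, int] = (112, 133),
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """Protein-protein H-bonds crossing the helix boundary.

    Exactly one partner (donor or acceptor heavy atom) lies in the inclusive
    helix residue range; intra-helix and rest-rest bonds are excluded.
    """
    lo, hi = sorted(helix_range)
    donors = donor_atoms(frame, _is_protein)
    acceptors = acceptor_atoms(frame, _is_protein)
    if not any(lo <= a.residue_number <= hi for a in frame.atoms if _is_protein(a)):
        raise SelectionError(f"helix range {lo}-{hi} selects no protein atoms")
    records = detect_hbonds(frame, donors, acceptors, criteria)
    out = []
    for r in records:
        in_helix = (lo <= r.donor.residue_number <= hi,
                    lo <= r.acceptor.residue_number <= hi)
        if in_helix[0] != in_helix[1]:
            out.append(r)
    return out


def _retained(trajectory: Trajectory, skip_ps: float) -> list[Frame]:
    frames = trajectory.after(skip_ps)
    if not frames:
        raise AnalysisError(
            f"no frames left after skipping the first {skip_ps} ps"
        )
    return frames


def hbond_count_series(
    trajectory: Trajectory,
    donor_set_fn,
    acceptor_set_fn,
    criteria: HBondCriteria = HBondCriteria(),
    skip_ps: float = 0.0,
) -> list[int]:
    """Per-retained-frame H-bond triple counts.

    ``donor_set_fn``/``acceptor_set_fn`` map a frame to its donor/acceptor
    atom lists (pass e.g. :func:`donor_atoms` / :func:`acceptor_atoms`, or
    closures over resolved selections).  Frames with time < ``skip_ps`` are
    discarded first.
    """
    frames = _retained(trajectory, skip_ps)
    return [
        len(detect_hbonds(f, donor_set_fn(f), acceptor_set_fn(f), criteria))
        for f in frames
    ]


def protein_atp_count_series(
    trajectory: Trajectory,
    criteria: HBondCriteria = HBondCriteria(),
    skip_ps: float = 0.0,
    ligand_resname: str = "ATP",
) -> list[int]:
    """Per-frame protein-ligand H-bond counts after equilibration skip."""
    return [
        len(protein_atp_hbonds(f, criteria, ligand_resname))
        for f in _retained(trajectory, skip_ps)
    ]


def helix_network_hbonds(
    trajectory: Trajectory,
    helix_range: tuple[int, int] = (112, 133),
    criteria: HBondCriteria = HBondCriteria(),
    skip_ps: float = 0.0,
) -> list[int]:
    """Per-frame counts of helix-to-rest protein H-bonds after skip."""
    return [
        len(helix_rest_hbonds(f, helix_range, criteria))
        for f in _retained(trajectory, skip_ps)
    ]


def min_distance_series(
    trajectory: Trajectory,
    group_a: Selector | str,
    group_b: Selector | str,
    label: str | None = None,
) -> DistanceSeries:
    """Per-frame minimum pairwise distance between two selected groups."""
    mins = []
    for frame in trajectory.frames:
        pa = np.array([a.xyz for a in resolve_group(frame, group_a)])
        pb = np.array([a.xyz for a in resolve_group(frame, group_b)])
        mins.append(float(cdist(pa, pb).min()))
    if label is None:
        label = f"{group_a}—{group_b}"
    return DistanceSeries(label=label, per_frame_min=np.array(mins))


def histogram(
    series: DistanceSeries | np.ndarray,
    bin_width: float,
    value_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized histogram (frequencies sum to 1) with half-open bins.

    Returns ``(bin_edges, frequencies)`` with ``len(edges) == len(freq)+1``.
    """
    values = series.per_frame_min if isinstance(series, DistanceSeries) else np.asarray(series, dtype=float)
    if values.size == 0:
        raise AnalysisError("cannot histogram an empty series")
    if bin_width <= 0:
        raise MgatpError("bin width must be positive")
    if value_range is None:
        lo = np.floor(values.min() / bin_width) * bin_width
        hi = values.max() + bin_width
    else:
        lo, hi = value_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return edges, counts / values.size
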