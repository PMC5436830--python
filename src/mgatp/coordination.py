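"""Mg2+ coordination-state classification and repulsive-contact counting.

The Mg2+ binding mode relative to the ATP phosphates is classified from the
minimal distances of the ion to the non-bridging alpha/beta/gamma phosphate
oxygen groups.  A bidentate first-sphere state requires both group distances
within the first-sphere cutoff (default 2.6 Å, the inner edge of the typical
bimodal Mg-O distance split); otherwise any group within the second-sphere
cutoff (default 5.0 Å, water-bridged) yields SECOND_SPHERE, else UNBOUND.

Repulsive contacts count binding-site cationic side chains (Arg NE/NH1/NH2,
Lys NZ) close to the Mg2+ cation (default cutoff 4.5 Å), either per residue
(a residue counts once however many of its atoms qualify) or per atom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, MgatpError, SelectionError
from .structures import Atom, Frame, Selector, Trajectory, resolve_group

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinationState",
    "CoordinationThresholds",
    "ContactCriteria",
    "OccupancyReport",
    "classify_mg_state",
    "occupancy",
    "repulsive_contacts",
    "default_binding_site",
]


class CoordinationState(str, Enum):
    """Categorical Mg2+-ATP binding mode."""

    FIRST_SPHERE_ALPHA_BETA = "FIRST_SPHERE_ALPHA_BETA"
    FIRST_SPHERE_BETA_GAMMA = "FIRST_SPHERE_BETA_GAMMA"
    SECOND_SPHERE = "SECOND_SPHERE"
    UNBOUND = "UNBOUND"


@dataclass(frozen=True)
class CoordinationThresholds:
    """Distance cutoffs (Å) separating first-sphere, second-sphere and
    unbound Mg2+."""

    first_sphere_max: float = 2.6
    second_sphere_max: float = 5.0

    def __post_init__(self):
        if not (0 < self.first_sphere_max < self.second_sphere_max):
            raise MgatpError(
                "require 0 < first_sphere_max < second_sphere_max"
            )


@dataclass(frozen=True)
class ContactCriteria:
    """Repulsive-contact definition: cationic atoms per residue type and the
    maximum distance to Mg2+."""

    max_distance: float = 4.5
    cation_atom_table: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
    )
    counting_mode: str = "per_residue"

    def __post_init__(self):
        if self.max_distance <= 0:
            raise MgatpError("contact cutoff must be positive")
        if not self.cation_atom_table:
            raise MgatpError("cation atom table must be non-empty")
        if self.counting_mode not in ("per_residue", "per_atom"):
            raise MgatpError(f"unknown counting mode {self.counting_mode!r}")


@dataclass
class OccupancyReport:
    """Fraction of retained frames in each coordination state."""

    fractions: dict[CoordinationState, float]
    n_frames: int

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.n_frames > 0 and abs(total - 1.0) > 1e-9:
            raise MgatpError(f"state fractions sum to {total}, expected 1")


def _mg_position(frame: Frame, mg_atom: Selector | str | Atom) -> np.ndarray:
    if isinstance(mg_atom, Atom):
        return mg_atom.xyz
    atoms = resolve_group(frame, mg_atom)
    if len(atoms) != 1:
        raise SelectionError(
            f"Mg selector matched {len(atoms)} atoms, expected exactly 1"
        )
    return atoms[0].xyz


def _group_min(frame: Frame, mg_pos: np.ndarray, selector: str) -> float:
    atoms = resolve_group(frame, selector)
    return float(min(np.linalg.norm(a.xyz - mg_pos) for a in atoms))


def classify_mg_state(
    frame: Frame,
    mg_atom: Selector | str | Atom = "MG",
    atp_residue: str = "ATP",
    thresholds: CoordinationThresholds = CoordinationThresholds(),
) -> CoordinationState:
    """Assign exactly one coordination state to ``frame``.

    Uses the minimal Mg distances d_alpha, d_beta, d_gamma to the
    non-bridging phosphate oxygen groups.  If both bidentate first-sphere
    patterns qualify simultaneously, the pair whose larger member distance is
    smaller wins (deterministic tie-break; the ambiguity is logged).
    """
    d_alpha, d_beta, d_gamma = mg_phosphate_distances(frame, mg_atom, atp_residue)
    f = thresholds.first_sphere_max
    ab = d_alpha <= f and d_beta <= f
    bg = d_beta <= f and d_gamma <= f
    if ab and bg:
        logger.info(
            "frame %d: both bidentate patterns qualify (d_alpha=%.2f, d_gamma=%.2f)",
            frame.index, d_alpha, d_gamma,
        )
        return (CoordinationState.FIRST_SPHERE_ALPHA_BETA
                if max(d_alpha, d_beta) <= max(d_beta, d_gamma)
                else CoordinationState.FIRST_SPHERE_BETA_GAMMA)
    if ab:
        return CoordinationState.FIRST_SPHERE_ALPHA_BETA
    if bg:
        return CoordinationState.FIRST_SPHERE_BETA_GAMMA
    if min(d_alpha, d_beta, d_gamma) <= thresholds.second_sphere_max:
        return CoordinationState.SECOND_SPHERE
    return CoordinationState.UNBOUND


def mg_phosphate_distances(
    frame: Frame,
    mg_atom: Selector | str | Atom = "MG",
    atp_residue: str = "ATP",
) -> tuple[float, float, float]:
    """Minimal Mg distances (Å) to the Oα, Oβ and Oγ oxygen groups."""
    mg_pos = _mg_position(frame, mg_atom)
    return (
        _group_min(frame, mg_pos, f"{atp_residue}:Oα"),
        _group_min(frame, mg_pos, f"{atp_residue}:Oβ"),
        _group_min(frame, mg_pos, f"{atp_residue}:Oγ"),
    )


def occupancy(
    trajectory: Trajectory,
    mg_atom: Selector | str = "MG",
    atp_residue: str = "ATP",
    thresholds: CoordinationThresholds = CoordinationThresholds(),
    skip_ps: float = 0.0,
) -> OccupancyReport:
    """Per-frame classification aggregated to state fractions."""
    frames = trajectory.after(skip_ps)
    if not frames:
        raise AnalysisError(f"no frames left after skipping {skip_ps} ps")
    counts = {state: 0 for state in CoordinationState}
    for f in frames:
        counts[classify_mg_state(f, mg_atom, atp_residue, thresholds)] += 1
    n = len(frames)
    return OccupancyReport(
        fractions={s: c / n for s, c in counts.items()}, n_frames=n
    )


def default_binding_site(
    frame: Frame,
    criteria: ContactCriteria = ContactCriteria(),
    atp_residue: str = "ATP",
    proximity: float = 8.0,
) -> list[tuple[str, int]]:
    """Arg/Lys residues with a listed cationic atom within ``proximity`` Å of
    any ligand atom — the default binding-site residue set."""
    try:
        atp = resolve_group(frame, atp_residue)
    except SelectionError:
        return []
    atp_pos = np.array([a.xyz for a in atp])
    site: list[tuple[str, int]] = []
    for atom in frame.atoms:
        names = criteria.cation_atom_table.get(atom.residue_name)
        if not names or atom.name not in names:
            continue
        if np.min(np.linalg.norm(atp_pos - atom.xyz, axis=1)) <= proximity:
            key = (atom.residue_name, atom.residue_number)
            if key not in site:
                site.append(key)
    return site


def repulsive_contacts(
    frame: Frame,
    binding_site_residues: Sequence[tuple[str, int]] | None = None,
    mg_atom: Selector | str | Atom = "MG",
    criteria: ContactCriteria = ContactCriteria(),
) -> int:
    """Count cationic-residue contacts with Mg2+ within the cutoff.

    ``binding_site_residues`` is a list of (residue name, residue number)
    pairs; if None, :func:`default_binding_site` of the frame is used.
    ``per_residue`` mode counts residues with >= 1 qualifying atom;
    ``per_atom`` counts qualifying atoms.
    """
    mg_pos = _mg_position(frame, mg_atom)
    if binding_site_residues is None:
        binding_site_residues = default_binding_site(frame, criteria)
    site = set(binding_site_residues)
    hit_residues: set[tuple[str, int]] = set()
    hit_atoms = 0
    for atom in frame.atoms:
        key = (atom.residue_name, atom.residue_number)
        if key not in site:
            continue
        names = criteria.cation_atom_table.get(atom.residue_name)
        if not names or atom.name not in names:
            continue
        if np.linalg.norm(atom.xyz - mg_pos) <= criteria.max_distance:
            hit_residues.add(key)
            hit_atoms += 1
    return len(hit_residues) if criteria.counting_mode == "per_residue" else hit_atoms


def contact_series(
    trajectory: Trajectory,
    binding_site_residues: Sequence[tuple[str, int]] | None = None,
    mg_atom: Selector | str = "MG",
    criteria: ContactCriteria = ContactCriteria(),
    skip_ps: float = 0.0,
) -> list[int]:
    """Per-retained-frame repulsive-contact counts."""
    frames = trajectory.after(skip_ps)
    if not frames:
        raise AnalysisError(f"no frames left after skipping {skip_ps} ps")
    return [
        repulsive_contacts(f, binding_site_residues, mg_atom, criteria)
        for f in frames
    ]
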