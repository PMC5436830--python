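"""Ground-truth-labelled synthetic inputs for every pipeline stage.

The trajectory generator builds a chemically minimal ATP binding site: an
ATP residue with canonically named phosphate/nucleoside atoms, a Mg2+ ion
placed to realize a requested coordination state, cationic Arg/Lys side
chains at chosen distances from the ion, and donor-hydrogen-acceptor triples
planted at exact distances and angular deviations.  Atom groups are laid out
on a widely spaced grid (cells ~8 Å apart) so that planted contacts are the
only contacts; frames then receive i.i.d. isotropic Gaussian positional
jitter.  The construction is pure geometry — no stereochemistry, force field
or kinetics — which is exactly what distance/angle analyses consume.

Work-sample generators draw forward/backward work from the Gaussian pair

    W_f ~ N(ΔF + βσ²/2, σ²),   W_r ~ N(−ΔF + βσ²/2, σ²)

which satisfies the Crooks fluctuation relation exactly, so BAR has a known
target (for β=1 and forward mean μ: ΔF = μ − σ²/2).  ∂H/∂λ generators emit
per-window series around closed-form λ-profiles with known integrals.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .constants import KJ_PER_KCAL
from .coordination import CoordinationState
from .errors import ConstructionError, MgatpError
from .structures import Atom, Frame, SampleSeries, Trajectory
from .free_energy import LambdaSeries, WorkSet

__all__ = [
    "PlantedHBond",
    "SiteConfig",
    "GroundTruth",
    "WorkConfig",
    "build_site_trajectory",
    "gaussian_work_samples",
    "gaussian_work_series",
    "gaussian_bar_standard_error",
    "synthetic_dhdl",
    "lambda_profile",
    "default_site_config",
    "DEFAULT_PROTEIN_ATP_BONDS",
    "DEFAULT_HELIX_BONDS",
]

_COVALENT_DH = 1.0  # planted donor-hydrogen distance, Å

# Primary (closest alias member) phosphate oxygen positions; 2.8 Å apart so
# that a bidentate Mg placement between neighbours is feasible.
_PHOSPHATE_PRIMARY = {
    "O1A": (0.0, 0.0, 0.0),
    "O1B": (2.8, 0.0, 0.0),
    "O1G": (5.6, 0.0, 0.0),
}
# Remaining phosphate atoms, parked on a distant row.
_PHOSPHATE_SECONDARY = {
    "O2A": (0.0, -9.0, 0.0),
    "O2B": (2.8, -9.0, 0.0),
    "O2G": (5.6, -9.0, 0.0),
    "O3G": (8.4, -9.0, 0.0),
    "O3A": (-2.8, -9.0, 0.0),
    "O3B": (11.2, -9.0, 0.0),
    "PA": (-1.0, -4.5, 0.0),
    "PB": (2.0, -4.5, 0.0),
    "PG": (5.0, -4.5, 0.0),
}
# Nucleoside atoms on an 8 Å grid well away from the phosphate/Mg region.
_NUCLEOSIDE_NAMES = ["O5'", "C5'", "O4'", "C1'", "N9", "N7", "N3", "N1", "N6", "O2'", "O3'"]
_NUCLEOSIDE_SLOTS = {
    name: (24.0 + 8.0 * (i % 4), 8.0 * (i // 4), 0.0)
    for i, name in enumerate(_NUCLEOSIDE_NAMES)
}

_ATP_RESID = 200
_MG_RESID = 300

# Directions cycled per anchor for successive planted bonds, and for cation
# contacts around Mg; chosen mutually well-separated.
_BOND_DIRECTIONS = [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0), (0.0, 1.0, 0.0), (0.0, -1.0, 0.0)]
_CONTACT_DIRECTIONS = [(0.0, 0.0, -1.0), (0.0, 1.0, 0.0),
                       (-0.7071067811865476, 0.0, -0.7071067811865476),
                       (0.0, 0.7071067811865476, -0.7071067811865476)]


@dataclass(frozen=True)
class PlantedHBond:
    """One donor-H···acceptor triple to realize at exact geometry.

    The ATP-side atom (or, for protein-protein bonds, the acceptor) anchors
    the construction at its grid slot; the partner is built outward so that
    d(H···A) and the deviation from D-H···A linearity match exactly.
    """

    donor_residue: str
    donor_number: int
    donor_atom: str
    acceptor_residue: str
    acceptor_number: int
    acceptor_atom: str
    d_ha: float
    deviation_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.d_ha < 10.0):
            raise ConstructionError(f"planted distance {self.d_ha} outside (0, 10) Å")
        if self.d_ha <= _COVALENT_DH * 0.5:
            raise ConstructionError(
                f"planted distance {self.d_ha} Å violates the covalent D-H constraint"
            )
        if not (0.0 <= self.deviation_deg < 90.0):
            raise ConstructionError(
                f"planted deviation {self.deviation_deg}° outside [0, 90)"
            )

    def kind(self, helix_range: tuple[int, int] = (112, 133)) -> str:
        sides_atp = (self.donor_residue == "ATP", self.acceptor_residue == "ATP")
        if sides_atp[0] != sides_atp[1]:
            return "protein_atp"
        if not any(sides_atp):
            lo, hi = sorted(helix_range)
            in_helix = (lo <= self.donor_number <= hi, lo <= self.acceptor_number <= hi)
            if in_helix[0] != in_helix[1]:
                return "helix"
            return "intra" if all(in_helix) else "other"
        return "other"


#: Nine protein-ATP bonds mirroring the named nucleoside-site interactions
#: (Arg92/Arg126 to the adenine and ribose, Glu83 to the 2'/3' hydroxyls,
#: Asp89 to N1/N6), sized to give the ~9-10 bond network seen in binding
#: simulations of this site.
DEFAULT_PROTEIN_ATP_BONDS: tuple[PlantedHBond, ...] = (
    PlantedHBond("ATP", _ATP_RESID, "N6", "ASP", 89, "O", 1.90, 5.0),
    PlantedHBond("ASP", 89, "N", "ATP", _ATP_RESID, "N1", 2.00, 5.0),
    PlantedHBond("ATP", _ATP_RESID, "O2'", "GLU", 83, "OE1", 1.85, 4.0),
    PlantedHBond("ATP", _ATP_RESID, "O3'", "GLU", 83, "OE2", 1.90, 5.0),
    PlantedHBond("ARG", 92, "NH1", "ATP", _ATP_RESID, "N7", 1.95, 4.0),
    PlantedHBond("ARG", 92, "NH2", "ATP", _ATP_RESID, "O4'", 1.90, 5.0),
    PlantedHBond("ARG", 92, "NE", "ATP", _ATP_RESID, "N3", 2.05, 4.0),
    PlantedHBond("ARG", 126, "NH1", "ATP", _ATP_RESID, "O5'", 1.95, 5.0),
    PlantedHBond("ARG", 126, "NH2", "ATP", _ATP_RESID, "N9", 2.10, 4.0),
)

#: Five backbone bonds from the C-terminal helix (residues 112-133) to the
#: rest of the protein, matching the ~5-bond helix network scale.
DEFAULT_HELIX_BONDS: tuple[PlantedHBond, ...] = (
    PlantedHBond("ALA", 115, "N", "ALA", 50, "O", 1.95, 5.0),
    PlantedHBond("ALA", 120, "N", "ALA", 55, "O", 2.00, 5.0),
    PlantedHBond("ALA", 125, "N", "ALA", 60, "O", 1.90, 4.0),
    PlantedHBond("ALA", 130, "N", "ALA", 65, "O", 2.05, 5.0),
    PlantedHBond("ALA", 133, "N", "ALA", 70, "O", 2.00, 5.0),
)


@dataclass
class SiteConfig:
    """Recipe for one synthetic binding-site trajectory."""

    n_frames: int = 50
    frame_spacing_ps: float = 10.0
    planted_hbonds: tuple[PlantedHBond, ...] = ()
    mg_state: CoordinationState = CoordinationState.FIRST_SPHERE_ALPHA_BETA
    mg_distances: tuple[float, float] | float | None = None
    cation_contacts: tuple[tuple[str, float], ...] = ()
    jitter_sigma: float = 0.0
    seed: int = 0
    helix_range: tuple[int, int] = (112, 133)
    label: str = "synthetic"

    def __post_init__(self):
        if self.n_frames < 1:
            raise ConstructionError("need at least one frame")
        if self.jitter_sigma < 0:
            raise ConstructionError("jitter sigma must be non-negative")


@dataclass
class GroundTruth:
    """What the analyses must recover from the noiseless construction."""

    n_hbonds_per_frame: int
    n_protein_atp: int
    n_helix: int
    ehb_protein_atp_kcal: float
    ehb_helix_kcal: float
    ehb_total_kcal: float
    expected_state: str
    contacts_per_residue: int
    contacts_per_atom: int
    binding_site: list[tuple[str, int]]
    planted_distances: dict[str, list[float]]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _mg_position(state: CoordinationState, distances) -> np.ndarray:
    o1a = np.array(_PHOSPHATE_PRIMARY["O1A"])
    o1b = np.array(_PHOSPHATE_PRIMARY["O1B"])
    o1g = np.array(_PHOSPHATE_PRIMARY["O1G"])

    def bidentate(p, q, d1, d2):
        sep = np.linalg.norm(q - p)
        if not (abs(d1 - d2) <= sep <= d1 + d2):
            raise ConstructionError(
                f"bidentate distances ({d1}, {d2}) infeasible for oxygen separation {sep:.2f} Å"
            )
        x = (d1 ** 2 - d2 ** 2 + sep ** 2) / (2 * sep)
        y2 = d1 ** 2 - x ** 2
        if y2 <= 0:
            raise ConstructionError("degenerate bidentate geometry")
        axis = (q - p) / sep
        return p + x * axis + math.sqrt(y2) * np.array([0.0, 1.0, 0.0])

    if state is CoordinationState.FIRST_SPHERE_ALPHA_BETA:
        d1, d2 = distances if distances else (2.0, 2.0)
        return bidentate(o1a, o1b, d1, d2)
    if state is CoordinationState.FIRST_SPHERE_BETA_GAMMA:
        d1, d2 = distances if distances else (2.0, 2.0)
        return bidentate(o1b, o1g, d1, d2)
    if state is CoordinationState.SECOND_SPHERE:
        r = float(distances) if distances else 4.0
        return o1b + np.array([0.0, r, 0.0])
    r = float(distances) if distances else 8.0
    return o1b + np.array([0.0, r, 0.0])


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return "H" if ch == "H" else ch.upper()
    return "X"


def build_site_trajectory(config: SiteConfig) -> tuple[Trajectory, GroundTruth]:
    """Construct the trajectory and its ground truth.

    Deterministic for a fixed seed; with ``jitter_sigma == 0`` every frame
    equals the noiseless base geometry and the analyses recover the ground
    truth exactly.
    """
    base: list[tuple[str, str, str, int]] = []   # (name, element, resname, resnum)
    coords: list[np.ndarray] = []

    def add(name: str, resname: str, resnum: int, pos, element: str | None = None):
        base.append((name, element or _element_of(name), resname, resnum))
        coords.append(np.asarray(pos, dtype=float))

    for name, pos in _PHOSPHATE_PRIMARY.items():
        add(name, "ATP", _ATP_RESID, pos)
    for name, pos in _PHOSPHATE_SECONDARY.items():
        add(name, "ATP", _ATP_RESID, pos, element="P" if name.startswith("P") else "O")
    for name, pos in _NUCLEOSIDE_SLOTS.items():
        add(name, "ATP", _ATP_RESID, pos)

    mg_pos = _mg_position(config.mg_state, config.mg_distances)
    add("MG", "MG", _MG_RESID, mg_pos, element="MG")

    # Cationic residues at requested distances from Mg.  Each residue gets
    # its full cationic-atom complement along one ray, nearest atom first.
    cation_atoms = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",)}
    binding_site: list[tuple[str, int]] = []
    contacts_per_residue = 0
    contacts_per_atom = 0
    for k, (restype, dist) in enumerate(config.cation_contacts):
        if restype not in cation_atoms:
            raise ConstructionError(f"unsupported cationic residue type {restype!r}")
        resnum = 301 + k
        direction = _unit(_CONTACT_DIRECTIONS[k % len(_CONTACT_DIRECTIONS)])
        residue_hit = False
        for j, aname in enumerate(cation_atoms[restype]):
            d = dist + 0.4 * j
            add(aname, restype, resnum, mg_pos + d * direction)
            if d <= 4.5:
                contacts_per_atom += 1
                residue_hit = True
        contacts_per_residue += int(residue_hit)
        binding_site.append((restype, resnum))

    # Planted hydrogen bonds.
    atp_slots = dict(_PHOSPHATE_PRIMARY) | {
        k: v for k, v in _PHOSPHATE_SECONDARY.items()
    } | dict(_NUCLEOSIDE_SLOTS)
    anchor_use: dict[tuple[str, int, str], int] = {}
    helix_cell = 0
    n_pa = n_hx = 0
    ehb_pa = ehb_hx = 0.0
    planted_d: dict[str, list[float]] = {"protein_atp": [], "helix": [], "other": []}
    hydrogen_counter: dict[tuple[str, int], int] = {}

    def next_direction(anchor_key) -> np.ndarray:
        i = anchor_use.get(anchor_key, 0)
        if i >= len(_BOND_DIRECTIONS):
            raise ConstructionError(
                f"too many bonds planted on anchor {anchor_key}"
            )
        anchor_use[anchor_key] = i + 1
        return _unit(_BOND_DIRECTIONS[i])

    def hydrogen_name(resname: str, resnum: int) -> str:
        i = hydrogen_counter.get((resname, resnum), 0)
        hydrogen_counter[(resname, resnum)] = i + 1
        return f"H{i + 1}"

    for bond in config.planted_hbonds:
        kind = bond.kind(config.helix_range)
        theta = math.radians(bond.deviation_deg)
        if bond.donor_residue == "ATP":
            # anchor = ATP donor atom at its slot; build H then acceptor.
            if bond.donor_atom not in atp_slots:
                raise ConstructionError(f"unknown ATP atom {bond.donor_atom!r}")
            d_pos = np.array(atp_slots[bond.donor_atom])
            u = next_direction(("ATP", _ATP_RESID, bond.donor_atom))
            h_pos = d_pos + _COVALENT_DH * u
            v = _perpendicular(u)
            a_pos = h_pos + bond.d_ha * (math.cos(theta) * u + math.sin(theta) * v)
            add(hydrogen_name("ATP", _ATP_RESID), "ATP", _ATP_RESID, h_pos, element="H")
            add(bond.acceptor_atom, bond.acceptor_residue, bond.acceptor_number, a_pos)
        else:
            # anchor = acceptor (ATP slot for protein->ATP bonds, a fresh
            # grid cell for protein-protein bonds); build H then donor.
            if bond.acceptor_residue == "ATP":
                if bond.acceptor_atom not in atp_slots:
                    raise ConstructionError(f"unknown ATP atom {bond.acceptor_atom!r}")
                a_pos = np.array(atp_slots[bond.acceptor_atom])
                anchor_key = ("ATP", _ATP_RESID, bond.acceptor_atom)
            else:
                a_pos = np.array([-20.0 - 8.0 * helix_cell, 0.0, 0.0])
                helix_cell += 1
                anchor_key = (bond.acceptor_residue, bond.acceptor_number, bond.acceptor_atom)
                add(bond.acceptor_atom, bond.acceptor_residue, bond.acceptor_number, a_pos)
            u = next_direction(anchor_key)
            h_pos = a_pos + bond.d_ha * u
            v = _perpendicular(u)
            d_pos = h_pos + _COVALENT_DH * (math.cos(theta) * u + math.sin(theta) * v)
            add(bond.donor_atom, bond.donor_residue, bond.donor_number, d_pos)
            add(hydrogen_name(bond.donor_residue, bond.donor_number),
                bond.donor_residue, bond.donor_number, h_pos, element="H")
            if bond.acceptor_residue == "ATP":
                pass  # acceptor already present at its slot
        e_kcal = 502e3 * math.exp(-3.6 * bond.d_ha) / KJ_PER_KCAL
        if kind == "protein_atp":
            n_pa += 1
            ehb_pa += e_kcal
            planted_d["protein_atp"].append(bond.d_ha)
        elif kind == "helix":
            n_hx += 1
            ehb_hx += e_kcal
            planted_d["helix"].append(bond.d_ha)
        else:
            planted_d["other"].append(bond.d_ha)

    # Filler helix residue so the helix range always selects atoms; its
    # donor hydrogen has no acceptor within reach.
    add("N", "ALA", 118, (-20.0, -14.0, 0.0))
    add("H1", "ALA", 118, (-20.0, -14.0, 1.0), element="H")
    add("O", "ALA", 118, (-16.0, -18.0, 0.0))

    base_coords = np.array(coords)
    rng = np.random.default_rng(config.seed)
    frames = []
    for i in range(config.n_frames):
        xyz = base_coords
        if config.jitter_sigma > 0:
            xyz = base_coords + rng.normal(0.0, config.jitter_sigma, base_coords.shape)
        atoms = [
            Atom(serial=j + 1, name=base[j][0], element=base[j][1],
                 residue_name=base[j][2], residue_number=base[j][3],
                 chain="A", position=tuple(float(x) for x in xyz[j]))
            for j in range(len(base))
        ]
        frames.append(Frame(index=i, time=i * config.frame_spacing_ps, atoms=atoms))

    truth = GroundTruth(
        n_hbonds_per_frame=len(config.planted_hbonds),
        n_protein_atp=n_pa,
        n_helix=n_hx,
        ehb_protein_atp_kcal=ehb_pa,
        ehb_helix_kcal=ehb_hx,
        ehb_total_kcal=ehb_pa + ehb_hx,
        expected_state=config.mg_state.value,
        contacts_per_residue=contacts_per_residue,
        contacts_per_atom=contacts_per_atom,
        binding_site=binding_site,
        planted_distances=planted_d,
    )
    return Trajectory(frames=frames, label=config.label), truth


def default_site_config(
    variant: str = "wild_type",
    n_frames: int = 50,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> SiteConfig:
    """A ready-made binding-site recipe per variant.

    The wild type carries two repulsive Arg contacts near the ion; the
    double mutant (its two extra arginines removed) carries one, and its
    protein-ATP network gains one bond — the qualitative contrast between
    the two systems this generator emulates.
    """
    bonds = DEFAULT_PROTEIN_ATP_BONDS + DEFAULT_HELIX_BONDS
    contacts: tuple[tuple[str, float], ...] = (("ARG", 4.0), ("ARG", 4.2))
    if variant == "mutant":
        bonds = bonds + (
            PlantedHBond("ARG", 99, "NH1", "ATP", _ATP_RESID, "N1", 1.90, 8.0),
        )
        contacts = (("ARG", 4.0),)
    elif variant != "wild_type":
        raise MgatpError(f"unknown variant {variant!r}")
    return SiteConfig(
        n_frames=n_frames,
        planted_hbonds=bonds,
        mg_state=CoordinationState.FIRST_SPHERE_ALPHA_BETA,
        cation_contacts=contacts,
        jitter_sigma=jitter_sigma,
        seed=seed,
        label=variant,
    )


# ---------------------------------------------------------------------------
# Free-energy sample generators
# ---------------------------------------------------------------------------

@dataclass
class WorkConfig:
    """Crooks-consistent Gaussian work recipe with known ΔF."""

    delta_f: float = 2.0
    sigma: float = 2.0
    n_samples: int = 1000
    beta: float = 1.0
    seed: int = 0
    unit_tag: str = "kJ/mol"

    def __post_init__(self):
        if self.sigma <= 0:
            raise MgatpError("sigma must be positive")
        if self.n_samples < 2:
            raise MgatpError("need at least 2 samples per direction")


def gaussian_work_samples(config: WorkConfig) -> WorkSet:
    """Draw the Crooks-consistent Gaussian forward/backward work pair."""
    rng = np.random.default_rng(config.seed)
    shift = config.beta * config.sigma ** 2 / 2.0
    forward = rng.normal(config.delta_f + shift, config.sigma, config.n_samples)
    backward = rng.normal(-config.delta_f + shift, config.sigma, config.n_samples)
    return WorkSet(forward=forward, backward=backward, beta=config.beta,
                   unit_tag=config.unit_tag)


def gaussian_work_series(
    config: WorkConfig,
    t0_ps: float = 0.0,
    spacing_ps: float = 1.0,
    forward_drift_per_ps: float = 0.0,
) -> tuple[SampleSeries, SampleSeries]:
    """Work samples with a time axis, for slice-convergence checks.

    ``forward_drift_per_ps`` adds a linear-in-time mean shift to the forward
    direction, modelling unequilibrated sampling.
    """
    ws = gaussian_work_samples(config)
    times = t0_ps + spacing_ps * np.arange(config.n_samples)
    fwd = ws.forward + forward_drift_per_ps * (times - t0_ps)
    return (
        SampleSeries(times=times, values=fwd, unit_tag=config.unit_tag),
        SampleSeries(times=times, values=ws.backward, unit_tag=config.unit_tag),
    )


def gaussian_bar_standard_error(
    delta_f: float, sigma: float, beta: float, n_per_direction: int
) -> float:
    """Analytic asymptotic standard error of BAR on the Gaussian Crooks pair.

    Computed as the inverse Fisher information of the logistic likelihood
    under the true mixture of the forward work density and the negated
    backward work density (equal sample counts per direction).
    """
    shift = beta * sigma ** 2 / 2.0

    def integrand(w):
        rho_f = norm.pdf(w, delta_f + shift, sigma)
        rho_v = norm.pdf(w, delta_f - shift, sigma)
        p = 1.0 / (1.0 + np.exp(-beta * (w - delta_f)))
        return (rho_f + rho_v) * p * (1.0 - p)

    lo = delta_f - shift - 12 * sigma
    hi = delta_f + shift + 12 * sigma
    integral, _ = quad(integrand, lo, hi, limit=200)
    info = beta ** 2 * n_per_direction * integral
    return float(1.0 / math.sqrt(info))


def lambda_profile(name: str, **params):
    """Closed-form ∂H/∂λ profiles with known integrals over [0, 1].

    ``constant``: value c.  ``linear``: slope·λ + intercept.
    ``cubic``: a + b·λ + c·λ² + d·λ³.
    Returns ``(fn, integral_01)``.
    """
    if name == "constant":
        c = params.get("c", 1.0)
        return (lambda lam: c + 0.0 * lam), c
    if name == "linear":
        s = params.get("slope", 2.0)
        b = params.get("intercept", 0.0)
        return (lambda lam: s * lam + b), s / 2.0 + b
    if name == "cubic":
        a = params.get("a", 0.0)
        b = params.get("b", 0.0)
        c = params.get("c", 0.0)
        d = params.get("d", 1.0)
        return (
            lambda lam: a + b * lam + c * lam ** 2 + d * lam ** 3,
            a + b / 2.0 + c / 3.0 + d / 4.0,
        )
    raise MgatpError(f"unknown profile {name!r}")


def synthetic_dhdl(
    profile,
    lambda_grid: Sequence[float] | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    n_samples_per_window: int = 40,
    window_ps: float = 500.0,
    unit_tag: str = "kJ/mol",
) -> LambdaSeries:
    """Per-window ∂H/∂λ series around a closed-form profile.

    ``profile`` is a callable λ → value or a profile name handled by
    :func:`lambda_profile`.  The default grid has 85 evenly spaced windows
    over [0, 1], the usual window count of a serial decoupling protocol.
    """
    if callable(profile):
        fn = profile
    else:
        fn, _ = lambda_profile(profile)
    if lambda_grid is None:
        lambda_grid = np.linspace(0.0, 1.0, 85)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise MgatpError("empty lambda grid")
    rng = np.random.default_rng(seed)
    times = np.arange(n_samples_per_window) * (window_ps / n_samples_per_window)
    series = []
    for lam in lambda_grid:
        values = np.full(times.shape, float(fn(lam)))
        if noise_sigma > 0:
            values = values + rng.normal(0.0, noise_sigma, values.shape)
        series.append(SampleSeries(times=times.copy(), values=values, unit_tag=unit_tag))
    return LambdaSeries(lambda_values=lambda_grid, dhdl_samples=series)
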