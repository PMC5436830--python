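"""Structure and sample-series I/O.

Multi-model PDB files are the trajectory format: one MODEL per frame,
coordinates in Angstrom, HETATM records (ATP, MG, HOH) retained.  Free-energy
sample series are read from two-column whitespace text files in the XVG
dialect ('#' and '@' lines are comments/metadata).

Atom selection supports the composite group labels common in binding-site
work: ``NHx`` for the two terminal arginine guanidinium nitrogens, ``Oεx``
for the glutamate carboxylate oxygens, and ``Oα``/``Oβ``/``Oγ`` for the
non-bridging oxygens of the ATP alpha/beta/gamma phosphates.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

from .errors import (
    EmptySeriesError,
    FormatError,
    ParseError,
    SelectionError,
    StructureError,
)

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "AtomGroupAlias",
    "SampleSeries",
    "Selector",
    "DEFAULT_ALIASES",
    "STANDARD_AMINO_ACIDS",
    "read_pdb",
    "write_pdb",
    "read_xvg",
    "write_xvg",
    "parse_selector",
    "resolve_group",
]

#: Residue names treated as protein when partitioning hydrogen bonds.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_ONE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass(frozen=True)
class Atom:
    """One named atom of one frame; position in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float]

    def __post_init__(self):
        if not self.name:
            raise StructureError("atom name must be non-empty")
        if not all(np.isfinite(self.position)):
            raise StructureError(f"non-finite position for atom {self.name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    def residue_key(self) -> tuple[str, int, str]:
        return (self.residue_name, self.residue_number, self.chain)


@dataclass
class Frame:
    """One trajectory frame: an ordered atom list at a time point (ps)."""

    index: int
    time: float
    atoms: list[Atom]

    def __post_init__(self):
        if self.index < 0 or self.time < 0:
            raise StructureError("frame index and time must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Trajectory:
    """Ordered frames with identical atom naming/ordering."""

    frames: list[Frame]
    label: str = ""

    def __post_init__(self):
        if not self.frames:
            raise StructureError("a trajectory must contain at least one frame")
        n0 = len(self.frames[0].atoms)
        for f in self.frames:
            if len(f.atoms) != n0:
                raise StructureError(
                    f"frame {f.index} has {len(f.atoms)} atoms, expected {n0}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def after(self, skip_ps: float) -> list[Frame]:
        """Frames with time >= ``skip_ps`` (equilibration discard)."""
        return [f for f in self.frames if f.time >= skip_ps]


@dataclass(frozen=True)
class AtomGroupAlias:
    """A composite atom label and the concrete atom names it stands for."""

    alias: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise SelectionError(f"alias {self.alias!r} has no members")


def _alias_table(pairs: dict[str, Iterable[str]]) -> dict[str, frozenset[str]]:
    return {k: frozenset(v) for k, v in pairs.items()}


#: Composite-label table.  The Greek spellings and ASCII fallbacks are
#: interchangeable.  Bridging phosphate oxygens (O3A, O3B) are deliberately
#: excluded from the Oα/Oβ/Oγ groups: cation chelation and arginine contacts
#: involve the non-bridging oxygens.
DEFAULT_ALIASES: dict[str, frozenset[str]] = _alias_table({
    "NHx": ["NH1", "NH2"],
    "Oεx": ["OE1", "OE2"],
    "OEx": ["OE1", "OE2"],
    "Oδx": ["OD1", "OD2"],
    "ODx": ["OD1", "OD2"],
    "N3/7/9": ["N3", "N7", "N9"],
    "Oα": ["O1A", "O2A"],
    "Oalpha": ["O1A", "O2A"],
    "Oβ": ["O1B", "O2B"],
    "Obeta": ["O1B", "O2B"],
    "Oγ": ["O1G", "O2G", "O3G"],
    "Ogamma": ["O1G", "O2G", "O3G"],
})


@dataclass(frozen=True)
class Selector:
    """Residue/atom filter.  ``atom=None`` selects every atom of the residue;
    an atom label may be an alias from the alias table."""

    residue_name: str | None = None
    residue_number: int | None = None
    chain: str | None = None
    atom: str | None = None

    def __str__(self) -> str:
        parts = []
        if self.residue_name:
            parts.append(self.residue_name)
        if self.residue_number is not None:
            parts.append(str(self.residue_number))
        if self.chain:
            parts.append(f"chain {self.chain}")
        if self.atom:
            parts.append(self.atom)
        return " ".join(parts) or "<any>"


_COLON_RE = re.compile(r"^([A-Za-z]+)(\d+)?:(.+)$")


def parse_selector(text: str) -> Selector:
    """Parse selector strings such as ``"ARG 92 NHx"``, ``"R92:NHx"``,
    ``"ATP:Oα"``, ``"E83:Oεx"`` or ``"MG"``.

    A leading single-letter residue code followed by a number (``R92``) is
    expanded to its three-letter name.  A bare residue name selects all its
    atoms.
    """
    text = text.strip()
    if not text:
        raise SelectionError("empty selector")
    m = _COLON_RE.match(text)
    if m:
        res, num, atom = m.group(1), m.group(2), m.group(3)
        res_name = _ONE_LETTER.get(res, res.upper()) if len(res) == 1 else res.upper()
        return Selector(
            residue_name=res_name,
            residue_number=int(num) if num else None,
            atom=atom,
        )
    tokens = text.split()
    if len(tokens) == 1:
        return Selector(residue_name=tokens[0].upper())
    if len(tokens) == 2:
        if tokens[1].isdigit():
            return Selector(residue_name=tokens[0].upper(), residue_number=int(tokens[1]))
        return Selector(residue_name=tokens[0].upper(), atom=tokens[1])
    if len(tokens) == 3:
        if not tokens[1].isdigit():
            raise SelectionError(f"cannot parse selector {text!r}")
        return Selector(
            residue_name=tokens[0].upper(),
            residue_number=int(tokens[1]),
            atom=tokens[2],
        )
    raise SelectionError(f"cannot parse selector {text!r}")


def resolve_group(
    frame: Frame,
    selector: Selector | str,
    aliases: dict[str, frozenset[str]] | None = None,
) -> list[Atom]:
    """All atoms of ``frame`` matching ``selector``; alias labels expand to
    their member-name sets.  Raises :class:`SelectionError` on zero matches.
    """
    if isinstance(selector, str):
        selector = parse_selector(selector)
    aliases = DEFAULT_ALIASES if aliases is None else aliases
    names: frozenset[str] | None = None
    if selector.atom is not None:
        names = aliases.get(selector.atom, frozenset([selector.atom]))
    out = []
    for atom in frame.atoms:
        if selector.residue_name is not None and atom.residue_name != selector.residue_name:
            continue
        if selector.residue_number is not None and atom.residue_number != selector.residue_number:
            continue
        if selector.chain is not None and atom.chain != selector.chain:
            continue
        if names is not None and atom.name not in names:
            continue
        out.append(atom)
    if not out:
        raise SelectionError(f"selector {selector} matched no atoms")
    return out


# ---------------------------------------------------------------------------
# PDB trajectory I/O (biotite handles the fixed-column format)
# ---------------------------------------------------------------------------

def _prevalidate_pdb(lines: Sequence[str]) -> None:
    for i, line in enumerate(lines, start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise ParseError(f"malformed {record} record: {line.rstrip()!r}", i)


def read_pdb(
    source: str | Path,
    label: str = "",
    frame_spacing_ps: float = 1.0,
    start_ps: float = 0.0,
    times: Sequence[float] | None = None,
) -> Trajectory:
    """Read a (multi-model) PDB file or PDB text into a :class:`Trajectory`.

    MODEL/ENDMDL records delimit frames; a single-model file yields one frame.
    PDB carries no time axis, so frame times default to
    ``start_ps + index * frame_spacing_ps`` unless ``times`` is given.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
        if not label:
            label = Path(source).stem
    else:
        text = str(source)
    lines = text.splitlines()
    _prevalidate_pdb(lines)
    try:
        pdb_file = _pdb.PDBFile.read(io.StringIO(text))
        stack = pdb_file.get_structure(model=None, extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise StructureError(f"cannot read PDB structure: {exc}") from exc
    if stack.array_length() == 0:
        raise StructureError("PDB file contains no atoms")

    frames: list[Frame] = []
    n_models = stack.stack_depth()
    if times is not None and len(times) != n_models:
        raise StructureError(
            f"got {len(times)} times for {n_models} models"
        )
    for m in range(n_models):
        arr = stack[m]
        t = times[m] if times is not None else start_ps + m * frame_spacing_ps
        atoms = [
            Atom(
                serial=int(arr.atom_id[i]),
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]),
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
                position=tuple(float(x) for x in arr.coord[i]),
            )
            for i in range(arr.array_length())
        ]
        frames.append(Frame(index=m, time=float(t), atoms=atoms))
    ref_names = [a.name for a in frames[0].atoms]
    for f in frames[1:]:
        if [a.name for a in f.atoms] != ref_names:
            raise StructureError(f"frame {f.index} atom ordering differs from frame 0")
    return Trajectory(frames=frames, label=label)


def write_pdb(
    trajectory: Trajectory,
    path: str | Path | None = None,
    always_model: bool = False,
) -> str:
    """Serialize a trajectory as fixed-column PDB text (one MODEL per frame).

    A one-frame trajectory is written without MODEL records unless
    ``always_model`` is set.
    """
    for atom in trajectory.frames[0].atoms:
        if len(atom.name) > 4:
            raise FormatError(f"atom name {atom.name!r} exceeds 4 characters")
    arrays = []
    for frame in trajectory.frames:
        n = len(frame.atoms)
        arr = struc.AtomArray(n)
        arr.coord = frame.positions
        arr.atom_name = np.array([a.name for a in frame.atoms])
        arr.res_name = np.array([a.residue_name for a in frame.atoms])
        arr.res_id = np.array([a.residue_number for a in frame.atoms])
        arr.chain_id = np.array([a.chain for a in frame.atoms])
        arr.element = np.array([a.element for a in frame.atoms])
        arr.hetero = np.array(
            [a.residue_name not in STANDARD_AMINO_ACIDS for a in frame.atoms]
        )
        arrays.append(arr)
    pdb_file = _pdb.PDBFile()
    if len(arrays) == 1 and not always_model:
        pdb_file.set_structure(arrays[0])
    else:
        pdb_file.set_structure(struc.stack(arrays))
    lines = list(pdb_file.lines)
    if len(arrays) == 1 and always_model and not any(
        ln.startswith("MODEL") for ln in lines
    ):
        lines = ["MODEL        1", *lines, "ENDMDL"]
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# XVG-dialect sample series
# ---------------------------------------------------------------------------

@dataclass
class SampleSeries:
    """Time-stamped scalar samples (e.g. per-window dH/dλ or work values)."""

    times: np.ndarray
    values: np.ndarray
    unit_tag: str = "kJ/mol"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise StructureError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise StructureError("times must be non-decreasing")

    def __len__(self) -> int:
        return self.times.size


def read_xvg(source: str | Path, unit_tag: str = "kJ/mol") -> SampleSeries:
    """Read a two-column whitespace text file; '#'/'@' lines are skipped."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    times, values = [], []
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped[0] in "#@":
            continue
        tokens = stripped.split()
        if len(tokens) < 2:
            raise ParseError(f"expected two columns, got {stripped!r}", i)
        try:
            times.append(float(tokens[0]))
            values.append(float(tokens[1]))
        except ValueError:
            raise ParseError(f"non-numeric token in data row {stripped!r}", i)
    if not times:
        raise EmptySeriesError("no numeric rows found")
    return SampleSeries(times=np.array(times), values=np.array(values), unit_tag=unit_tag)


def write_xvg(series: SampleSeries, path: str | Path | None = None,
              title: str = "") -> str:
    """Write a series so that :func:`read_xvg` reproduces it bit-identically
    (shortest round-trip float representation)."""
    lines = []
    if title:
        lines.append(f"# {title}")
    lines.append(f"@ units {series.unit_tag}")
    for t, v in zip(series.times, series.values):
        lines.append(f"{float(t)!r} {float(v)!r}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
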