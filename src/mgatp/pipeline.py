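"""Wild-type vs mutant comparison pipeline.

Runs the full analysis over replica trajectory sets for two variants at one
Mg2+ coordination state each: hydrogen-bond counts (protein-ligand and
helix-to-rest), repulsive contacts, network energies with replica mean ± SD,
and the binding-energy penalty ΔE_HB = E_HB(mutant) − E_HB(wild type).

Outputs are deterministic: identical configuration and inputs produce
byte-identical TSV/JSON files (fixed float formatting, 6 significant digits
in machine files, 1 decimal in the human-readable table).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coordination import (
    ContactCriteria,
    CoordinationThresholds,
    contact_series,
)
from .energetics import (
    EnergyTable,
    EspinosaParams,
    ReplicaSummary,
    energy_components,
    energy_penalty,
    replica_summary,
)
from .errors import MgatpError
from .hbonds import (
    HBondCriteria,
    helix_network_hbonds,
    protein_atp_count_series,
)
from .structures import Trajectory, read_pdb

logger = logging.getLogger(__name__)

__all__ = ["VariantSpec", "RunConfig", "run_compare", "load_config"]

#: Defaults that encode the analysis conditions, echoed to the run log.
_PARAMETER_SOURCES = {
    "hbond_distance_cutoff": "2.7 Å (donor hydrogen to acceptor)",
    "hbond_angle_cutoff": "30° deviation from linearity",
    "contact_cutoff": "4.5 Å cationic atom to Mg2+",
    "skip_ps": "10 ns equilibration discard",
    "helix_range": "second C-terminal helix, residues 112-133",
    "espinosa_prefactor": "502e3 kJ/mol",
    "espinosa_decay": "3.6 1/Å",
}


@dataclass
class VariantSpec:
    """Replica trajectories of one variant at one coordination state."""

    trajectories: list[str | Path | Trajectory]
    coordination: str = "FIRST_SPHERE_ALPHA_BETA"


@dataclass
class RunConfig:
    """All knobs of one comparison run."""

    variants: dict[str, VariantSpec]
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    contact_criteria: ContactCriteria = field(default_factory=ContactCriteria)
    thresholds: CoordinationThresholds = field(default_factory=CoordinationThresholds)
    espinosa: EspinosaParams = field(default_factory=EspinosaParams)
    skip_ps: float = 10_000.0
    helix_range: tuple[int, int] = (112, 133)
    frame_spacing_ps: float = 100.0
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        if not self.variants:
            raise MgatpError("at least one variant required")
        for name, spec in self.variants.items():
            if not spec.trajectories:
                raise MgatpError(f"variant {name!r} has no replicas")


def _load(item, spacing: float) -> Trajectory:
    if isinstance(item, Trajectory):
        return item
    return read_pdb(Path(item), frame_spacing_ps=spacing)


def _analyse_variant(name: str, spec: VariantSpec, cfg: RunConfig) -> EnergyTable:
    runs = [_load(t, cfg.frame_spacing_ps) for t in spec.trajectories]
    count_pa = [protein_atp_count_series(t, cfg.criteria, cfg.skip_ps) for t in runs]
    count_hx = [helix_network_hbonds(t, cfg.helix_range, cfg.criteria, cfg.skip_ps)
                for t in runs]
    contacts = [contact_series(t, None, "MG", cfg.contact_criteria, cfg.skip_ps)
                for t in runs]
    energies = energy_components(
        runs, cfg.criteria, cfg.helix_range, cfg.espinosa, cfg.skip_ps
    )
    return EnergyTable(
        variant=name,
        coordination=spec.coordination,
        hbond_count_protein_atp=replica_summary(count_pa),
        hbond_count_helix=replica_summary(count_hx),
        repulsive_contacts=replica_summary(contacts),
        energy_protein_atp=energies["protein_atp"],
        energy_helix=energies["helix_network"],
        energy_total=energies["total"],
    )


def _summary_cell(s: ReplicaSummary | None, decimals: int = 1) -> str:
    if s is None:
        return "n/a"
    if s.sd is None:
        return f"{s.mean:.{decimals}f}"
    return f"{s.mean:.{decimals}f} +/- {s.sd:.{decimals}f}"


_ROWS = [
    ("h-bonds (protein-ATP)", "hbond_count_protein_atp"),
    ("h-bonds (2nd alpha-helix)", "hbond_count_helix"),
    ("repulsive contacts", "repulsive_contacts"),
    ("E_HB (h-bonds (protein-ATP))", "energy_protein_atp"),
    ("E_HB (h-bonds (2nd alpha-helix))", "energy_helix"),
    ("E_HB", "energy_total"),
]


def tables_to_frame(tables: dict[str, EnergyTable]) -> pd.DataFrame:
    """Human-readable results table, one column per variant."""
    data = {}
    for name, tab in tables.items():
        col = f"{name} ({tab.coordination})"
        data[col] = [_summary_cell(getattr(tab, attr)) for _, attr in _ROWS]
    return pd.DataFrame(data, index=[label for label, _ in _ROWS])


def _table_json(tab: EnergyTable) -> dict:
    out = {"variant": tab.variant, "coordination": tab.coordination}
    for _, attr in _ROWS:
        s: ReplicaSummary | None = getattr(tab, attr)
        out[attr] = None if s is None else {
            "run_means": [round(x, 6) for x in s.run_means],
            "mean": round(s.mean, 6),
            "sd": None if s.sd is None else round(s.sd, 6),
        }
    return out


def run_compare(cfg: RunConfig) -> tuple[dict[str, EnergyTable], float | None]:
    """Analyse every variant and, if both ``wild_type`` and ``mutant`` are
    present, report the binding-energy penalty mutant − wild type.

    When ``cfg.output_dir`` is set, writes ``table.tsv``, ``table.json``,
    ``report.txt`` and ``run.log``; on any stage failure the partially
    written files are removed and the error re-raised with the stage name.
    """
    written: list[Path] = []
    outdir = Path(cfg.output_dir) if cfg.output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        tables: dict[str, EnergyTable] = {}
        for name, spec in cfg.variants.items():
            try:
                tables[name] = _analyse_variant(name, spec, cfg)
            except MgatpError as exc:
                raise MgatpError(f"stage {name!r}: {exc}") from exc
        penalty = None
        if "wild_type" in tables and "mutant" in tables:
            penalty = energy_penalty(tables["mutant"], tables["wild_type"])
        if outdir is not None:
            frame = tables_to_frame(tables)
            p = outdir / "table.tsv"
            frame.to_csv(p, sep="\t")
            written.append(p)
            payload = {
                "tables": {k: _table_json(t) for k, t in tables.items()},
                "penalty_kcal_per_mol": None if penalty is None else round(penalty, 6),
            }
            p = outdir / "table.json"
            p.write_text(json.dumps(payload, indent=2) + "\n")
            written.append(p)
            report = frame.to_string()
            if penalty is not None:
                report += f"\n\nDelta E_HB (mutant - wild type): {penalty:.1f} kcal/mol\n"
            p = outdir / "report.txt"
            p.write_text(report)
            written.append(p)
            p = outdir / "run.log"
            p.write_text(_run_log(cfg))
            written.append(p)
        return tables, penalty
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _run_log(cfg: RunConfig) -> str:
    lines = ["# parameter values (value | meaning)"]
    entries = {
        "hbond_distance_cutoff": cfg.criteria.max_h_acceptor_distance,
        "hbond_angle_cutoff": cfg.criteria.max_angle_deviation,
        "contact_cutoff": cfg.contact_criteria.max_distance,
        "contact_counting_mode": cfg.contact_criteria.counting_mode,
        "first_sphere_max": cfg.thresholds.first_sphere_max,
        "second_sphere_max": cfg.thresholds.second_sphere_max,
        "skip_ps": cfg.skip_ps,
        "helix_range": cfg.helix_range,
        "espinosa_prefactor": cfg.espinosa.prefactor,
        "espinosa_decay": cfg.espinosa.decay,
        "frame_spacing_ps": cfg.frame_spacing_ps,
        "seed": cfg.seed,
    }
    for key, value in entries.items():
        note = _PARAMETER_SOURCES.get(key, "")
        lines.append(f"{key} = {value}" + (f"  | {note}" if note else ""))
    for name, spec in cfg.variants.items():
        files = [str(t) if not isinstance(t, Trajectory) else t.label
                 for t in spec.trajectories]
        lines.append(f"variant {name}: coordination={spec.coordination} replicas={files}")
    return "\n".join(lines) + "\n"


def load_config(path: str | Path) -> RunConfig:
    """Read a TOML run configuration.

    Layout: one table per variant with ``trajectories`` (list of PDB paths)
    and ``coordination``; an optional ``[parameters]`` table overriding any
    numeric default.
    """
    import tomllib

    raw = tomllib.loads(Path(path).read_text())
    params = raw.pop("parameters", {})
    base = Path(path).parent
    variants = {}
    for name, block in raw.items():
        paths = [str((base / p)) if not Path(p).is_absolute() else p
                 for p in block["trajectories"]]
        for p in paths:
            if not Path(p).exists():
                raise MgatpError(f"trajectory file not found: {p}")
        variants[name] = VariantSpec(
            trajectories=paths,
            coordination=block.get("coordination", "FIRST_SPHERE_ALPHA_BETA"),
        )
    return RunConfig(
        variants=variants,
        criteria=HBondCriteria(
            max_h_acceptor_distance=params.get("hbond_distance_cutoff", 2.7),
            max_angle_deviation=params.get("hbond_angle_cutoff", 30.0),
        ),
        contact_criteria=ContactCriteria(
            max_distance=params.get("contact_cutoff", 4.5),
            counting_mode=params.get("contact_counting_mode", "per_residue"),
        ),
        thresholds=CoordinationThresholds(
            first_sphere_max=params.get("first_sphere_max", 2.6),
            second_sphere_max=params.get("second_sphere_max", 5.0),
        ),
        espinosa=EspinosaParams(
            prefactor=params.get("espinosa_prefactor", 502e3),
            decay=params.get("espinosa_decay", 3.6),
        ),
        skip_ps=params.get("skip_ps", 10_000.0),
        helix_range=(params.get("helix_lo", 112), params.get("helix_hi", 133)),
        frame_spacing_ps=params.get("frame_spacing_ps", 100.0),
        output_dir=params.get("output_dir"),
        seed=params.get("seed", 0),
    )
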