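"""Hydrogen-bond energetics and replica statistics.

Each detected hydrogen bond is scored with the empirical exponential
distance-energy relation

    E_HB = -502e3 * exp(-3.6 * d(H···A))   [kJ/mol]

where d(H···A) is the hydrogen-to-acceptor distance in Å.  Network energies
are the sum over all detected bonds, converted to kcal/mol (4.184 kJ/kcal)
and reported as magnitudes, matching the usual tabular convention for
binding-network strengths.

Replica statistics follow the runs-as-sample convention: each independent
run is first reduced to its own time average; the reported mean and sample
standard deviation (n-1 denominator) are taken across those run means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KJ_PER_KCAL
from .errors import AnalysisError, MgatpError
from .hbonds import (
    HBondCriteria,
    HBondRecord,
    helix_rest_hbonds,
    protein_atp_hbonds,
)
from .structures import Trajectory

__all__ = [
    "EspinosaParams",
    "EnergyComponents",
    "ReplicaSummary",
    "EnergyTable",
    "espinosa_energy",
    "frame_ehb",
    "replica_summary",
    "energy_components",
    "energy_penalty",
]


@dataclass(frozen=True)
class EspinosaParams:
    """Parameters of the exponential distance-energy relation.

    The default prefactor (502e3 kJ/mol) and decay (3.6 1/Å) are the
    published constants of the relation; both are configurable.
    """

    prefactor: float = 502e3
    decay: float = 3.6
    report_unit: str = "kcal/mol"

    def __post_init__(self):
        if self.prefactor <= 0 or self.decay <= 0:
            raise MgatpError("prefactor and decay must be positive")


def espinosa_energy(d_ha: float, params: EspinosaParams = EspinosaParams()) -> float:
    """Signed bond energy (kJ/mol, negative) for H···A distance ``d_ha`` (Å)."""
    if d_ha <= 0:
        raise MgatpError(f"distance must be positive, got {d_ha}")
    return -params.prefactor * np.exp(-params.decay * d_ha)


def frame_ehb(
    records: Sequence[HBondRecord],
    params: EspinosaParams = EspinosaParams(),
) -> float:
    """Magnitude of the summed bond energies of one frame, in kcal/mol."""
    total_kj = sum(espinosa_energy(r.d_ha, params) for r in records)
    return abs(total_kj) / KJ_PER_KCAL


@dataclass
class ReplicaSummary:
    """Mean and sample SD across per-run averages.

    ``sd`` is ``None`` (not 0) for a single run, where the sample standard
    deviation is undefined.
    """

    run_means: list[float]
    mean: float
    sd: float | None

    def __str__(self) -> str:
        if self.sd is None:
            return f"{self.mean:.2f}"
        return f"{self.mean:.2f} +/- {self.sd:.2f}"


def replica_summary(per_run_series: Sequence[Sequence[float]]) -> ReplicaSummary:
    """Reduce each run to its mean, then summarize across runs.

    Pooling all frames of unequal-length runs would weight runs by length;
    this deliberately uses the mean of run means instead.
    """
    if not per_run_series:
        raise AnalysisError("no runs provided")
    run_means = []
    for i, series in enumerate(per_run_series):
        arr = np.asarray(series, dtype=float)
        if arr.size == 0:
            raise AnalysisError(f"run {i} has no retained frames")
        run_means.append(float(arr.mean()))
    mean = float(np.mean(run_means))
    if len(run_means) == 1:
        sd = None
    elif all(m == run_means[0] for m in run_means):
        sd = 0.0  # exact, avoids float round-off through the mean
    else:
        sd = float(np.std(run_means, ddof=1))
    return ReplicaSummary(run_means=run_means, mean=mean, sd=sd)


@dataclass
class EnergyComponents:
    """Protein-ligand and helix-network energy magnitudes and their total
    (kcal/mol).  The total is always the sum of the two components."""

    protein_atp: float
    helix_network: float
    total: float = field(init=False)

    def __post_init__(self):
        if self.protein_atp < 0 or self.helix_network < 0:
            raise MgatpError("component magnitudes must be non-negative")
        self.total = self.protein_atp + self.helix_network


def energy_components(
    trajectory_set: Sequence[Trajectory],
    criteria: HBondCriteria = HBondCriteria(),
    helix_range: tuple[int, int] = (112, 133),
    params: EspinosaParams = EspinosaParams(),
    skip_ps: float = 0.0,
    ligand_resname: str = "ATP",
) -> dict[str, ReplicaSummary]:
    """Per-replica-set energy components.

    For every run: each retained frame is scored for (a) protein-ligand
    bonds and (b) helix-to-rest protein bonds; per-frame E_HB sums are
    averaged over the run.  Totals are formed per run (component sum) before
    cross-run summarizing, so the total summary is consistent with the
    component summaries.

    Returns a dict with keys ``protein_atp``, ``helix_network``, ``total``.
    """
    per_run_pa: list[list[float]] = []
    per_run_hx: list[list[float]] = []
    for traj in trajectory_set:
        frames = traj.after(skip_ps)
        if not frames:
            raise AnalysisError(
                f"run {traj.label!r}: no frames after {skip_ps} ps skip"
            )
        pa = [frame_ehb(protein_atp_hbonds(f, criteria, ligand_resname), params)
              for f in frames]
        hx = [frame_ehb(helix_rest_hbonds(f, helix_range, criteria), params)
              for f in frames]
        per_run_pa.append(pa)
        per_run_hx.append(hx)
    s_pa = replica_summary(per_run_pa)
    s_hx = replica_summary(per_run_hx)
    totals = [[a + b] for a, b in zip(s_pa.run_means, s_hx.run_means)]
    return {
        "protein_atp": s_pa,
        "helix_network": s_hx,
        "total": replica_summary(totals),
    }


@dataclass
class EnergyTable:
    """One variant x coordination-state column of the results table."""

    variant: str
    coordination: str
    hbond_count_protein_atp: ReplicaSummary | None = None
    hbond_count_helix: ReplicaSummary | None = None
    repulsive_contacts: ReplicaSummary | None = None
    energy_protein_atp: ReplicaSummary | None = None
    energy_helix: ReplicaSummary | None = None
    energy_total: ReplicaSummary | None = None

    @classmethod
    def from_components(
        cls,
        variant: str,
        coordination: str,
        protein_atp: float,
        helix_network: float,
    ) -> "EnergyTable":
        """Assemble a table column from already-averaged component energies
        (kcal/mol magnitudes); the total is their sum."""
        comp = EnergyComponents(protein_atp=protein_atp, helix_network=helix_network)
        return cls(
            variant=variant,
            coordination=coordination,
            energy_protein_atp=ReplicaSummary([protein_atp], protein_atp, None),
            energy_helix=ReplicaSummary([helix_network], helix_network, None),
            energy_total=ReplicaSummary([comp.total], comp.total, None),
        )

    @property
    def total(self) -> float:
        if self.energy_total is None:
            raise AnalysisError("table has no energy totals")
        return self.energy_total.mean


def energy_penalty(table_mutant: EnergyTable, table_wild_type: EnergyTable) -> float:
    """Binding-network energy penalty ΔE_HB = E_HB(mutant) - E_HB(wild type).

    Both tables must refer to the same Mg2+ coordination state.
    """
    if table_mutant.coordination != table_wild_type.coordination:
        raise MgatpError(
            "cannot compare tables at different coordination states: "
            f"{table_mutant.coordination} vs {table_wild_type.coordination}"
        )
    return table_mutant.total - table_wild_type.total
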