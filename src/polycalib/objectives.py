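"""Six-objective evaluation for polymorph force-field calibration.

For each of three polymorphs the calibration scores a candidate parameter
set by (i) the absolute fractional error of the relaxed lattice energy and
(ii) the root-mean-square fractional error of the six relaxed cell
parameters, against experimental (or fixture-generated) targets.  A
stability-ordering constraint flags parameter sets that rank the
polymorphs correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import SymmetryConstraint, UnitCell, build_supercell
from .forcefield import ParameterVector, apply_parameters
from .properties import lattice_energy
from .relax import RelaxSettings, full_relaxation

__all__ = [
    "PolymorphTarget",
    "PolymorphStructure",
    "ObjectiveVector",
    "rms_fractional_error",
    "lattice_objective",
    "cell_objective",
    "ordering_constraint",
    "evaluate_objectives",
    "FAILED_OBJECTIVE",
]

#: sentinel objective value for failed relaxations (keeps optimizers alive)
FAILED_OBJECTIVE = 1e3

#: tie tolerance (kJ mol^-1) for the stability-ordering constraint
ORDERING_TIE_TOL = 1e-9


@dataclass(frozen=True)
class PolymorphTarget:
    """Experimental targets for one polymorph."""

    name: str
    e_latt_exp: float
    cell_exp: tuple  # (a, b, c, alpha, beta, gamma)

    def __post_init__(self):
        if len(self.cell_exp) != 6:
            raise ValueError("cell_exp must have six components")


@dataclass
class PolymorphStructure:
    """Starting structure + replication + symmetry family for one polymorph."""

    name: str
    cell: UnitCell
    replication: tuple[int, int, int] = (1, 1, 1)
    constraint: SymmetryConstraint = field(default_factory=SymmetryConstraint)


@dataclass
class ObjectiveVector:
    """The six-component objective f = (f_elatt^α,β,γ, f_cell^α,β,γ).

    ``raw`` keeps the per-polymorph predictions (lattice energy and cell
    parameters) so the ordering constraint and audit trails can be built
    without re-relaxing.
    """

    values: np.ndarray
    feasible: bool
    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("objective values must form a non-empty vector")

    @property
    def max_objective(self) -> float:
        return float(self.values.max())


def rms_fractional_error(y, y_exp) -> float:
    """sqrt((1/d) Σ ((y_i − y_exp_i)/y_exp_i)²) — scale-free by construction."""
    y = np.asarray(y, dtype=float)
    y_exp = np.asarray(y_exp, dtype=float)
    if y.shape != y_exp.shape:
        raise ValueError("shape mismatch")
    if np.any(y_exp == 0.0):
        raise ValueError("zero reference entry in fractional error")
    frac = (y - y_exp) / y_exp
    return float(np.sqrt((frac**2).mean()))


def lattice_objective(e: float, e_exp: float) -> float:
    """Absolute fractional error in the lattice energy."""
    if e_exp == 0.0:
        raise ValueError("zero reference lattice energy")
    return abs((e - e_exp) / e_exp)


def cell_objective(cell, cell_exp) -> float:
    """RMS fractional error over (a, b, c, α, β, γ), d = 6.

    Constrained angles are kept in the average (contributing zero when
    preserved exactly), matching the printed definition of the objective.
    """
    cell = np.asarray(cell, dtype=float)
    cell_exp = np.asarray(cell_exp, dtype=float)
    if cell.shape != (6,) or cell_exp.shape != (6,):
        raise ValueError("cells must be 6-vectors")
    return rms_fractional_error(cell, cell_exp)


def ordering_constraint(e_alpha: float, e_beta: float, e_gamma: float) -> bool:
    """True iff stability order is γ ≥ α ≥ β (E_γ ≤ E_α ≤ E_β, ties allowed)."""
    for e in (e_alpha, e_beta, e_gamma):
        if not np.isfinite(e):
            return False
    return (
        e_gamma <= e_alpha + ORDERING_TIE_TOL
        and e_alpha <= e_beta + ORDERING_TIE_TOL
    )


def evaluate_objectives(
    pvec: ParameterVector,
    structures: list[PolymorphStructure],
    targets: list[PolymorphTarget],
    relax_settings: RelaxSettings | None = None,
    x: np.ndarray | None = None,
) -> ObjectiveVector:
    """Relax all polymorphs under parameters x and score the six objectives.

    Polymorphs are matched to targets by name, so input order is
    irrelevant.  A failed relaxation marks the whole vector with the
    sentinel value and ``feasible=False`` instead of raising, so
    optimization loops survive unstable parameter regions.
    """
    ff = apply_parameters(pvec, x)
    by_name = {t.name: t for t in targets}
    if set(s.name for s in structures) != set(by_name):
        raise ValueError("structure/target name mismatch")
    order = sorted(by_name)  # alpha, beta, gamma labels sort naturally
    e_latt_obj, cell_obj, raw = {}, {}, {}
    energies = {}
    for s in structures:
        tgt = by_name[s.name]
        try:
            sc = build_supercell(s.cell, s.replication)
            res = full_relaxation(sc, ff, s.constraint, relax_settings)
            (a, b, c), (al, be, ga) = res.structure.cell_parameters
            e_latt = lattice_energy(res.energy, res.structure.n_molecules)
            e_latt_obj[s.name] = lattice_objective(e_latt, tgt.e_latt_exp)
            cell_obj[s.name] = cell_objective(
                (a, b, c, al, be, ga), tgt.cell_exp
            )
            energies[s.name] = e_latt
            raw[s.name] = {
                "e_latt": e_latt,
                "cell": (a, b, c, al, be, ga),
                "converged": res.converged,
            }
        except Exception as exc:  # unstable region: sentinel, stay alive
            e_latt_obj[s.name] = FAILED_OBJECTIVE
            cell_obj[s.name] = FAILED_OBJECTIVE
            energies[s.name] = np.nan
            raw[s.name] = {"error": str(exc)}
    values = np.array(
        [e_latt_obj[n] for n in order] + [cell_obj[n] for n in order]
    )
    feasible = ordering_constraint(
        energies[order[0]], energies[order[1]], energies[order[2]]
    )
    raw["energies"] = [energies[n] for n in order]
    return ObjectiveVector(values=values, feasible=feasible, raw=raw)
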