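"""Structure relaxation for rigid-molecule crystals.

The full relaxation mirrors a three-step protocol: (1) relax positions at
fixed cell, (2) relax the free cell lengths under the symmetry constraint
(with an inner position relaxation each sweep), (3) a final position
relaxation at the fixed optimal cell.  All steps are deterministic 0 K
minimizations — there is no stochastic dynamics anywhere in this module —
so a given (structure, force field, settings) always yields the same
result.

Molecules are treated as rigid bodies: positions are minimized over
molecular translations (and, optionally, rotations), and cell scaling moves
molecular centers affinely while keeping intramolecular geometry fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .crystal import (
    Supercell,
    SymmetryConstraint,
    canonicalize_box,
    parameters_from_cell_matrix,
)
from .energy import EwaldSettings, NonbondedKernel
from .forcefield import ForceField

__all__ = [
    "RelaxResult",
    "RelaxSettings",
    "minimize_positions",
    "relax_cell",
    "full_relaxation",
    "EnergyDivergenceError",
    "CellCollapseError",
]

#: 0.1 kJ mol^-1 nm^-1 expressed in internal units (kJ mol^-1 Å^-1)
DEFAULT_FORCE_TOL = 0.01


class EnergyDivergenceError(RuntimeError):
    pass


class CellCollapseError(RuntimeError):
    pass


@dataclass
class RelaxSettings:
    """Knobs for the relaxation loops.

    ``force_tol`` is the maximum allowed force component on any rigid body,
    in kJ mol⁻¹ Å⁻¹ (default equals 0.1 kJ mol⁻¹ nm⁻¹).  ``cell_tol`` is
    the energy decrease (kJ mol⁻¹) below which the outer cell loop stops.
    """

    force_tol: float = DEFAULT_FORCE_TOL
    max_steps: int = 2000
    cell_tol: float = 1e-6
    max_cell_cycles: int = 12
    line_search_span: tuple[float, float] = (0.8, 1.3)
    line_search_xatol: float = 1e-4
    line_search_maxiter: int = 30
    rotations: bool = False
    initial_step: float = 0.02
    lj_cutoff: float = 9.0
    tail_correction: bool = True
    ewald: EwaldSettings | None = None


@dataclass
class RelaxResult:
    structure: Supercell
    energy: float
    max_force: float
    n_steps: int
    cell_trajectory: list = field(default_factory=list)
    converged: bool = False

    @property
    def cell_parameters(self):
        return self.structure.cell_parameters


class _RigidSystem:
    """Rigid-body view of a supercell bound to an energy kernel."""

    def __init__(self, supercell: Supercell, ff: ForceField, settings: RelaxSettings):
        self.sc = supercell.copy()
        self.settings = settings
        self.kernel = NonbondedKernel(
            self.sc, ff,
            settings=settings.ewald or EwaldSettings.auto(self.sc.cell_matrix),
            lj_cutoff=settings.lj_cutoff,
            tail_correction=settings.tail_correction,
        )
        mol = self.sc.molecule_map
        self.groups = [np.where(mol == m)[0] for m in range(self.sc.n_molecules)]
        self.cell = self.sc.cell_matrix.copy()
        self.pos = self.sc.cart_pos.copy()

    # centers are geometric (no masses carried by sites)
    def centers(self) -> np.ndarray:
        return np.array([self.pos[g].mean(axis=0) for g in self.groups])

    def energy(self) -> float:
        return self.kernel.energy(self.pos, self.cell).total

    def forces(self):
        br, f_site = self.kernel.forces(self.pos, self.cell)
        f_mol = np.array([f_site[g].sum(axis=0) for g in self.groups])
        torques = None
        if self.settings.rotations:
            cen = self.centers()
            torques = np.array([
                np.cross(self.pos[g] - cen[i], f_site[g]).sum(axis=0)
                for i, g in enumerate(self.groups)
            ])
        return br.total, f_mol, torques

    def translate(self, disp: np.ndarray) -> None:
        for i, g in enumerate(self.groups):
            self.pos[g] += disp[i]

    def rotate(self, axis_angle: np.ndarray) -> None:
        from scipy.spatial.transform import Rotation

        cen = self.centers()
        for i, g in enumerate(self.groups):
            theta = np.linalg.norm(axis_angle[i])
            if theta < 1e-14:
                continue
            rot = Rotation.from_rotvec(axis_angle[i])
            self.pos[g] = cen[i] + rot.apply(self.pos[g] - cen[i])

    def set_cell_row_scale(self, row: int, scale: float) -> None:
        """Scale one lattice vector, moving molecular centers affinely."""
        cen = self.centers()
        frac = cen @ np.linalg.inv(self.cell)
        new_cell = self.cell.copy()
        new_cell[row] *= scale
        new_cen = frac @ new_cell
        for i, g in enumerate(self.groups):
            self.pos[g] += new_cen[i] - cen[i]
        self.cell = new_cell

    def snapshot(self) -> Supercell:
        out = self.sc.copy()
        out.cell_matrix = self.cell.copy()
        out.cart_pos = self.pos.copy()
        return out

    def diagnose_overlap(self) -> str:
        d = self.pos[None, :, :] - self.pos[:, None, :]
        r = np.sqrt((d**2).sum(axis=-1))
        np.fill_diagonal(r, np.inf)
        i, j = np.unravel_index(np.argmin(r), r.shape)
        return f"closest pair ({i}, {j}) at {r[i, j]:.4f} Å"


def _steepest_descent(system: _RigidSystem, settings: RelaxSettings):
    """Adaptive-step steepest descent over rigid-body coordinates."""
    e, f_mol, torques = system.forces()
    if not math.isfinite(e):
        raise EnergyDivergenceError(
            f"non-finite starting energy; {system.diagnose_overlap()}"
        )
    step = settings.initial_step
    n_steps = 0
    max_f = _max_component(f_mol, torques)
    while max_f > settings.force_tol and n_steps < settings.max_steps:
        scale = step / max(max_f, 1e-300)
        pos_backup = system.pos.copy()
        system.translate(f_mol * scale)
        if torques is not None:
            system.rotate(torques * scale)
        e_new = system.energy()
        n_steps += 1
        if math.isfinite(e_new) and e_new < e:
            e = e_new
            step = min(step * 1.2, 0.2)
            _, f_mol, torques = system.forces()
            max_f = _max_component(f_mol, torques)
        else:
            system.pos = pos_backup
            step *= 0.5
            if step < 1e-10:
                break
    converged = max_f <= settings.force_tol
    return e, max_f, n_steps, converged


def _max_component(f_mol, torques) -> float:
    m = float(np.abs(f_mol).max()) if f_mol.size else 0.0
    if torques is not None and torques.size:
        m = max(m, float(np.abs(torques).max()))
    return m


def minimize_positions(supercell: Supercell, ff: ForceField,
                       settings: RelaxSettings | None = None) -> RelaxResult:
    """Relax rigid-body positions at fixed cell to the force tolerance."""
    settings = settings or RelaxSettings()
    system = _RigidSystem(supercell, ff, settings)
    e, max_f, n_steps, converged = _steepest_descent(system, settings)
    return RelaxResult(
        structure=system.snapshot(),
        energy=e,
        max_force=max_f,
        n_steps=n_steps,
        cell_trajectory=[parameters_from_cell_matrix(system.cell)],
        converged=converged,
    )


def relax_cell(supercell: Supercell, ff: ForceField,
               constraint: SymmetryConstraint | None = None,
               settings: RelaxSettings | None = None) -> RelaxResult:
    """Symmetry-constrained relaxation of the free cell lengths.

    Outer loop: line search on each free lattice-vector length with
    molecular fractional centers held fixed, then an inner rigid-body
    position relaxation; repeat until the energy gain per cycle drops below
    ``cell_tol``.  Fixed angles are preserved bit-identically because only
    row scalings are applied.
    """
    settings = settings or RelaxSettings()
    constraint = constraint or SymmetryConstraint()
    lengths, angles = supercell.cell_parameters
    constraint.check(angles)
    system = _RigidSystem(supercell, ff, settings)
    vol0 = abs(np.linalg.det(system.cell))
    e = system.energy()
    total_steps = 0
    trajectory = [parameters_from_cell_matrix(system.cell)]
    converged = False
    lo, hi = settings.line_search_span
    for _cycle in range(settings.max_cell_cycles):
        e_start = e
        for row in range(3):
            if not constraint.free_lengths[row]:
                continue

            def obj(scale: float, row=row) -> float:
                pos_backup = system.pos.copy()
                cell_backup = system.cell.copy()
                system.set_cell_row_scale(row, scale)
                val = system.energy()
                system.pos = pos_backup
                system.cell = cell_backup
                return val if math.isfinite(val) else 1e30

            res = minimize_scalar(
                obj, bounds=(lo, hi), method="bounded",
                options={
                    "xatol": settings.line_search_xatol,
                    "maxiter": settings.line_search_maxiter,
                },
            )
            if res.fun < e:
                system.set_cell_row_scale(row, float(res.x))
                e = float(res.fun)
            total_steps += int(res.nfev)
        e, max_f, n_steps, _ = _steepest_descent(system, settings)
        total_steps += n_steps
        trajectory.append(parameters_from_cell_matrix(system.cell))
        vol = abs(np.linalg.det(system.cell))
        if vol < 0.25 * vol0:
            raise CellCollapseError(
                f"cell volume collapsed to {vol / vol0:.2%} of the start"
            )
        if e_start - e < settings.cell_tol:
            converged = True
            break
    _, f_mol, torques = system.forces()
    return RelaxResult(
        structure=system.snapshot(),
        energy=e,
        max_force=_max_component(f_mol, torques),
        n_steps=total_steps,
        cell_trajectory=trajectory,
        converged=converged,
    )


def full_relaxation(supercell: Supercell, ff: ForceField,
                    constraint: SymmetryConstraint | None = None,
                    settings: RelaxSettings | None = None) -> RelaxResult:
    """Positions → constrained cell → positions, with canonical reporting.

    The returned structure carries the skew-reduced (canonical) cell so the
    reported cell parameters are representation-independent.
    """
    settings = settings or RelaxSettings()
    first = minimize_positions(supercell, ff, settings)
    cellr = relax_cell(first.structure, ff, constraint, settings)
    final = minimize_positions(cellr.structure, ff, settings)
    cell, pos = canonicalize_box(final.structure.cell_matrix, final.structure.cart_pos)
    out = final.structure.copy()
    out.cell_matrix = cell
    out.cart_pos = pos
    return RelaxResult(
        structure=out,
        energy=final.energy,
        max_force=final.max_force,
        n_steps=first.n_steps + cellr.n_steps + final.n_steps,
        cell_trajectory=cellr.cell_trajectory,
        converged=first.converged and cellr.converged and final.converged,
    )
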