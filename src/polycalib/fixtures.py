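"""Deterministic generators for test structures and signals.

Everything the test suite needs is generated here at run time: ionic
reference lattices with known Madelung energies, Lennard-Jones crystals,
toy rigid dipolar molecular crystals, a three-polymorph calibration
problem with known ground-truth parameters, and Brownian trajectories
with known diffusion constants.  Same arguments + seed ⇒ bitwise-identical
fixture.

The calibration triple is a synthetic stand-in for a real polymorph
data set: three small crystals of a four-site rigid dipolar molecule in
three symmetry families, whose "experimental" targets are the model's own
relaxed properties at a chosen ground-truth parameter vector — so the
calibration loop has a known recoverable answer and the ordering
constraint is satisfiable by construction.
"""

from __future__ import annotations

import numpy as np

from .crystal import (
    MONOCLINIC,
    ORTHORHOMBIC,
    TRIGONAL,
    AtomSite,
    UnitCell,
    build_supercell,
)
from .forcefield import ForceField, LJType, ParameterVector, make_bounds
from .objectives import PolymorphStructure, PolymorphTarget
from .properties import TrajectorySet, lattice_energy
from .relax import RelaxSettings, full_relaxation

__all__ = [
    "make_rocksalt",
    "rocksalt_forcefield",
    "make_lj_fcc",
    "lj_forcefield",
    "make_dipolar_crystal",
    "dipolar_forcefield",
    "make_calibration_triple",
    "calibration_relax_settings",
    "make_brownian",
]


# ------------------------------------------------------------- rock salt
def make_rocksalt(spacing: float = 2.82, q: float = 1.0) -> UnitCell:
    """Conventional cubic rock-salt cell: 4 cation/anion pairs, ±q charges.

    ``spacing`` is the nearest-neighbor cation–anion distance d; the cubic
    cell edge is 2d.  LJ parameters are zero, so the Ewald energy per ion
    pair is exactly −M·C·q²/d with M the rock-salt Madelung constant.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    a = 2.0 * spacing
    cation = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    anion = [(0.5, 0, 0), (0, 0.5, 0), (0, 0, 0.5), (0.5, 0.5, 0.5)]
    sites = []
    for i, f in enumerate(cation):
        sites.append(AtomSite(f"Na{i}", "Na", "Na", f, q, molecule_id=i))
    for i, f in enumerate(anion):
        sites.append(AtomSite(f"Cl{i}", "Cl", "Cl", f, -q, molecule_id=4 + i))
    return UnitCell((a, a, a), (90.0, 90.0, 90.0), tuple(sites), formula_units=4)


def rocksalt_forcefield() -> ForceField:
    return ForceField({"Na": LJType("Na", 0.0, 0.0), "Cl": LJType("Cl", 0.0, 0.0)})


# ------------------------------------------------------------ LJ crystal
def make_lj_fcc(spacing: float, sigma: float = 3.4) -> UnitCell:
    """Face-centered-cubic LJ crystal; ``spacing`` is the cubic cell edge."""
    fracs = [(0, 0, 0), (0.5, 0.5, 0), (0.5, 0, 0.5), (0, 0.5, 0.5)]
    sites = tuple(
        AtomSite(f"X{i}", "X", "X", f, 0.0, molecule_id=i)
        for i, f in enumerate(fracs)
    )
    return UnitCell((spacing,) * 3, (90.0,) * 3, sites, formula_units=4)


def lj_forcefield(sigma: float = 3.4, epsilon: float = 1.0) -> ForceField:
    return ForceField({"X": LJType("X", sigma, epsilon)})


# ----------------------------------------------------- dipolar molecular
_DIPOLE_OFFSETS = np.array([[0.0, 0.0, -0.6], [0.0, 0.0, 0.6]])


def make_dipolar_crystal(spacing: float = 4.5, q: float = 0.3,
                         antiparallel: bool = True) -> UnitCell:
    """Two rigid two-site dipoles per cubic cell (Z = 2).

    With ``antiparallel`` the second molecule is flipped, giving a
    zero-dipole cell; otherwise the cell carries a net dipole (exercises
    the tinfoil convention).
    """
    sites = []
    a = spacing
    for m, (center, flip) in enumerate(
        [((0.25, 0.25, 0.25), 1.0), ((0.75, 0.75, 0.75), -1.0 if antiparallel else 1.0)]
    ):
        for k, off in enumerate(_DIPOLE_OFFSETS):
            frac = np.array(center) + flip * off / a
            charge = q if k == 0 else -q
            sites.append(
                AtomSite(f"D{m}{k}", "X", "D", tuple(frac), charge, molecule_id=m)
            )
    return UnitCell((a, a, a), (90.0,) * 3, tuple(sites), formula_units=2)


def dipolar_forcefield(sigma: float = 3.0, epsilon: float = 0.8) -> ForceField:
    return ForceField({"D": LJType("D", sigma, epsilon)})


# ------------------------------------------------------ calibration triple
#: rigid four-site molecular geometry (Å offsets from the molecular origin)
_TOY_GEOMETRY = np.array([
    [0.00, 0.00, 0.00],
    [1.30, 0.00, 0.00],
    [-0.75, 1.05, 0.00],
    [-0.75, -1.05, 0.00],
])
_TOY_TYPES = ("A", "B", "Cc", "Hx")
_TOY_CHARGES = (0.38, -0.38, 0.22, -0.22)
_TOY_ELEMENTS = ("N", "O", "C", "H")


def toy_base_forcefield() -> ForceField:
    """Ground-truth force field x* for the calibration problem."""
    return ForceField({
        "A": LJType("A", 3.30, 0.55),
        "B": LJType("B", 2.95, 0.70),
        "Cc": LJType("Cc", 3.60, 0.40),
        "Hx": LJType("Hx", 0.0, 0.0),
    })


def _toy_cell(lengths, angles, rotation_deg: float) -> UnitCell:
    """One toy molecule per cell, rotated about z by ``rotation_deg``."""
    th = np.radians(rotation_deg)
    rot = np.array([
        [np.cos(th), -np.sin(th), 0.0],
        [np.sin(th), np.cos(th), 0.0],
        [0.0, 0.0, 1.0],
    ])
    geom = _TOY_GEOMETRY @ rot.T
    cell0 = UnitCell(lengths, angles, (), formula_units=1)
    inv = np.linalg.inv(cell0.cell_matrix)
    center = np.array([0.5, 0.5, 0.5]) @ cell0.cell_matrix
    sites = tuple(
        AtomSite(f"T{i}", _TOY_ELEMENTS[i], _TOY_TYPES[i],
                 tuple((center + geom[i]) @ inv), _TOY_CHARGES[i], molecule_id=0)
        for i in range(4)
    )
    return UnitCell(lengths, angles, sites, formula_units=1)


def calibration_relax_settings() -> RelaxSettings:
    """Relaxation settings used both to build targets and to score candidates."""
    return RelaxSettings(
        force_tol=0.05,
        max_steps=400,
        cell_tol=1e-5,
        max_cell_cycles=8,
        line_search_xatol=5e-4,
        line_search_maxiter=25,
        lj_cutoff=9.0,
        tail_correction=True,
    )


def make_calibration_triple(seed: int = 0):
    """Three-polymorph calibration problem with a recoverable ground truth.

    Returns (structures, targets, parameter_vector) where the parameter
    vector's values are the ground truth x*.  Targets are the relaxed
    lattice energies and canonical cells under x*, with polymorph labels
    assigned so the stability ordering γ ≤ α ≤ β holds by construction.
    """
    del seed  # the construction is fully deterministic; kept for API symmetry
    base = toy_base_forcefield()
    candidates = [
        ((5.1, 4.2, 3.8), (90.0, 90.0, 90.0), 0.0, ORTHORHOMBIC),
        ((5.5, 3.8, 3.8), (90.0, 103.0, 90.0), 25.0, MONOCLINIC),
        ((5.8, 4.0, 3.8), (90.0, 90.0, 120.0), 50.0, TRIGONAL),
    ]
    settings = calibration_relax_settings()
    relaxed = []
    for lengths, angles, rot, constraint in candidates:
        cell = _toy_cell(lengths, angles, rot)
        sc = build_supercell(cell, (1, 1, 1))
        res = full_relaxation(sc, base, constraint, settings)
        (a, b, c), (al, be, ga) = res.structure.cell_parameters
        e_latt = lattice_energy(res.energy, res.structure.n_molecules)
        relaxed.append((cell, constraint, e_latt, (a, b, c, al, be, ga)))
    # label by stability: most stable -> gamma, then alpha, then beta
    order = np.argsort([r[2] for r in relaxed])  # ascending energy
    names_by_rank = ("gamma", "alpha", "beta")
    structures, targets = [], []
    for rank, idx in enumerate(order):
        cell, constraint, e_latt, cell6 = relaxed[idx]
        name = names_by_rank[rank]
        structures.append(PolymorphStructure(name, cell, (1, 1, 1), constraint))
        targets.append(PolymorphTarget(name, e_latt, cell6))
    structures.sort(key=lambda s: s.name)
    targets.sort(key=lambda t: t.name)
    pvec = make_bounds(base, ["A", "B", "Cc", "Hx"])
    return structures, targets, pvec


# --------------------------------------------------------------- Brownian
def make_brownian(n_molecules: int = 500, n_steps: int = 10_000,
                  dt: float = 1.0, d_true: float = 1.0,
                  seed: int = 0) -> TrajectorySet:
    """Independent Brownian center-of-mass trajectories.

    ``d_true`` is the diffusion coefficient in 10⁻⁹ m² s⁻¹ (0.1 Å²/ps);
    each Cartesian increment has variance 2·D·dt.  Positions are unwrapped.
    """
    if n_molecules < 1 or n_steps < 1 or dt <= 0 or d_true < 0:
        raise ValueError("invalid Brownian generator arguments")
    rng = np.random.default_rng(seed)
    d_internal = 0.1 * d_true  # Å²/ps
    std = np.sqrt(2.0 * d_internal * dt)
    steps = rng.standard_normal((n_steps, n_molecules, 3)) * std
    pos = np.concatenate([
        np.zeros((1, n_molecules, 3)), np.cumsum(steps, axis=0)
    ])
    times = np.arange(n_steps + 1) * dt
    return TrajectorySet(times, pos)
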