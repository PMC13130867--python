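"""Crystal data model: unit cells, supercells, and triclinic-box conventions.

The cell matrix convention throughout is *lower-triangular row vectors*:
the first lattice vector lies along x, the second in the xy plane.  This is
the triclinic-box convention of mainstream molecular-dynamics engines and
makes box skew/unskew operations well defined.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AtomSite",
    "UnitCell",
    "Supercell",
    "SymmetryConstraint",
    "InvalidCellError",
    "cell_matrix_from_parameters",
    "parameters_from_cell_matrix",
    "cell_volume",
    "build_supercell",
    "canonicalize_box",
    "minimum_image_distance",
    "MONOCLINIC",
    "TRIGONAL",
    "ORTHORHOMBIC",
]


class InvalidCellError(ValueError):
    """Raised for degenerate or non-positive-volume cell parameters."""


@dataclass(frozen=True)
class AtomSite:
    """One crystallographic site: identity, fractional position and charge.

    ``molecule_id`` groups sites into (rigid) molecules; ``atom_type`` is the
    key into a force field's Lennard-Jones table.  Charges are in units of
    the elementary charge.
    """

    label: str
    element: str
    atom_type: str
    frac_pos: tuple[float, float, float]
    charge: float = 0.0
    molecule_id: int = 0

    def __post_init__(self):
        if not all(math.isfinite(x) for x in self.frac_pos):
            raise ValueError(f"non-finite fractional position for site {self.label}")
        if self.molecule_id < 0:
            raise ValueError("molecule_id must be non-negative")


@dataclass(frozen=True)
class UnitCell:
    """A unit cell: lengths (Å), angles (degrees), sites and Z.

    Fractional coordinates are wrapped into [0, 1) on construction.
    """

    lengths: tuple[float, float, float]
    angles: tuple[float, float, float]
    sites: tuple[AtomSite, ...]
    formula_units: int = 1

    def __post_init__(self):
        if any(l <= 0 for l in self.lengths):
            raise InvalidCellError(f"cell lengths must be positive: {self.lengths}")
        if any(not 0.0 < a < 180.0 for a in self.angles):
            raise InvalidCellError(f"cell angles must lie in (0, 180): {self.angles}")
        if self.formula_units < 1:
            raise InvalidCellError("formula_units (Z) must be >= 1")
        wrapped = tuple(
            replace(s, frac_pos=tuple(float(x) % 1.0 for x in s.frac_pos))
            for s in self.sites
        )
        object.__setattr__(self, "sites", wrapped)
        # side effect: validates the angle combination
        cell_matrix_from_parameters(self.lengths, self.angles)

    @property
    def cell_matrix(self) -> np.ndarray:
        return cell_matrix_from_parameters(self.lengths, self.angles)

    @property
    def volume(self) -> float:
        return cell_volume(self.lengths, self.angles)

    @property
    def n_molecules(self) -> int:
        return len({s.molecule_id for s in self.sites})

    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac_pos for s in self.sites], dtype=float).reshape(-1, 3)


@dataclass
class SymmetryConstraint:
    """Which cell angles are pinned and which lengths may relax.

    Angles listed in ``fixed_angles`` are preserved *exactly* (bit-identical)
    through any cell relaxation; angles not listed are simply never varied
    (this package relaxes lengths only).
    """

    fixed_angles: dict[str, float] = field(default_factory=dict)
    free_lengths: tuple[bool, bool, bool] = (True, True, True)

    def check(self, angles: tuple[float, float, float], tol: float = 1e-6) -> None:
        names = ("alpha", "beta", "gamma")
        for name, value in self.fixed_angles.items():
            got = angles[names.index(name)]
            if abs(got - value) > tol:
                raise InvalidCellError(
                    f"angle {name}={got} violates fixed value {value}"
                )


MONOCLINIC = SymmetryConstraint(fixed_angles={"alpha": 90.0, "gamma": 90.0})
TRIGONAL = SymmetryConstraint(fixed_angles={"alpha": 90.0, "beta": 90.0, "gamma": 120.0})
ORTHORHOMBIC = SymmetryConstraint(
    fixed_angles={"alpha": 90.0, "beta": 90.0, "gamma": 90.0}
)


def cell_matrix_from_parameters(lengths, angles) -> np.ndarray:
    """Lower-triangular row-vector cell matrix from (a, b, c, α, β, γ).

    Rows are the lattice vectors in Å; a lies along x, b in the xy plane.
    Raises :class:`InvalidCellError` for degenerate angle combinations.
    """
    a, b, c = (float(x) for x in lengths)
    al, be, ga = (math.radians(float(x)) for x in angles)
    cos_al, cos_be, cos_ga = math.cos(al), math.cos(be), math.cos(ga)
    sin_ga = math.sin(ga)
    bx, by = b * cos_ga, b * sin_ga
    cx = c * cos_be
    cy = c * (cos_al - cos_be * cos_ga) / sin_ga
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0.0:
        raise InvalidCellError(
            f"degenerate cell: angles {angles} give non-positive volume"
        )
    cz = math.sqrt(cz_sq)
    return np.array([[a, 0.0, 0.0], [bx, by, 0.0], [cx, cy, cz]])


def parameters_from_cell_matrix(m: np.ndarray):
    """(lengths, angles) in Å/degrees from a row-vector cell matrix."""
    m = np.asarray(m, dtype=float)
    lengths = np.linalg.norm(m, axis=1)

    def ang(i, j):
        cosv = float(m[i] @ m[j] / (lengths[i] * lengths[j]))
        return math.degrees(math.acos(max(-1.0, min(1.0, cosv))))

    angles = (ang(1, 2), ang(0, 2), ang(0, 1))
    return tuple(float(x) for x in lengths), angles


def cell_volume(lengths, angles) -> float:
    a, b, c = lengths
    cos_al, cos_be, cos_ga = (math.cos(math.radians(x)) for x in angles)
    arg = (
        1.0
        - cos_al**2
        - cos_be**2
        - cos_ga**2
        + 2.0 * cos_al * cos_be * cos_ga
    )
    if arg <= 0.0:
        raise InvalidCellError(f"degenerate cell: angles {angles}")
    return a * b * c * math.sqrt(arg)


@dataclass
class Supercell:
    """Cartesian replication of a unit cell.

    ``cart_pos`` holds site positions in Å with molecules kept whole: each
    molecule is unwrapped about its first site before Cartesian conversion,
    so intramolecular displacements never straddle a periodic boundary.
    """

    cell_matrix: np.ndarray
    cart_pos: np.ndarray
    sites: tuple[AtomSite, ...]
    molecule_map: np.ndarray
    replication: tuple[int, int, int]
    formula_units: int

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_map.max()) + 1 if len(self.sites) else 0

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.cell_matrix)))

    @property
    def cell_parameters(self):
        return parameters_from_cell_matrix(self.cell_matrix)

    def frac_coords(self, wrap: bool = True) -> np.ndarray:
        frac = self.cart_pos @ np.linalg.inv(self.cell_matrix)
        return frac % 1.0 if wrap else frac

    def copy(self) -> "Supercell":
        return Supercell(
            self.cell_matrix.copy(),
            self.cart_pos.copy(),
            self.sites,
            self.molecule_map.copy(),
            self.replication,
            self.formula_units,
        )


def _unwrap_molecules(frac: np.ndarray, mol_ids: np.ndarray) -> np.ndarray:
    """Shift fractional coords so each molecule is contiguous (whole)."""
    out = frac.copy()
    for mol in np.unique(mol_ids):
        idx = np.where(mol_ids == mol)[0]
        ref = out[idx[0]]
        delta = out[idx] - ref
        out[idx] = ref + delta - np.round(delta)
    return out


def build_supercell(cell: UnitCell, replication=(1, 1, 1)) -> Supercell:
    """Replicate a unit cell n_a × n_b × n_c into a Cartesian supercell.

    Site ordering is cell-image-major (image (0,0,0) first, images in
    C-order), preserving within-cell site order, so molecule indexing is
    deterministic.
    """
    na, nb, nc = (int(n) for n in replication)
    if min(na, nb, nc) < 1:
        raise ValueError("replication components must be >= 1")
    m_unit = cell.cell_matrix
    frac = _unwrap_molecules(cell.frac_coords(), np.array([s.molecule_id for s in cell.sites]))
    mol_ids = np.array([s.molecule_id for s in cell.sites], dtype=int)
    n_mols_cell = len(np.unique(mol_ids))
    # remap molecule ids within the cell to 0..n_mols-1 preserving order
    order = {m: i for i, m in enumerate(dict.fromkeys(mol_ids.tolist()))}
    mol_local = np.array([order[m] for m in mol_ids], dtype=int)

    images = list(itertools.product(range(na), range(nb), range(nc)))
    cart_blocks, map_blocks, site_blocks = [], [], []
    for k, (ia, ib, ic) in enumerate(images):
        shift = np.array([ia, ib, ic], dtype=float)
        cart_blocks.append((frac + shift) @ m_unit)
        map_blocks.append(mol_local + k * n_mols_cell)
        site_blocks.extend(cell.sites)
    cell_matrix = m_unit * np.array([[na], [nb], [nc]], dtype=float)
    return Supercell(
        cell_matrix=cell_matrix,
        cart_pos=np.vstack(cart_blocks),
        sites=tuple(site_blocks),
        molecule_map=np.concatenate(map_blocks),
        replication=(na, nb, nc),
        formula_units=cell.formula_units,
    )


def canonicalize_box(cell_matrix: np.ndarray, cart_pos: np.ndarray):
    """Reduce a lattice basis to the canonical skew-free representation.

    Returns an equivalent basis (same lattice, same fractional site set,
    rotated to lower-triangular with a along x) in which every off-diagonal
    element satisfies ``|m_ij| <= m_jj / 2``.  Cell parameters derived from
    the output are the canonical ones.  Volume is preserved exactly and the
    operation is idempotent.
    """
    m = np.asarray(cell_matrix, dtype=float)
    if abs(np.linalg.det(m)) < 1e-12:
        raise InvalidCellError("singular cell matrix")
    frac = np.asarray(cart_pos, dtype=float).reshape(-1, 3) @ np.linalg.inv(m)
    # rotate into the lower-triangular representation via the Gram matrix
    gram = m @ m.T
    low = np.linalg.cholesky(gram)
    # integer basis reduction: subtract integer multiples of earlier rows
    for _ in range(64):
        changed = False
        for i, j in ((1, 0), (2, 1), (2, 0)):
            k = round(low[i, j] / low[j, j])
            if k != 0:
                low[i] -= k * low[j]
                frac[:, j] += k * frac[:, i]
                changed = True
        if not changed:
            break
    # positions are transformed exactly (a pure rotation in Cartesian space);
    # they are deliberately not wrapped so molecules stay whole
    return low, frac @ low


def minimum_image_distance(supercell: Supercell, i: int, j: int) -> float:
    """Shortest periodic distance (Å) between sites i and j.

    Exact for separations below half the minimum perpendicular cell width;
    searches image shifts in {-2..2}^3 so moderately skewed cells are safe.
    """
    m = supercell.cell_matrix
    d_frac = supercell.frac_coords()[j] - supercell.frac_coords()[i]
    d_frac -= np.round(d_frac)
    shifts = np.array(list(itertools.product((-2, -1, 0, 1, 2), repeat=3)), dtype=float)
    cand = (d_frac + shifts) @ m
    return float(np.sqrt((cand**2).sum(axis=1)).min())


def perpendicular_widths(cell_matrix: np.ndarray) -> np.ndarray:
    """Perpendicular width of the cell along each lattice direction (Å)."""
    m = np.asarray(cell_matrix, dtype=float)
    vol = abs(np.linalg.det(m))
    widths = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        widths.append(vol / np.linalg.norm(np.cross(m[j], m[k])))
    return np.array(widths)
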