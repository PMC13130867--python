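"""Force-field containers: Lennard-Jones types, combining rules and the
bounded parameter vector used for calibration.

Units: sigma in Å, epsilon in kJ mol⁻¹, charges in elementary charges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LJType",
    "ForceField",
    "ParameterVector",
    "combine_lj",
    "make_bounds",
    "apply_parameters",
    "extract_parameters",
    "BoundsViolationError",
]


class BoundsViolationError(ValueError):
    pass


@dataclass(frozen=True)
class LJType:
    atom_type: str
    sigma: float
    epsilon: float

    def __post_init__(self):
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError(f"negative LJ parameter for {self.atom_type}")


@dataclass(frozen=True)
class ForceField:
    """LJ parameters per atom type plus global nonbonded conventions.

    ``exclusion_policy``:

    * ``"rigid-molecule"`` — all intramolecular nonbonded pairs excluded and
      molecules treated as rigid bodies (the default; the single-molecule
      vacuum energy is then zero by construction).
    * ``"bonded-graph"`` — 1-2/1-3 pairs excluded, 1-4 pairs scaled by
      ``scale14_lj`` / ``scale14_coulomb``; requires a bond list on the
      energy kernel.
    """

    lj_types: dict[str, LJType] = field(default_factory=dict)
    combining_rule: str = "geometric"
    exclusion_policy: str = "rigid-molecule"
    scale14_lj: float = 0.5
    scale14_coulomb: float = 0.5

    def __post_init__(self):
        if self.combining_rule not in ("geometric", "lorentz-berthelot"):
            raise ValueError(f"unknown combining rule {self.combining_rule!r}")
        if self.exclusion_policy not in ("rigid-molecule", "bonded-graph"):
            raise ValueError(f"unknown exclusion policy {self.exclusion_policy!r}")
        for s in (self.scale14_lj, self.scale14_coulomb):
            if not 0.0 <= s <= 1.0:
                raise ValueError("1-4 scale factors must lie in [0, 1]")

    def lj(self, atom_type: str) -> LJType:
        try:
            return self.lj_types[atom_type]
        except KeyError:
            raise KeyError(f"atom type {atom_type!r} not in force field") from None

    def with_types(self, new_types: dict[str, LJType]) -> "ForceField":
        merged = dict(self.lj_types)
        merged.update(new_types)
        return ForceField(
            merged,
            self.combining_rule,
            self.exclusion_policy,
            self.scale14_lj,
            self.scale14_coulomb,
        )


def combine_lj(type_i: LJType, type_j: LJType, rule: str = "geometric"):
    """Cross-interaction (σ_ij, ε_ij) under the given combining rule."""
    eps = math.sqrt(type_i.epsilon * type_j.epsilon)
    if rule == "geometric":
        sig = math.sqrt(type_i.sigma * type_j.sigma)
    elif rule == "lorentz-berthelot":
        sig = 0.5 * (type_i.sigma + type_j.sigma)
    else:
        raise ValueError(f"unknown combining rule {rule!r}")
    return sig, eps


@dataclass
class ParameterVector:
    """Bounded calibration vector x = (σ, ε) per optimized atom type.

    Component order is [σ_t1, ε_t1, σ_t2, ε_t2, ...] following
    ``type_order``.  ``bounds`` is an (n, 2) array of (low, high); frozen
    components (e.g. a zero-parameter hydrogen type kept in the vector for
    dimensionality bookkeeping) carry zero-width bounds.
    """

    values: np.ndarray
    bounds: np.ndarray
    base: ForceField
    type_order: tuple[str, ...]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.values.shape != (len(self.type_order) * 2,):
            raise ValueError("parameter vector length must be 2 x n_types")
        if self.bounds.shape != (len(self.values), 2):
            raise ValueError("bounds must be (n, 2)")
        self.check_bounds(self.values)

    @property
    def dim(self) -> int:
        return len(self.values)

    def check_bounds(self, x: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        tol = 1e-9 * np.maximum(1.0, np.abs(hi))
        if np.any(x < lo - tol) or np.any(x > hi + tol):
            bad = np.where((x < lo - tol) | (x > hi + tol))[0]
            raise BoundsViolationError(f"components {bad.tolist()} out of bounds")

    def with_values(self, x) -> "ParameterVector":
        return ParameterVector(np.asarray(x, dtype=float), self.bounds, self.base, self.type_order)

    def normalized(self, x=None) -> np.ndarray:
        """Map values into the unit cube (frozen dims map to 0.5)."""
        x = self.values if x is None else np.asarray(x, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        width = hi - lo
        out = np.full_like(x, 0.5)
        ok = width > 0
        out[ok] = (x[ok] - lo[ok]) / width[ok]
        return out

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return lo + np.asarray(u, dtype=float) * (hi - lo)


def make_bounds(
    base: ForceField,
    types: list[str],
    sigma_frac: float = 0.25,
    epsilon_frac: float = 0.5,
    keep_zero_types: bool = False,
) -> ParameterVector:
    """Build the calibration vector with ±fractional bounds about base values.

    σ bounds are [σ₀(1−sigma_frac), σ₀(1+sigma_frac)] and ε bounds
    [ε₀(1−epsilon_frac), ε₀(1+epsilon_frac)].  Types with σ = ε = 0
    (typically hydrogens) are dropped from the vector unless
    ``keep_zero_types`` is set, in which case they stay as frozen
    (zero-width) components.
    """
    if not types:
        raise ValueError("no atom types selected for calibration")
    if sigma_frac < 0 or epsilon_frac < 0:
        raise ValueError("bound fractions must be non-negative")
    kept = []
    for t in types:
        lj = base.lj(t)
        if lj.sigma == 0.0 and lj.epsilon == 0.0 and not keep_zero_types:
            continue
        kept.append(t)
    if not kept:
        raise ValueError("all selected types have zero LJ parameters")
    values, bounds = [], []
    for t in kept:
        lj = base.lj(t)
        values += [lj.sigma, lj.epsilon]
        bounds += [
            (lj.sigma * (1 - sigma_frac), lj.sigma * (1 + sigma_frac)),
            (lj.epsilon * (1 - epsilon_frac), lj.epsilon * (1 + epsilon_frac)),
        ]
    return ParameterVector(
        np.array(values), np.array(bounds), base, tuple(kept)
    )


def apply_parameters(pvec: ParameterVector, x=None) -> ForceField:
    """Force field with the optimized σ/ε substituted; the base is untouched."""
    x = pvec.values if x is None else np.asarray(x, dtype=float)
    pvec.check_bounds(x)
    new_types = {}
    for k, t in enumerate(pvec.type_order):
        new_types[t] = LJType(t, float(x[2 * k]), float(x[2 * k + 1]))
    return pvec.base.with_types(new_types)


def extract_parameters(pvec: ParameterVector, ff: ForceField) -> np.ndarray:
    """Inverse of :func:`apply_parameters` for the optimized types."""
    out = []
    for t in pvec.type_order:
        lj = ff.lj(t)
        out += [lj.sigma, lj.epsilon]
    return np.array(out)
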