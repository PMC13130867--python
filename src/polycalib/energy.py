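"""Nonbonded energy kernel for periodic molecular crystals.

Lennard-Jones with cutoff and analytic dispersion tail, plus classical
Ewald electrostatics under tinfoil (conducting) boundary conditions — no
surface-dipole term, so cells with a net dipole moment are well defined.
Real-space sums run over explicit lattice images, so cells smaller than the
cutoff are handled exactly (important for the small test crystals used
throughout).

Units are fixed globally: Å, kJ mol⁻¹, elementary charges, degrees.
The Coulomb prefactor e²/4πε₀ = 1389.35458 kJ mol⁻¹ Å e⁻².
"""

from __future__ import annotations

import itertools
import math
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.special import erf, erfc

from .crystal import Supercell, perpendicular_widths
from .forcefield import ForceField, combine_lj

__all__ = [
    "COULOMB_CONSTANT",
    "EwaldSettings",
    "EnergyBreakdown",
    "NonbondedKernel",
    "lj_energy",
    "ewald_energy",
    "total_energy",
    "scaled_coulomb_pair",
    "softcore_lj_pair",
    "NonNeutralCellError",
]

#: e^2 / (4 pi eps0) in kJ mol^-1 Å e^-2
COULOMB_CONSTANT = 1389.35458


class NonNeutralCellError(ValueError):
    """Raised for cells with non-zero net charge (no background correction)."""


@dataclass
class EwaldSettings:
    """Classical-Ewald control parameters.

    ``alpha_screen`` (Å⁻¹) splits real/reciprocal space; ``kmax`` is the
    minimum integer reciprocal cutoff per axis.  Both are derived from
    ``relative_accuracy`` by the standard error heuristics when
    :meth:`auto` is used; the Ewald total is then independent of the split
    to within that accuracy.
    """

    real_cutoff: float = 9.0
    alpha_screen: float = 0.4
    kmax: int = 8
    relative_accuracy: float = 1e-6

    def __post_init__(self):
        if self.real_cutoff <= 0 or self.alpha_screen <= 0 or self.kmax < 1:
            raise ValueError("invalid Ewald settings")

    @classmethod
    def auto(cls, cell_matrix: np.ndarray, real_cutoff: float = 9.0,
             relative_accuracy: float = 1e-6) -> "EwaldSettings":
        p = math.sqrt(-math.log(relative_accuracy))
        alpha = p / real_cutoff
        kcut = 2.0 * alpha * p
        widths = perpendicular_widths(np.asarray(cell_matrix, dtype=float))
        kmax = int(np.ceil(kcut * widths.max() / (2.0 * math.pi)))
        return cls(real_cutoff, alpha, max(kmax, 1), relative_accuracy)


@dataclass
class EnergyBreakdown:
    lj_real: float = 0.0
    lj_tail: float = 0.0
    coul_real: float = 0.0
    coul_recip: float = 0.0
    coul_self: float = 0.0
    coul_excl: float = 0.0

    @property
    def coulomb(self) -> float:
        return self.coul_real + self.coul_recip + self.coul_self + self.coul_excl

    @property
    def total(self) -> float:
        return self.lj_real + self.lj_tail + self.coulomb

    def as_dict(self) -> dict[str, float]:
        return {
            "lj_real": self.lj_real,
            "lj_tail": self.lj_tail,
            "coul_real": self.coul_real,
            "coul_recip": self.coul_recip,
            "coul_self": self.coul_self,
            "coul_excl": self.coul_excl,
            "total": self.total,
        }


def scaled_coulomb_pair(r: float, q_i: float, q_j: float, lam: float) -> float:
    """Linearly decoupled Coulomb pair energy (1−λ)·C·q_i q_j / r."""
    if r <= 0:
        raise ValueError("r must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return (1.0 - lam) * COULOMB_CONSTANT * q_i * q_j / r


def softcore_lj_pair(r, sigma: float, epsilon: float, lam: float,
                     alpha_sc: float = 0.5):
    """Beutler soft-core Lennard-Jones pair energy.

    U(r; λ) = 4ε(1−λ) [ (αλ + (r/σ)⁶)⁻² − (αλ + (r/σ)⁶)⁻¹ ].

    Reduces to standard LJ at λ = 0, vanishes at λ = 1, and stays finite at
    r = 0 for λ > 0 — the property that makes alchemical decoupling
    integrable.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    den = alpha_sc * lam + (r / sigma) ** 6
    out = 4.0 * epsilon * (1.0 - lam) * (1.0 / den**2 - 1.0 / den)
    return float(out) if out.ndim == 0 else out


def _half_shifts(cell_matrix: np.ndarray, rmax: float) -> np.ndarray:
    """Nonzero lattice shift vectors (one per ± pair) reaching within rmax."""
    widths = perpendicular_widths(cell_matrix)
    nmax = np.ceil(rmax / widths).astype(int)
    out = [n for n in itertools.product(*(range(-m, m + 1) for m in nmax))
           if n > (0, 0, 0)]  # lexicographic half-space
    if not out:
        return np.zeros((0, 3))
    return np.array(out, dtype=float) @ cell_matrix


class NonbondedKernel:
    """Precomputed pairwise tables for fast repeated energy/force evaluation.

    Built once per (topology, force field); positions and the cell matrix
    are passed per call, so relaxation loops reuse the kernel.  For the
    ``bonded-graph`` exclusion policy a bond list (pairs of site indices)
    must be supplied.
    """

    def __init__(self, supercell: Supercell, ff: ForceField,
                 settings: EwaldSettings | None = None,
                 lj_cutoff: float = 9.0, tail_correction: bool = True,
                 bonds: list[tuple[int, int]] | None = None):
        self.ff = ff
        self.lj_cutoff = float(lj_cutoff)
        self.tail_correction = bool(tail_correction)
        n = supercell.n_sites
        self.n_sites = n
        self.charges = np.array([s.charge for s in supercell.sites])
        self.molecule_map = supercell.molecule_map.copy()
        if settings is None:
            settings = EwaldSettings.auto(supercell.cell_matrix)
        self.settings = settings

        types = [s.atom_type for s in supercell.sites]
        unique = sorted(set(types))
        tidx = np.array([unique.index(t) for t in types])
        nt = len(unique)
        sig_tbl = np.zeros((nt, nt))
        eps_tbl = np.zeros((nt, nt))
        for a in range(nt):
            for b in range(nt):
                sig_tbl[a, b], eps_tbl[a, b] = combine_lj(
                    ff.lj(unique[a]), ff.lj(unique[b]), ff.combining_rule
                )
        self.sigma_mat = sig_tbl[tidx[:, None], tidx[None, :]]
        self.eps_mat = eps_tbl[tidx[:, None], tidx[None, :]]
        self.qq_mat = self.charges[:, None] * self.charges[None, :]
        self._type_counts = np.bincount(tidx, minlength=nt)
        self._sig_tbl, self._eps_tbl = sig_tbl, eps_tbl

        # per-pair scale factors for the home-image (n = 0) interaction
        lj_scale = np.ones((n, n))
        q_scale = np.ones((n, n))
        if ff.exclusion_policy == "rigid-molecule":
            same = self.molecule_map[:, None] == self.molecule_map[None, :]
            lj_scale[same] = 0.0
            q_scale[same] = 0.0
        else:
            if bonds is None:
                raise ValueError("bonded-graph policy requires a bond list")
            adj = [[] for _ in range(n)]
            for i, j in bonds:
                adj[i].append(j)
                adj[j].append(i)
            for i in range(n):
                # BFS to depth 3: 1-2/1-3 excluded, 1-4 scaled
                depth = {i: 0}
                queue = deque([i])
                while queue:
                    u = queue.popleft()
                    if depth[u] == 3:
                        continue
                    for v in adj[u]:
                        if v not in depth:
                            depth[v] = depth[u] + 1
                            queue.append(v)
                for j, d in depth.items():
                    if j == i:
                        continue
                    if d <= 2:
                        lj_scale[i, j] = q_scale[i, j] = 0.0
                    else:
                        lj_scale[i, j] = ff.scale14_lj
                        q_scale[i, j] = ff.scale14_coulomb
        np.fill_diagonal(lj_scale, 0.0)
        np.fill_diagonal(q_scale, 0.0)
        iu = np.triu_indices(n, k=1)
        self._iu = iu
        self.lj_scale_pairs = lj_scale[iu]
        self.q_scale_pairs = q_scale[iu]
        self.sig_pairs = self.sigma_mat[iu]
        self.eps_pairs = self.eps_mat[iu]
        self.qq_pairs = self.qq_mat[iu]

        self._cell_key = None
        self._has_charge = bool(np.any(self.charges != 0.0))
        if self._has_charge and abs(self.charges.sum()) > 1e-8:
            raise NonNeutralCellError(
                f"net charge {self.charges.sum():.3e} e; "
                "background correction is not implemented"
            )

    # -- geometry-dependent caches -------------------------------------
    def _prepare_cell(self, m: np.ndarray, pad: float) -> None:
        key = (m.tobytes(), math.ceil(pad))
        if key == self._cell_key:
            return
        self._cell_key = key
        rmax = max(self.lj_cutoff, self.settings.real_cutoff) + math.ceil(pad)
        self._shifts = _half_shifts(m, rmax)
        self._volume = float(abs(np.linalg.det(m)))
        if self._has_charge:
            bmat = 2.0 * math.pi * np.linalg.inv(m).T
            alpha = self.settings.alpha_screen
            p = math.sqrt(-math.log(self.settings.relative_accuracy))
            kcut = 2.0 * alpha * p
            nmax = np.ceil(kcut / np.linalg.norm(bmat, axis=1)).astype(int)
            nmax = np.minimum(np.maximum(nmax, self.settings.kmax), 64)
            rng = [np.arange(-v, v + 1) for v in nmax]
            grid = np.array(np.meshgrid(*rng, indexing="ij")).reshape(3, -1).T
            half = grid[
                (grid[:, 0] > 0)
                | ((grid[:, 0] == 0) & (grid[:, 1] > 0))
                | ((grid[:, 0] == 0) & (grid[:, 1] == 0) & (grid[:, 2] > 0))
            ]
            k = half @ bmat
            k2 = (k**2).sum(axis=1)
            keep = k2 <= (kcut * 1.05) ** 2
            self._kvecs = np.ascontiguousarray(k[keep])
            self._ak = np.exp(-k2[keep] / (4.0 * alpha**2)) / k2[keep]

    # -- evaluation ------------------------------------------------------
    def energy(self, cart_pos: np.ndarray, cell_matrix: np.ndarray) -> EnergyBreakdown:
        e, _ = self._evaluate(cart_pos, cell_matrix, want_forces=False)
        return e

    def forces(self, cart_pos: np.ndarray, cell_matrix: np.ndarray):
        """Returns (EnergyBreakdown, per-site forces in kJ mol⁻¹ Å⁻¹)."""
        return self._evaluate(cart_pos, cell_matrix, want_forces=True)

    def _evaluate(self, cart_pos, cell_matrix, want_forces):
        m = np.ascontiguousarray(cell_matrix, dtype=float)
        pos = np.asarray(cart_pos, dtype=float)
        n = self.n_sites
        diff = pos[None, :, :] - pos[:, None, :]  # diff[i, j] = r_j - r_i
        d0max = math.sqrt(float((diff**2).sum(axis=-1).max()))
        self._prepare_cell(m, d0max)
        alpha = self.settings.alpha_screen
        C = COULOMB_CONSTANT
        br = EnergyBreakdown()
        F = np.zeros((n, 3)) if want_forces else None
        iu = self._iu

        # assemble one flat term list: home-image unique pairs (scaled) then
        # all ordered pairs under each nonzero half-space shift (full scale)
        d0 = diff[iu]
        ns = len(self._shifts)
        if ns:
            dimg = (diff.reshape(1, -1, 3) + self._shifts[:, None, :]).reshape(-1, 3)
            dvec = np.vstack([d0, dimg])
            tile = np.tile
            sig = np.concatenate([self.sig_pairs, tile(self.sigma_mat.ravel(), ns)])
            eps = np.concatenate([self.eps_pairs, tile(self.eps_mat.ravel(), ns)])
            qq = np.concatenate([self.qq_pairs, tile(self.qq_mat.ravel(), ns)])
            s_lj = np.concatenate([self.lj_scale_pairs, np.ones(ns * n * n)])
            s_q = np.concatenate([self.q_scale_pairs, np.ones(ns * n * n)])
            flat_j = tile(np.arange(n * n) % n, ns)
            flat_i = tile(np.arange(n * n) // n, ns)
            idx_i = np.concatenate([iu[0], flat_i[: ns * n * n]])
            idx_j = np.concatenate([iu[1], flat_j[: ns * n * n]])
        else:
            dvec, sig, eps, qq = d0, self.sig_pairs, self.eps_pairs, self.qq_pairs
            s_lj, s_q = self.lj_scale_pairs, self.q_scale_pairs
            idx_i, idx_j = iu[0], iu[1]

        r2 = (dvec**2).sum(axis=1)
        r2 = np.maximum(r2, 1e-300)
        dU_r = np.zeros_like(r2) if want_forces else None

        mask = (r2 <= self.lj_cutoff**2) & (s_lj > 0) & (eps > 0)
        if np.any(mask):
            sr6 = (sig[mask] ** 2 / r2[mask]) ** 3
            e_pair = 4.0 * eps[mask] * s_lj[mask] * (sr6**2 - sr6)
            br.lj_real = float(e_pair.sum())
            if want_forces:
                dU_r[mask] += (
                    4.0 * eps[mask] * s_lj[mask]
                    * (-12.0 * sr6**2 + 6.0 * sr6) / r2[mask]
                )
        if self._has_charge:
            mask = (r2 <= self.settings.real_cutoff**2) & (s_q > 0) & (qq != 0)
            if np.any(mask):
                r = np.sqrt(r2[mask])
                w = C * s_q[mask] * qq[mask]
                ec = erfc(alpha * r)
                br.coul_real = float((w * ec / r).sum())
                if want_forces:
                    dU_r[mask] += -w * (
                        ec / r2[mask]
                        + 2.0 * alpha / math.sqrt(math.pi)
                        * np.exp(-((alpha * r) ** 2)) / r
                    ) / r
        if want_forces:
            nz = dU_r != 0.0
            fpair = dU_r[nz, None] * dvec[nz]  # gradient wrt r_j
            np.add.at(F, idx_j[nz], -fpair)
            np.add.at(F, idx_i[nz], fpair)

        if self._has_charge:
            # exclusion compensation: remove the reciprocal-space (erf) part
            # of excluded / scaled home pairs so their net Coulomb term is
            # exactly the scaled physical interaction
            comp = 1.0 - self.q_scale_pairs
            sel = (comp > 0) & (self.qq_pairs != 0)
            if np.any(sel):
                dv = d0[sel]
                r = np.linalg.norm(dv, axis=1)
                ok = r > 1e-12
                w = comp[sel][ok] * self.qq_pairs[sel][ok] * C
                r = r[ok]
                ef = erf(alpha * r)
                br.coul_excl = float((-w * ef / r).sum())
                if want_forces:
                    # (dU/dr)/r with U = -w erf(ar)/r
                    du = w * (
                        ef / r**3
                        - 2.0 * alpha / math.sqrt(math.pi)
                        * np.exp(-((alpha * r) ** 2)) / r**2
                    )
                    i_idx = iu[0][sel][ok]
                    j_idx = iu[1][sel][ok]
                    fpair = du[:, None] * dv[ok]
                    np.add.at(F, j_idx, -fpair)
                    np.add.at(F, i_idx, fpair)

            # reciprocal sum (tinfoil boundary: no surface-dipole term)
            k = self._kvecs
            phase = pos @ k.T
            co, si = np.cos(phase), np.sin(phase)
            s_re = self.charges @ co
            s_im = self.charges @ si
            pref = C * 4.0 * math.pi / self._volume  # x2 for the half k-set
            br.coul_recip = float(pref * (self._ak * (s_re**2 + s_im**2)).sum())
            br.coul_self = (
                -C * alpha / math.sqrt(math.pi) * float((self.charges**2).sum())
            )
            if want_forces:
                t = si * (self._ak * s_re) - co * (self._ak * s_im)
                F += 2.0 * pref * self.charges[:, None] * (t @ k)

        if self.tail_correction:
            br.lj_tail = self._tail_energy(self._volume)
        return br, F

    def _tail_energy(self, volume: float) -> float:
        """Uniform-density dispersion correction beyond the LJ cutoff."""
        rc = self.lj_cutoff
        e = 0.0
        counts = self._type_counts
        for a in range(len(counts)):
            for b in range(len(counts)):
                sig, eps = self._sig_tbl[a, b], self._eps_tbl[a, b]
                if eps == 0.0 or sig == 0.0:
                    continue
                x = (sig / rc) ** 3
                e += (
                    8.0 * math.pi * counts[a] * counts[b] * eps * sig**3
                    / (3.0 * volume) * (x**3 / 3.0 - x)
                )
        return e


def lj_energy(supercell: Supercell, ff: ForceField, cutoff: float = 9.0,
              tail_correction: bool = True) -> float:
    """Lennard-Jones lattice energy (kJ mol⁻¹) with optional dispersion tail."""
    kern = NonbondedKernel(
        _chargeless(supercell), ff, lj_cutoff=cutoff, tail_correction=tail_correction
    )
    br = kern.energy(supercell.cart_pos, supercell.cell_matrix)
    return br.lj_real + br.lj_tail


def ewald_energy(supercell: Supercell, ff: ForceField,
                 settings: EwaldSettings | None = None) -> EnergyBreakdown:
    """Coulomb parts of the Ewald sum (LJ components left zero)."""
    kern = NonbondedKernel(supercell, ff, settings=settings, tail_correction=False)
    br = kern.energy(supercell.cart_pos, supercell.cell_matrix)
    br.lj_real = 0.0
    br.lj_tail = 0.0
    return br


def total_energy(supercell: Supercell, ff: ForceField,
                 settings: EwaldSettings | None = None,
                 lj_cutoff: float = 9.0, tail_correction: bool = True) -> EnergyBreakdown:
    """Full nonbonded breakdown (LJ + Ewald) with a consistent exclusion set."""
    kern = NonbondedKernel(
        supercell, ff, settings=settings,
        lj_cutoff=lj_cutoff, tail_correction=tail_correction,
    )
    return kern.energy(supercell.cart_pos, supercell.cell_matrix)


def _chargeless(supercell: Supercell) -> Supercell:
    from dataclasses import replace as _replace

    sc = supercell.copy()
    sc.sites = tuple(_replace(s, charge=0.0) for s in sc.sites)
    return sc
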