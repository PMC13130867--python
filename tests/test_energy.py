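"""Energy kernel: LJ lattice sums, Ewald electrostatics, alchemical pairs."""

import itertools
import math

import numpy as np
import pytest

from polycalib.crystal import AtomSite, UnitCell, build_supercell
from polycalib.energy import (
    COULOMB_CONSTANT,
    EwaldSettings,
    NonNeutralCellError,
    ewald_energy,
    lj_energy,
    scaled_coulomb_pair,
    softcore_lj_pair,
    total_energy,
)
from polycalib.fixtures import (
    dipolar_forcefield,
    lj_forcefield,
    make_dipolar_crystal,
    make_rocksalt,
    rocksalt_forcefield,
)

MADELUNG_NACL = 1.747565


def _pair_cell(r, box=50.0, q=(0.0, 0.0)):
    sites = (
        AtomSite("a", "X", "X", (0.1, 0.1, 0.1), q[0], 0),
        AtomSite("b", "X", "X", (0.1 + r / box, 0.1, 0.1), q[1], 1),
    )
    return UnitCell((box, box, box), (90,) * 3, sites, formula_units=2)


def _direct_lj_sum(supercell, sigma, epsilon, rmax):
    """Brute-force image sum oracle, independent of the kernel."""
    m = supercell.cell_matrix
    pos = supercell.cart_pos
    mol = supercell.molecule_map
    nmax = [int(np.ceil(rmax / np.linalg.norm(m[i]))) + 1 for i in range(3)]
    e = 0.0
    for n in itertools.product(*(range(-k, k + 1) for k in nmax)):
        shift = np.array(n, dtype=float) @ m
        for i in range(len(pos)):
            for j in range(len(pos)):
                if n == (0, 0, 0) and (i == j or mol[i] == mol[j]):
                    continue
                r = np.linalg.norm(pos[j] - pos[i] + shift)
                if 0 < r <= rmax:
                    sr6 = (sigma / r) ** 6
                    e += 0.5 * 4 * epsilon * (sr6**2 - sr6)
    return e


class TestLennardJones:
    def test_pair_zero_crossing_at_sigma(self):
        cell = _pair_cell(3.0)
        sc = build_supercell(cell)
        e = lj_energy(sc, lj_forcefield(3.0, 1.0), cutoff=9.0, tail_correction=False)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_pair_minimum_minus_epsilon(self):
        r = 2 ** (1 / 6) * 3.0
        sc = build_supercell(_pair_cell(r))
        e = lj_energy(sc, lj_forcefield(3.0, 0.7), cutoff=9.0, tail_correction=False)
        assert e == pytest.approx(-0.7, rel=1e-12)

    def test_lattice_matches_direct_image_sum(self):
        """Kernel real-space sum equals the brute-force oracle at equal cutoff."""
        sigma = 2.0
        cell = make_rocksalt(spacing=1.2 * sigma)  # rock-salt geometry, LJ only
        sc = build_supercell(cell)
        ff = lj_forcefield(sigma, 0.5)
        # replace types so every site uses the LJ type
        from dataclasses import replace

        sc.sites = tuple(replace(s, atom_type="X", charge=0.0) for s in sc.sites)
        e_kernel = lj_energy(sc, ff, cutoff=7.0, tail_correction=False)
        e_direct = _direct_lj_sum(sc, sigma, 0.5, 7.0)
        assert e_kernel == pytest.approx(e_direct, rel=1e-10)

    def test_tail_correction_converges_to_long_cutoff_sum(self, lj_crystal):
        cell, ff = lj_crystal
        sc = build_supercell(cell, (1, 1, 1))
        reference = lj_energy(sc, ff, cutoff=40.0, tail_correction=False)
        errors = []
        for rc in (8.5, 10.2, 11.9):  # 2.5, 3.0, 3.5 sigma
            e = lj_energy(sc, ff, cutoff=rc, tail_correction=True)
            errors.append(abs(e - reference))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] / abs(reference) < 5e-3


class TestEwald:
    def test_zero_charges_zero_coulomb(self, dipolar):
        cell, ff = dipolar
        from dataclasses import replace

        sc = build_supercell(cell)
        sc.sites = tuple(replace(s, charge=0.0) for s in sc.sites)
        br = ewald_energy(sc, ff)
        assert br.coulomb == 0.0

    def test_rocksalt_madelung_constant(self, rocksalt):
        cell, ff = rocksalt
        sc = build_supercell(cell)
        settings = EwaldSettings.auto(sc.cell_matrix, real_cutoff=9.0,
                                      relative_accuracy=1e-8)
        br = ewald_energy(sc, ff, settings)
        e_per_pair = br.total / 4
        madelung = -e_per_pair * 2.82 / COULOMB_CONSTANT
        assert madelung == pytest.approx(MADELUNG_NACL, abs=2e-6)

    def test_energy_scales_inversely_with_spacing(self):
        ff = rocksalt_forcefield()
        sc1 = build_supercell(make_rocksalt(2.5))
        sc2 = build_supercell(make_rocksalt(5.0))
        acc = 1e-9
        e1 = ewald_energy(sc1, ff, EwaldSettings.auto(sc1.cell_matrix, 9.0, acc)).total
        e2 = ewald_energy(sc2, ff, EwaldSettings.auto(sc2.cell_matrix, 18.0, acc)).total
        assert e1 == pytest.approx(2 * e2, rel=1e-8)

    def test_alpha_invariance(self, rocksalt):
        cell, ff = rocksalt
        sc = build_supercell(cell)
        values = [
            ewald_energy(
                sc, ff,
                EwaldSettings(real_cutoff=10.0, alpha_screen=a, kmax=14,
                              relative_accuracy=1e-8),
            ).total
            for a in (0.4, 0.6, 0.8)
        ]
        assert max(values) - min(values) < 1e-6 * abs(values[0])

    def test_dipolar_crystal_convergence(self, dipolar):
        """Total is stable under over-converged cutoff and k-space settings."""
        cell, ff = dipolar
        sc = build_supercell(cell)
        base = EwaldSettings.auto(sc.cell_matrix, real_cutoff=9.0,
                                  relative_accuracy=1e-7)
        e0 = total_energy(sc, ff, base, lj_cutoff=9.0).total
        bumped = EwaldSettings(
            real_cutoff=base.real_cutoff + 2.0, alpha_screen=base.alpha_screen,
            kmax=base.kmax + 2, relative_accuracy=base.relative_accuracy,
        )
        e1 = total_energy(sc, ff, bumped, lj_cutoff=9.0).total
        assert e1 == pytest.approx(e0, rel=1e-6)

    def test_non_neutral_cell_rejected(self):
        cell = _pair_cell(3.0, q=(1.0, -0.5))
        with pytest.raises(NonNeutralCellError):
            ewald_energy(build_supercell(cell), lj_forcefield(3.0, 0.0))


class TestTotalEnergy:
    def test_single_rigid_molecule_in_huge_cell_is_zero(self):
        sites = (
            AtomSite("a", "X", "D", (0.5, 0.5, 0.5), 0.3, 0),
            AtomSite("b", "X", "D", (0.5, 0.5, 0.5 + 1.2 / 200), -0.3, 0),
        )
        cell = UnitCell((200, 200, 200), (90,) * 3, sites, formula_units=1)
        sc = build_supercell(cell)
        settings = EwaldSettings(real_cutoff=30.0, alpha_screen=0.12, kmax=8,
                                 relative_accuracy=1e-6)
        br = total_energy(sc, dipolar_forcefield(), settings, lj_cutoff=30.0,
                          tail_correction=False)
        assert abs(br.total) < 1e-4  # periodic self-image residue only

    def test_two_molecules_match_explicit_pair_terms(self):
        """Supercell total equals the hand-summed intermolecular pair terms."""
        q, sigma, eps, box = 0.3, 3.0, 0.8, 60.0
        offs = np.array([[0, 0, -0.6], [0, 0, 0.6]])
        centers = np.array([[20.0, 20.0, 20.0], [24.0, 20.0, 20.0]])
        sites = []
        qs = [q, -q, -q, q]  # antiparallel: net cell dipole ~ 0
        for m, c in enumerate(centers):
            for k, off in enumerate(offs):
                frac = (c + off) / box
                sites.append(
                    AtomSite(f"d{m}{k}", "X", "D", tuple(frac),
                             qs[2 * m + k], m)
                )
        cell = UnitCell((box,) * 3, (90,) * 3, tuple(sites), formula_units=2)
        sc = build_supercell(cell)
        settings = EwaldSettings(real_cutoff=25.0, alpha_screen=0.25, kmax=18,
                                 relative_accuracy=1e-8)
        br = total_energy(sc, dipolar_forcefield(sigma, eps), settings,
                          lj_cutoff=25.0, tail_correction=False)
        e_manual = 0.0
        pos = sc.cart_pos
        for i in range(2):
            for j in range(2, 4):
                r = np.linalg.norm(pos[j] - pos[i])
                sr6 = (sigma / r) ** 6
                e_manual += 4 * eps * (sr6**2 - sr6)
                e_manual += COULOMB_CONSTANT * qs[i] * qs[j] / r
        assert br.total == pytest.approx(e_manual, abs=2e-3)

    def test_translation_invariance(self, dipolar):
        cell, ff = dipolar
        sc = build_supercell(cell)
        e0 = total_energy(sc, ff).total
        sc2 = sc.copy()
        sc2.cart_pos = sc.cart_pos + np.array([1.234, -0.777, 3.1])
        e1 = total_energy(sc2, ff).total
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_breakdown_sums_to_total(self, dipolar):
        cell, ff = dipolar
        br = total_energy(build_supercell(cell), ff)
        parts = br.lj_real + br.lj_tail + br.coul_real + br.coul_recip \
            + br.coul_self + br.coul_excl
        assert br.total == pytest.approx(parts, rel=1e-12)


class TestAlchemicalPairs:
    def test_scaled_coulomb(self):
        assert scaled_coulomb_pair(2.5, 0.4, -0.2, 1.0) == 0.0
        assert scaled_coulomb_pair(1.0, 1.0, -1.0, 0.0) == pytest.approx(
            -COULOMB_CONSTANT
        )
        full = scaled_coulomb_pair(1.7, 0.3, 0.5, 0.0)
        assert scaled_coulomb_pair(1.7, 0.3, 0.5, 0.5) == pytest.approx(full / 2)

    def test_softcore_reduces_to_lj_at_lambda_zero(self):
        r = np.linspace(0.8, 3.0, 40) * 2.9
        sc = softcore_lj_pair(r, 2.9, 0.55, 0.0)
        sr6 = (2.9 / r) ** 6
        np.testing.assert_allclose(sc, 4 * 0.55 * (sr6**2 - sr6), rtol=1e-14)

    def test_softcore_vanishes_at_lambda_one(self):
        r = np.linspace(0.1, 3.0, 20)
        np.testing.assert_array_equal(softcore_lj_pair(r, 3.0, 1.0, 1.0), 0.0)

    def test_softcore_hand_value(self):
        # lambda=0.5, alpha=0.5, r=sigma: 4*0.5*(1/1.25^2 - 1/1.25) = -0.32
        assert softcore_lj_pair(3.0, 3.0, 1.0, 0.5) == pytest.approx(-0.32)

    def test_softcore_finite_at_overlap(self):
        lam, alpha = 0.25, 0.5
        expected = 4 * 1.0 * (1 - lam) * (1 / (alpha * lam) ** 2 - 1 / (alpha * lam))
        assert softcore_lj_pair(0.0, 3.0, 1.0, lam) == pytest.approx(expected)

    def test_softcore_monotone_and_continuous_in_lambda(self):
        # beyond the LJ minimum (r >= 2^(1/6) sigma) the pair energy rises
        # monotonically to zero as the interaction decouples; inside the
        # minimum a transient dip exists, so only continuity is required
        lams = np.linspace(0.0, 1.0, 201)
        for r_over_sigma in (2 ** (1 / 6), 1.3, 2.0):
            u = np.array([
                softcore_lj_pair(r_over_sigma * 3.1, 3.1, 0.8, lam) for lam in lams
            ])
            assert np.all(np.diff(u) >= -1e-12)
        u_inside = np.array([
            softcore_lj_pair(3.1, 3.1, 0.8, lam) for lam in lams
        ])
        assert np.max(np.abs(np.diff(u_inside))) < 0.05  # continuous in lambda
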