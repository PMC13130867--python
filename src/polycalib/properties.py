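"""Thermodynamic and transport property calculators.

Lattice-energy bookkeeping (per-molecule energies, the sublimation-enthalpy
route to a reference lattice energy, solution/solvation enthalpies),
crystal densities, mean-squared-displacement diffusion estimates and
block-averaged uncertainties.

Sign conventions: lattice energies are negative for bound crystals; a
*positive* solution enthalpy means crystal growth is exothermic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .crystal import Supercell

__all__ = [
    "GAS_CONSTANT",
    "AVOGADRO",
    "LatticeReport",
    "TrajectorySet",
    "lattice_energy",
    "lattice_energy_from_sublimation",
    "solution_enthalpy",
    "solvation_enthalpy_gh",
    "msd",
    "diffusion_from_msd",
    "block_average",
    "crystal_density",
    "saturation_mole_fraction",
    "supersaturation",
]

#: kJ mol^-1 K^-1
GAS_CONSTANT = 8.31446e-3
AVOGADRO = 6.02214076e23

#: molar masses (g/mol) for the elements used in this package's structures
MOLAR_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "Na": 22.990, "Cl": 35.45, "S": 32.06, "X": 20.0,
}


@dataclass
class LatticeReport:
    """Per-molecule lattice energy and the quantities it was built from."""

    e_total: float
    n_molecules: int
    e_single: float
    density: float | None = None
    cell: tuple | None = None

    @property
    def e_latt(self) -> float:
        return self.e_total / self.n_molecules - self.e_single


def lattice_energy(e_total: float, n: int, e_single: float = 0.0) -> float:
    """Lattice energy per molecule: E_total / N − E_single (kJ mol⁻¹).

    Under the rigid-molecule exclusion policy the vacuum single-molecule
    energy is zero by construction, so the lattice energy is simply the
    supercell energy per molecule.
    """
    if n < 1:
        raise ValueError("molecule count must be >= 1")
    return e_total / n - e_single


def lattice_energy_from_sublimation(dh_sub: float, T: float, de_pt: float = 0.0) -> float:
    """Reference lattice energy from a sublimation enthalpy.

    Inverts ΔH_sub = −E_latt − 2RT + ΔE_pt, where the 2RT term is the
    difference between the ideal-gas enthalpy (4RT) and the lattice
    vibrational/librational enthalpy (6RT), and ΔE_pt corrects the gas-phase
    reference for proton transfer (neutral → zwitterion).  T is the
    temperature of the sublimation measurement.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -dh_sub - 2.0 * GAS_CONSTANT * T + de_pt


def solution_enthalpy(dh_solv: float, e_latt: float) -> float:
    """ΔH_sol = ΔH_solv − E_latt (kJ mol⁻¹); positive ⇔ exothermic growth."""
    return dh_solv - e_latt


def solvation_enthalpy_gh(dg1: float, t1: float, dg2: float, t2: float) -> float:
    """Solvation enthalpy from free energies at two temperatures.

    Integrated Gibbs–Helmholtz: ΔH = (ΔG₂/T₂ − ΔG₁/T₁) / (1/T₂ − 1/T₁).
    Exact for any ΔG(T) affine in T (constant ΔH, ΔS).
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("temperatures must be positive")
    if t1 == t2:
        raise ValueError("temperatures must differ")
    return (dg2 / t2 - dg1 / t1) / (1.0 / t2 - 1.0 / t1)


@dataclass
class TrajectorySet:
    """Unwrapped center-of-mass trajectories: times (ps) × molecules × xyz (Å)."""

    times: np.ndarray
    com_positions: np.ndarray  # (n_frames, n_molecules, 3)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.com_positions = np.asarray(self.com_positions, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.com_positions.shape[0] != len(self.times):
            raise ValueError("frame count mismatch")
        if not np.all(np.isfinite(self.com_positions)):
            raise ValueError("non-finite positions")

    @property
    def n_molecules(self) -> int:
        return self.com_positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def msd(traj: TrajectorySet, lags: np.ndarray | None = None):
    """Windowed mean squared displacement ⟨Δr²(τ)⟩ (Å²).

    Averages over all time origins and all molecules; the per-molecule
    curves are returned alongside the ensemble mean so uncertainties can be
    propagated.  Returns (lags_ps, mean_msd, per_molecule_msd).
    """
    n_frames = len(traj.times)
    dt = traj.dt
    if lags is None:
        lag_steps = np.arange(1, n_frames)
    else:
        lag_steps = np.unique(np.round(np.asarray(lags, dtype=float) / dt).astype(int))
        keep = (lag_steps >= 1) & (lag_steps < n_frames)
        if not np.all(keep):
            warnings.warn("some lags exceed the trajectory span; omitted")
        lag_steps = lag_steps[keep]
    pos = traj.com_positions
    mean_curve = np.empty(len(lag_steps))
    per_mol = np.empty((len(lag_steps), traj.n_molecules))
    for k, lag in enumerate(lag_steps):
        disp = pos[lag:] - pos[:-lag]  # (origins, molecules, 3)
        sq = (disp**2).sum(axis=-1)
        per_mol[k] = sq.mean(axis=0)
        mean_curve[k] = per_mol[k].mean()
    return lag_steps * dt, mean_curve, per_mol


def diffusion_from_msd(traj: TrajectorySet, fit_max: float,
                       slope_window_check: bool = True,
                       lags: np.ndarray | None = None):
    """Einstein-relation diffusion coefficient from MSD slopes.

    D = (1/6) d⟨Δr²⟩/dτ, least-squares fitted over lags up to ``fit_max``
    (ps).  With ``slope_window_check`` the fit is restricted to lags where
    the local log-log slope of the ensemble MSD lies in [0.9, 1.1] — the
    diffusive regime.  Returns (per-molecule D, mean D, standard error of
    the mean), with D in 10⁻⁹ m² s⁻¹ (1 Å²/ps = 10 × 10⁻⁹ m² s⁻¹).

    Raises if no lag passes the slope check (e.g. purely ballistic motion).
    """
    taus, mean_curve, per_mol = msd(traj, lags)
    window = taus <= fit_max
    if slope_window_check:
        with np.errstate(divide="ignore", invalid="ignore"):
            log_t = np.log(taus)
            log_m = np.log(np.maximum(mean_curve, 1e-300))
        slope_local = np.gradient(log_m, log_t)
        window &= (slope_local >= 0.9) & (slope_local <= 1.1)
    if window.sum() < 2:
        raise RuntimeError(
            "no diffusive window found: log-log MSD slope is never ~1 "
            "below fit_max"
        )
    t = taus[window]
    design = np.vstack([t, np.ones_like(t)]).T
    slopes = np.linalg.lstsq(design, per_mol[window], rcond=None)[0][0]
    d_mol = slopes / 6.0 * 10.0  # Å²/ps -> 1e-9 m²/s
    d_mean = float(d_mol.mean())
    d_sem = float(d_mol.std(ddof=1) / np.sqrt(len(d_mol))) if len(d_mol) > 1 else 0.0
    return d_mol, d_mean, d_sem


def block_average(series: np.ndarray):
    """Mean and autocorrelation-robust standard error by block doubling.

    Blocks of size 1, 2, 4, ... are averaged; the standard error of the
    block means rises until blocks decorrelate.  The reported error is the
    first plateau value (change < 10% over two successive doublings), or
    the maximum over block sizes if no plateau is reached.
    """
    x = np.asarray(series, dtype=float).ravel()
    if len(x) < 8:
        raise ValueError("need at least 8 samples for block averaging")
    mean = float(x.mean())
    errs = []
    block = 1
    while len(x) // block >= 4:
        nb = len(x) // block
        bm = x[: nb * block].reshape(nb, block).mean(axis=1)
        errs.append(float(bm.std(ddof=1) / np.sqrt(nb)))
        block *= 2
    errs = np.array(errs)
    stderr = float(errs.max())
    for i in range(len(errs) - 2):
        window = errs[i : i + 3]
        base = max(window[0], 1e-300)
        if np.all(np.abs(np.diff(window)) / base < 0.10):
            stderr = float(window[-1])
            break
    if np.allclose(x, x[0]):
        stderr = 0.0
    return mean, stderr


def crystal_density(supercell: Supercell, molar_masses: dict | None = None) -> float:
    """Mass density in g cm⁻³ from site elements and the cell volume."""
    masses = molar_masses or MOLAR_MASSES
    try:
        total = sum(masses[s.element] for s in supercell.sites)
    except KeyError as exc:
        raise KeyError(f"no molar mass for element {exc.args[0]!r}") from None
    vol_cm3 = supercell.volume * 1e-24
    if total == 0.0:
        return 0.0
    return total / (AVOGADRO * vol_cm3)


def saturation_mole_fraction(solubility_g_per_l: float, solute_mm: float,
                             water_mm: float = 18.015) -> float:
    """Saturation mole fraction from a solubility in grams per liter of water.

    One liter of water is 1000/water_mm ≈ 55.5 mol; the solute contributes
    solubility/solute_mm mol.
    """
    if solute_mm <= 0 or water_mm <= 0:
        raise ValueError("molar masses must be positive")
    n_solute = solubility_g_per_l / solute_mm
    n_water = 1000.0 / water_mm
    return n_solute / (n_solute + n_water)


def supersaturation(x: float, x_sat: float) -> float:
    """Ratio of a mole fraction to the saturation mole fraction."""
    if x_sat <= 0:
        raise ValueError("saturation mole fraction must be positive")
    return x / x_sat
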