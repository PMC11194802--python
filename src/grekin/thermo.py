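"""Rigid-rotor/harmonic-oscillator vibrational analysis and Eyring kinetics.

This module provides the thermochemistry stage behind barrier tables of the
form Δ(E+thermal): mass-weighted normal-mode analysis of a Cartesian Hessian,
isotope substitution by mass replacement, scaled zero-point and thermal
vibrational corrections, and transition-state-theory rate and kinetic isotope
effect (KIE) calculators,

    k = κ · (kB·T / h) · exp(−ΔE‡ / R·T),

with the barrier in kJ/mol.  Rotational/translational thermal terms are
omitted: they cancel between a transition state and the minimum of the same
system.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import AMU_KG, BOHR_M, CONSTANTS, HARTREE_J, Constants

__all__ = [
    "HarmonicSystem",
    "ThermalCorrection",
    "hessian_frequencies",
    "thermal_energy",
    "isotope_substitute",
    "eyring_rate",
    "kie_from_barriers",
    "barrier_from_energies",
    "read_hessian_file",
    "write_hessian_file",
]


@dataclass(frozen=True)
class HarmonicSystem:
    """Cartesian Hessian plus per-atom masses.

    Parameters
    ----------
    masses
        Per-atom masses in amu, length N.
    hessian
        Symmetric 3N x 3N matrix of Cartesian second derivatives in
        hartree/bohr² (the quantum-chemistry convention; converted to SI
        internally via ``HARTREE_J`` and ``BOHR_M``).
    labels
        Per-atom element symbols (bookkeeping only).
    coords
        Optional N x 3 Cartesian coordinates (bohr), needed to project out
        rigid rotations.
    """

    masses: np.ndarray
    hessian: np.ndarray
    labels: tuple[str, ...] = ()
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        hessian = np.asarray(self.hessian, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "hessian", hessian)
        if masses.ndim != 1 or np.any(masses <= 0):
            raise ValueError("masses must be a 1-D array of positive values")
        n = masses.size
        if hessian.shape != (3 * n, 3 * n):
            raise ValueError(
                f"hessian must be {3 * n}x{3 * n} for {n} atoms, got {hessian.shape}"
            )
        scale = max(1.0, float(np.abs(hessian).max()))
        if not np.allclose(hessian, hessian.T, atol=1e-8 * scale):
            raise ValueError("hessian must be symmetric (1e-8 relative)")
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (n, 3):
                raise ValueError("coords must be N x 3")
            object.__setattr__(self, "coords", coords)

    @property
    def n_atoms(self) -> int:
        return self.masses.size


@dataclass(frozen=True)
class ThermalCorrection:
    """Scaled ZPE + thermal vibrational energy, kJ/mol at temperature T."""

    zpe: float
    e_vib: float
    total: float
    T: float


def _tr_projector(system: HarmonicSystem) -> np.ndarray:
    """Projector removing rigid translations (and rotations if coords given)."""
    n = system.n_atoms
    sqm = np.sqrt(system.masses)
    vecs = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sqm
        vecs.append(v.ravel())
    if system.coords is not None:
        com = (system.masses[:, None] * system.coords).sum(0) / system.masses.sum()
        x = system.coords - com
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = 1.0
            v = np.cross(x, e) * sqm[:, None]
            vecs.append(v.ravel())
    basis = np.array(vecs).T
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return np.eye(3 * n) - q @ q.T


def hessian_frequencies(system: HarmonicSystem, project_tr: bool = False) -> np.ndarray:
    """Harmonic wavenumbers (cm⁻¹) from a mass-weighted Hessian.

    Negative curvature (imaginary modes) is reported as negative wavenumbers.
    With ``project_tr``, rigid translations — and rotations, when the system
    carries coordinates — are projected out before diagonalisation.
    """
    sqm = np.repeat(np.sqrt(system.masses * AMU_KG), 3)
    h_si = system.hessian * (HARTREE_J / BOHR_M**2)  # J/m^2
    mwh = h_si / np.outer(sqm, sqm)
    if project_tr:
        p = _tr_projector(system)
        mwh = p @ mwh @ p
    evals = np.linalg.eigvalsh(mwh)  # rad^2/s^2
    omega = np.sign(evals) * np.sqrt(np.abs(evals))
    wavenumbers = omega / (2.0 * math.pi * CONSTANTS.c)
    return np.sort(wavenumbers)


def thermal_energy(
    wavenumbers: Sequence[float],
    T: float = CONSTANTS.T_default,
    scale: float = CONSTANTS.freq_scale,
    constants: Constants = CONSTANTS,
    scale_evib: bool = True,
) -> ThermalCorrection:
    """Scaled ZPE and thermal vibrational energy (kJ/mol) of harmonic modes.

    Per mode of wavenumber ν̃:  zpe = NA·h·c·ν̃/2 and
    e_vib = NA·h·c·ν̃ / (exp(h·c·ν̃/kB·T) − 1).  The scaling factor is applied
    to both terms by default; ``scale_evib=False`` restricts it to the ZPE.
    Imaginary (negative) modes must be excluded by the caller.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    if np.any(nu < 0):
        raise ValueError("negative wavenumbers not allowed; exclude imaginary modes")
    if T <= 0:
        raise ValueError("T must be positive")
    hc_nu = constants.h * constants.c * nu  # J per quantum
    zpe = constants.NA * hc_nu.sum() / 2.0 / 1000.0  # kJ/mol
    x = hc_nu / (constants.kB * T)
    with np.errstate(over="ignore"):
        occ = np.where(x > 0, 1.0 / np.expm1(np.clip(x, 1e-300, 700.0)), np.nan)
    # nu -> 0 equipartition limit: e_vib per mode -> kB*T
    term = np.where(x > 1e-12, hc_nu * occ, constants.kB * T)
    e_vib = constants.NA * term.sum() / 1000.0
    zpe_s = scale * zpe
    e_vib_s = scale * e_vib if scale_evib else e_vib
    return ThermalCorrection(zpe=zpe_s, e_vib=e_vib_s, total=zpe_s + e_vib_s, T=T)


def isotope_substitute(
    system: HarmonicSystem, atom_indices: Sequence[int], new_mass: float
) -> HarmonicSystem:
    """Replace the masses of selected atoms, keeping the Hessian fixed.

    This is the mass-substitution route to kinetic isotope effects: the
    potential-energy surface (Hessian) is isotope independent, only the
    mass-weighting changes the frequencies.
    """
    masses = system.masses.copy()
    for i in atom_indices:
        if not 0 <= i < system.n_atoms:
            raise IndexError(f"atom index {i} out of range (N={system.n_atoms})")
        masses[i] = new_mass
    return HarmonicSystem(
        masses=masses, hessian=system.hessian, labels=system.labels, coords=system.coords
    )


def eyring_rate(
    barrier_kj_mol: float,
    T: float = CONSTANTS.T_default,
    kappa: float | None = None,
    constants: Constants = CONSTANTS,
) -> float:
    """Transition-state-theory rate constant (s⁻¹) for a barrier in kJ/mol.

    Negative barriers are allowed (the prefactor then underestimates a
    barrierless rate; they arise only in sensitivity scans).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if kappa is None:
        kappa = constants.kappa
    return kappa * (constants.kB * T / constants.h) * math.exp(
        -barrier_kj_mol * 1000.0 / (constants.R * T)
    )


def kie_from_barriers(
    barrier_ref_kj_mol: float,
    barrier_iso_kj_mol: float,
    T: float = CONSTANTS.T_default,
    constants: Constants = CONSTANTS,
) -> float:
    """KIE = k(reference)/k(isotope-substituted) = exp(ΔΔE‡/RT).

    Values below 1 are inverse secondary effects (the labelled reaction is
    faster, typical of sp²→sp³ rehybridisation at the labelled centre).
    """
    if T <= 0:
        raise ValueError("T must be positive")
    return math.exp(
        (barrier_iso_kj_mol - barrier_ref_kj_mol) * 1000.0 / (constants.R * T)
    )


def barrier_from_energies(
    e_elec_ts: float,
    e_elec_min: float,
    corr_ts: ThermalCorrection,
    corr_min: ThermalCorrection,
) -> float:
    """Δ(E+thermal) barrier (kJ/mol) from electronic energies and corrections."""
    return (e_elec_ts + corr_ts.total) - (e_elec_min + corr_min.total)


# ---------------------------------------------------------------------------
# plain-text Hessian file format:
#   line 1: atom count N
#   N lines: "element mass_amu x y z"   (coordinates in bohr)
#   3N x 3N whitespace-separated Hessian in hartree/bohr^2
# ---------------------------------------------------------------------------

def read_hessian_file(path: str | Path) -> HarmonicSystem:
    tokens_per_line = [ln.split() for ln in Path(path).read_text().splitlines()
                       if ln.strip() and not ln.lstrip().startswith("#")]
    if not tokens_per_line:
        raise ValueError(f"{path}: empty Hessian file")
    try:
        n = int(tokens_per_line[0][0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}: first line must be the atom count") from exc
    if len(tokens_per_line) < 1 + n:
        raise ValueError(f"{path}: expected {n} atom lines")
    labels, masses, coords = [], [], []
    for row in tokens_per_line[1 : 1 + n]:
        if len(row) != 5:
            raise ValueError(f"{path}: atom lines must be 'element mass x y z'")
        labels.append(row[0])
        masses.append(float(row[1]))
        coords.append([float(v) for v in row[2:5]])
    flat = [float(v) for row in tokens_per_line[1 + n :] for v in row]
    if len(flat) != (3 * n) ** 2:
        raise ValueError(
            f"{path}: expected {(3 * n) ** 2} Hessian entries, got {len(flat)}"
        )
    hessian = np.array(flat).reshape(3 * n, 3 * n)
    return HarmonicSystem(
        masses=np.array(masses), hessian=hessian,
        labels=tuple(labels), coords=np.array(coords),
    )


def write_hessian_file(system: HarmonicSystem, path: str | Path) -> None:
    n = system.n_atoms
    labels = system.labels or ("X",) * n
    coords = system.coords if system.coords is not None else np.zeros((n, 3))
    lines = [str(n)]
    for i in range(n):
        x, y, z = coords[i]
        lines.append(f"{labels[i]} {system.masses[i]:.10g} {x:.10g} {y:.10g} {z:.10g}")
    for row in system.hessian:
        lines.append(" ".join(f"{v:.12e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
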