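"""Seeded generators for every input class the analysis pipeline consumes.

Each generator is a pure function of its configuration: a fixed seed yields
byte-identical output, via a single explicitly-seeded RNG stream per call
(no global RNG state).  Noise models follow detector behaviour: additive
Gaussian for EPR intensities, multiplicative log-normal for MS ion counts,
Gaussian perturbations for barrier tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import epr as _epr
from . import msdeconv as _ms
from . import simulate as _sim
from .network import BarrierRecord, canonical_barriers
from .thermo import HarmonicSystem

__all__ = [
    "GeneratorConfig",
    "gen_barrier_table",
    "gen_epr_dataset",
    "gen_ms_timeseries",
    "gen_toy_hessian",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Common knobs of the synthetic generators.

    ``noise_rms`` is a fraction of the signal scale (peak-to-peak amplitude
    for EPR, multiplicative log-sigma for MS); ``barrier_sigma_kj_mol`` the
    standard deviation of Gaussian barrier perturbations.
    """

    seed: int = 0
    noise_rms: float = 0.0
    replicate_count: int = 1
    barrier_sigma_kj_mol: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_rms < 0 or self.barrier_sigma_kj_mol < 0:
            raise ValueError("noise levels must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_barrier_table(config: GeneratorConfig, base_form: str = "ES") -> list[BarrierRecord]:
    """Canonical barrier table with independent Gaussian perturbations.

    ``barrier_sigma_kj_mol = 0`` returns the canonical table exactly.
    """
    rng = config.rng()
    records = canonical_barriers(base_form)
    if config.barrier_sigma_kj_mol == 0:
        return records
    noise = rng.normal(0.0, config.barrier_sigma_kj_mol, size=len(records))
    return [
        BarrierRecord(r.enzyme_form, r.step_kind, r.site, r.isotope,
                      r.gly_source, r.barrier + dn)
        for r, dn in zip(records, noise)
    ]


def gen_epr_dataset(
    config: GeneratorConfig,
    c_H: float,
    c_D: float,
    g_iso: float = 2.0034,
    microwave_freq_GHz: float = 9.4,
    hyperfine_mT: float = 1.5,
    linewidth_mT: float = 0.5,
    n_points: int = 1024,
    span_mT: float = 12.0,
) -> tuple[_epr.Spectrum, _epr.Spectrum, _epr.Spectrum]:
    """(composite, basis_H, basis_D): a noisy two-component EPR mixture.

    The protiated basis is the 1.5 mT doublet, the deuterated one the
    collapsed triplet; the composite is c_H·basis_H + c_D·basis_D plus
    additive Gaussian noise whose RMS is ``noise_rms`` of the noiseless
    composite's peak-to-peak amplitude.
    """
    if c_H < 0 or c_D < 0:
        raise ValueError("mixing coefficients must be non-negative")
    rng = config.rng()
    center = _epr.field_center_from_g(g_iso, microwave_freq_GHz)
    axis = np.linspace(center - span_mT / 2.0, center + span_mT / 2.0, n_points)
    model_h = _epr.SpectrumModel(
        g_iso=g_iso, microwave_freq_GHz=microwave_freq_GHz,
        hyperfine_mT=hyperfine_mT, nucleus="H", linewidth_mT=linewidth_mT,
    )
    model_d = _epr.SpectrumModel(
        g_iso=g_iso, microwave_freq_GHz=microwave_freq_GHz,
        hyperfine_mT=hyperfine_mT, nucleus="D", linewidth_mT=linewidth_mT,
    )
    basis_h = _epr.simulate_spectrum(model_h, axis)
    basis_d = _epr.simulate_spectrum(model_d, axis)
    clean = c_H * basis_h.intensity + c_D * basis_d.intensity
    pp = clean.max() - clean.min()
    noisy = clean + config.noise_rms * pp * rng.standard_normal(axis.size)
    composite = _epr.Spectrum(
        field_mT=axis, intensity=noisy,
        meta={"c_H": c_H, "c_D": c_D, "noise_rms": config.noise_rms,
              "seed": config.seed},
    )
    return composite, basis_h, basis_d


def gen_ms_timeseries(
    config: GeneratorConfig,
    k_a: float,
    k_b: float,
    c0_uM: float,
    times_min: np.ndarray,
    formula: str = "C11H11O4",
    base_mz: int = 207,
    calibration_slope: float = 1.0,
) -> "np.recarray":
    """SIM intensity rows (time_min, mz, intensity) for a deuteration time course.

    d0/d1/d2 concentrations follow the sequential exchange kinetics, each
    species is folded through the natural-abundance isotope pattern of
    ``formula``, scaled by ``calibration_slope``, and multiplied by log-normal
    noise exp(noise_rms·N(0,1)).
    """
    rng = config.rng()
    times_min = np.asarray(times_min, dtype=float)
    conc = _sim.product_deuteration(k_a, k_b, c0_uM, times_min * 60.0)
    pattern = _ms.isotope_pattern(formula, n_offsets=3)
    rows = []
    for j, t in enumerate(times_min):
        amounts = [conc["d0"][j], conc["d1"][j], conc["d2"][j]]
        channels = _ms.fold_amounts(amounts, pattern) * calibration_slope
        for offset, intensity in enumerate(channels):
            if config.noise_rms > 0:
                intensity = intensity * np.exp(
                    config.noise_rms * rng.standard_normal()
                )
            rows.append((t, base_mz + offset, intensity))
    return np.rec.fromrecords(
        rows, names="time_min,mz,intensity",
        formats="f8,i8,f8",
    )


def gen_toy_hessian(
    config: GeneratorConfig,
    n_atoms: int = 2,
    spring_constants: np.ndarray | None = None,
    masses: np.ndarray | None = None,
) -> HarmonicSystem:
    """Chain-of-springs Hessian with analytically known normal modes.

    Atoms sit along x with nearest-neighbour springs (hartree/bohr²); the y/z
    blocks are zero, so 2N modes are exactly zero and the x modes follow the
    tridiagonal spring-chain eigenproblem.  Unsupplied spring constants and
    masses are drawn from the seeded RNG.
    """
    rng = config.rng()
    if n_atoms < 1:
        raise ValueError("need at least one atom")
    if spring_constants is None:
        spring_constants = rng.uniform(0.1, 1.0, size=max(n_atoms - 1, 0))
    k = np.asarray(spring_constants, dtype=float)
    if k.size != n_atoms - 1:
        raise ValueError("need one spring constant per adjacent pair")
    if masses is None:
        masses = rng.uniform(1.0, 16.0, size=n_atoms)
    masses = np.asarray(masses, dtype=float)
    hessian = np.zeros((3 * n_atoms, 3 * n_atoms))
    for i, ki in enumerate(k):
        a, b = 3 * i, 3 * (i + 1)  # x components of atoms i, i+1
        hessian[a, a] += ki
        hessian[b, b] += ki
        hessian[a, b] -= ki
        hessian[b, a] -= ki
    coords = np.zeros((n_atoms, 3))
    coords[:, 0] = np.arange(n_atoms, dtype=float) * 2.0  # bohr spacing
    return HarmonicSystem(
        masses=masses, hessian=hessian,
        labels=tuple("X" for _ in range(n_atoms)), coords=coords,
    )
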