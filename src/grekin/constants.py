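"""Physical constants and unit conversions.

CODATA 2018 values throughout.  The default temperature is 303 K and the
transmission coefficient is unity, matching the conditions under which the
elementary rate constants of the thiyl/glycyl hydrogen-transfer steps are
evaluated.  The harmonic frequency scaling factor 0.9806 is the standard
B3LYP/6-31G(d) correction of Scott and Radom.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "Constants",
    "CONSTANTS",
    "AMU_KG",
    "HARTREE_J",
    "BOHR_M",
    "GAMMA_H_OVER_GAMMA_D",
]

#: atomic mass unit, kg
AMU_KG = 1.66053906660e-27
#: Hartree energy, J
HARTREE_J = 4.3597447222071e-18
#: Bohr radius, m
BOHR_M = 5.29177210903e-11
#: ratio of the proton to deuteron nuclear gyromagnetic ratio;
#: hyperfine couplings scale inversely with this on H -> D substitution.
GAMMA_H_OVER_GAMMA_D = 6.514


@dataclass(frozen=True)
class Constants:
    """Bundle of physical constants and model defaults.

    All SI except where noted.  ``R`` is derived from ``kB * NA`` and the two
    agree to better than 6 significant figures by construction.
    """

    kB: float = 1.380649e-23          # Boltzmann constant, J/K
    h: float = 6.62607015e-34         # Planck constant, J s
    NA: float = 6.02214076e23         # Avogadro constant, 1/mol
    c: float = 2.99792458e10          # speed of light, cm/s (spectroscopy units)
    muB: float = 9.2740100783e-24     # Bohr magneton, J/T
    T_default: float = 303.0          # K
    kappa: float = 1.0                # transmission coefficient
    freq_scale: float = 0.9806        # harmonic frequency scaling factor
    R: float = field(init=False)      # gas constant, J/mol/K

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", self.kB * self.NA)

    def with_(self, **kwargs) -> "Constants":
        """Return a copy with selected fields overridden (``R`` re-derived)."""
        return replace(self, **kwargs)


#: module-level default constant set
CONSTANTS = Constants()
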