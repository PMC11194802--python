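"""Isotopologue bookkeeping for the LC-MS read-out of product deuteration.

Deuterium incorporated at C3 of benzylsuccinate shifts the [M-H]⁻
quasi-molecular ion from m/z 207 to 208 (d1) and 209 (d2) — the same channels
that carry the natural ¹³C/²H/¹⁷O/¹⁸O satellites of the lighter species.
Quantifying the labelled species therefore requires deconvoluting the SIM
intensities with the natural-abundance isotope pattern of the ion's elemental
formula (a lower-triangular linear system solved by forward substitution).
Nominal-mass (unit-resolution) arithmetic is used throughout, matching the
SIM channel design.

Also here: specific-activity arithmetic for extract assays, fragmentation
m/z bookkeeping (water/HDO/CO2 losses), and ordinary linear calibration.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ElementalFormula",
    "IsotopePattern",
    "AssaySetup",
    "NATURAL_ABUNDANCES",
    "isotope_pattern",
    "deconvolute_deuteration",
    "specific_activity",
    "activity_ratio",
    "fragment_mz",
    "linear_calibration",
    "LinearCalibration",
]

#: natural isotopic abundances by nominal-mass offset (IUPAC representative
#: values): 13C 1.07%, 2H 0.0115%, 17O 0.038%, 18O 0.205%.
NATURAL_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "O": (0.99757, 0.00038, 0.00205),
    "N": (0.99636, 0.00364),
    "S": (0.9499, 0.0075, 0.0425),
    # deuterium as an explicit label (monoisotopic by construction)
    "D": (1.0,),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → count map with charge (e.g. C11H11O4 for benzylsuccinate [M-H]⁻)."""

    counts: dict[str, int]
    charge: int = -1

    def __post_init__(self) -> None:
        if not self.counts or all(v == 0 for v in self.counts.values()):
            raise ValueError("formula must contain at least one atom")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("element counts must be non-negative")

    @classmethod
    def parse(cls, formula: str, charge: int = -1) -> "ElementalFormula":
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(counts=counts, charge=charge)


@dataclass(frozen=True)
class IsotopePattern:
    """Relative abundances of the M, M+1, M+2, … nominal-mass isotopologues."""

    offsets: tuple[int, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances)
        if np.any(a < 0):
            raise ValueError("abundances must be non-negative")
        if abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


@dataclass(frozen=True)
class AssaySetup:
    """Volumes/protein/duration of a cell-free extract assay."""

    total_volume_mL: float = 1.0
    extract_volume_mL: float = 0.2
    protein_conc_mg_mL: float = 39.0
    duration_min: float = 240.0

    def __post_init__(self) -> None:
        if min(self.total_volume_mL, self.extract_volume_mL,
               self.protein_conc_mg_mL, self.duration_min) <= 0:
            raise ValueError("all assay parameters must be positive")
        if self.extract_volume_mL > self.total_volume_mL:
            raise ValueError("extract volume cannot exceed total volume")


def isotope_pattern(
    formula: ElementalFormula | str,
    abundance_table: Mapping[str, Sequence[float]] | None = None,
    n_offsets: int = 3,
) -> IsotopePattern:
    """Natural-abundance isotope pattern of a formula by elemental convolution.

    Each element contributes the n-fold self-convolution of its single-atom
    pattern; element patterns are convolved together, truncated to
    ``n_offsets`` and renormalised.
    """
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    table = dict(NATURAL_ABUNDANCES if abundance_table is None else abundance_table)
    pattern = np.array([1.0])
    for element, count in formula.counts.items():
        if element not in table:
            raise KeyError(f"no abundance data for element {element!r}")
        single = np.asarray(table[element], dtype=float)
        single = single / single.sum()
        for _ in range(count):
            pattern = np.convolve(pattern, single)[:n_offsets]
    pattern = pattern[:n_offsets]
    if pattern.size < n_offsets:
        pattern = np.pad(pattern, (0, n_offsets - pattern.size))
    pattern = pattern / pattern.sum()
    return IsotopePattern(
        offsets=tuple(range(n_offsets)), abundances=tuple(pattern)
    )


def fold_amounts(amounts: Sequence[float], pattern: IsotopePattern) -> np.ndarray:
    """Forward model: channel intensities from labelled-species amounts.

    I(M+j) = Σ_i amount_i · a_{j−i}, with as many channels as species.
    """
    a = np.asarray(pattern.abundances)
    d = np.asarray(amounts, dtype=float)
    n = d.size
    out = np.zeros(n)
    for j in range(n):
        for i in range(j + 1):
            if j - i < a.size:
                out[j] += d[i] * a[j - i]
    return out


def deconvolute_deuteration(
    intensities: Sequence[float],
    pattern: IsotopePattern,
    noise_floor: float = 0.0,
) -> np.ndarray:
    """Labelled-species amounts from SIM channel intensities (M, M+1, M+2).

    Solves the lower-triangular mixing system by forward substitution.  Small
    negative solutions (|value| ≤ ``noise_floor``) are clamped to zero with a
    warning; larger negatives are clamped too but indicate an inconsistent
    pattern or baseline.
    """
    y = np.asarray(intensities, dtype=float)
    if np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    a = np.asarray(pattern.abundances)
    if a.size < y.size:
        raise ValueError(
            f"pattern covers offsets 0-{a.size - 1}, need 0-{y.size - 1}"
        )
    if a[0] == 0:
        raise ValueError("pattern monoisotopic abundance a0 must be nonzero")
    d = np.zeros_like(y)
    for j in range(y.size):
        acc = y[j]
        for i in range(j):
            acc -= d[i] * a[j - i]
        d[j] = acc / a[0]
    if np.any(d < 0):
        worst = float(d.min())
        level = "within noise" if abs(worst) <= noise_floor else "beyond noise floor"
        warnings.warn(
            f"negative deconvoluted amount {worst:.3g} ({level}); clamped to 0",
            stacklevel=2,
        )
        d = np.clip(d, 0.0, None)
    return d


def specific_activity(amount_uM: float, setup: AssaySetup) -> float:
    """Specific activity in pmol·min⁻¹·(mg extract protein)⁻¹.

    amount (µM) × total volume (mL) gives nmol of product; divided by the
    assay duration and the milligrams of extract protein
    (extract volume × protein concentration), converted to pmol.
    """
    if amount_uM < 0:
        raise ValueError("amount must be non-negative")
    nmol = amount_uM * setup.total_volume_mL  # µM * mL = nmol
    mg_protein = setup.extract_volume_mL * setup.protein_conc_mg_mL
    return nmol * 1e3 / setup.duration_min / mg_protein


def activity_ratio(a: float, b: float) -> float:
    """Fold ratio a/b of two rates (same units)."""
    if b == 0:
        raise ValueError("reference rate must be nonzero")
    return a / b


_LOSS_DELTA = {"H2O": 18, "HDO": 19, "CO2": 44}


def fragment_mz(parent_mz: int, n_deuterons_at_C3: int, loss: str) -> int:
    """Nominal fragment m/z after a neutral loss from the [M-H]⁻ ion.

    Water loss takes an H from C3; HDO loss requires at least one deuteron
    there.  E.g. 207 − H2O → 189, 208 − HDO → 189, 209 − HDO → 190.
    """
    if loss not in _LOSS_DELTA:
        raise ValueError(f"unknown loss {loss!r}; expected one of {list(_LOSS_DELTA)}")
    if n_deuterons_at_C3 not in (0, 1, 2):
        raise ValueError("n_deuterons_at_C3 must be 0, 1 or 2")
    if loss == "HDO" and n_deuterons_at_C3 == 0:
        raise ValueError("HDO loss requires at least one deuteron at C3")
    if loss == "H2O" and n_deuterons_at_C3 == 2:
        raise ValueError("H2O loss from C3 requires a protium there")
    return parent_mz - _LOSS_DELTA[loss]


@dataclass(frozen=True)
class LinearCalibration:
    """Ordinary least-squares calibration line response = slope·conc + intercept."""

    slope: float
    intercept: float

    def predict_response(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept

    def predict(self, response: float) -> float:
        """Inverse prediction: concentration from a measured response."""
        if self.slope == 0:
            raise ValueError("zero slope; cannot invert calibration")
        return (response - self.intercept) / self.slope


def linear_calibration(
    concentrations: Sequence[float], responses: Sequence[float]
) -> LinearCalibration:
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two concentration/response pairs")
    if np.unique(x).size < 2:
        raise ValueError("calibration requires at least two distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearCalibration(slope=float(slope), intercept=float(intercept))
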