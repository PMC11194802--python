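"""Steady-state observed H/D-exchange constants and elementary rate tables.

Isotope exchange at the glycyl radical proceeds through a two-step pathway:
a reversible addition of the solvent isotope from the cysteine sulfhydryl to
one face of the radical (k1, reversed by k−1) followed by abstraction of the
*other* Cα substituent by the thiyl radical (k2).  The second step is
irreversible with respect to isotope content because the abstracted atom
equilibrates with the bulk solvent.  The observed first-order constant for
the reactant → product conversion is, in the default slow-eigenvalue
approximation,

    k_obs = k1·k2 / (k1 + k−1 + k2),

the small-k_obs limit of the slow eigenvalue of the explicit three-state rate
matrix.  The textbook pre-equilibrium flux form k1·k2/(k−1 + k2) and the
exact slow eigenvalue are available as alternative variants.

Two pathways exist per direction (via the R- or the S-monodeuterated closed
glycine); the faster one dominates the observable exchange.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

from .constants import CONSTANTS
from .network import BarrierRecord, canonical_barriers
from .thermo import eyring_rate

__all__ = [
    "PathwayResult",
    "RateEntry",
    "ExchangeConstants",
    "VARIANTS",
    "steady_state_kobs",
    "pathway_rates",
    "exchange_constants",
    "rate_table",
    "fold_preference",
]

VARIANTS = ("slow-eigenvalue-approx", "pre-equilibrium-flux", "exact-slow-eigenvalue")


@dataclass(frozen=True)
class PathwayResult:
    """Elementary and observed constants of one two-step exchange pathway."""

    pathway: str
    k1: float         # s^-1, addition of the solvent isotope
    k_minus1: float   # s^-1, reverse abstraction of the added atom
    k2: float         # s^-1, abstraction of the other substituent (irreversible)
    k_obs: float      # s^-1
    formula_variant: str


@dataclass(frozen=True)
class RateEntry:
    """One elementary step with its Eyring rate and intrinsic KIE."""

    record: BarrierRecord
    rate: float
    ikie: float


@dataclass(frozen=True)
class ExchangeConstants:
    """Both pathway constants for one enzyme form and exchange direction."""

    enzyme_form: str
    direction: str
    T: float
    pathways: tuple[PathwayResult, PathwayResult]
    preferred: PathwayResult
    preference_ratio: float  # preferred k_obs / other k_obs


def steady_state_kobs(
    k1: float, k_minus1: float, k2: float,
    variant: str = "slow-eigenvalue-approx",
) -> float:
    """Observed first-order constant of the reversible+irreversible two-step scheme."""
    if min(k1, k_minus1, k2) < 0:
        raise ValueError("rates must be non-negative")
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if k1 == 0 and k_minus1 == 0 and k2 == 0:
        warnings.warn("all rates zero; k_obs = 0", stacklevel=2)
        return 0.0
    if variant == "slow-eigenvalue-approx":
        denom = k1 + k_minus1 + k2
        return k1 * k2 / denom if denom > 0 else 0.0
    if variant == "pre-equilibrium-flux":
        denom = k_minus1 + k2
        return k1 * k2 / denom if denom > 0 else 0.0
    # exact slow eigenvalue of the 3-state rate matrix; the discriminant is
    # non-negative for any non-negative rates since (k1+km1+k2)^2 >= 4 k1 k2.
    # The product form avoids the catastrophic cancellation of
    # (s - sqrt(s^2 - 4 k1 k2))/2 when k1 k2 << s^2.
    s = k1 + k_minus1 + k2
    disc = s * s - 4.0 * k1 * k2
    return 2.0 * k1 * k2 / (s + math.sqrt(max(disc, 0.0)))


# (direction, intermediate) -> keys of (k1, k_minus1, k2) as
# (step_kind, site, isotope, gly_source)
_PATHWAY_STEPS = {
    ("h2d", "S-GlyDH"): (
        ("addition", "si", "D", "GlyH_rad"),
        ("abstraction", "S", "D", "S-GlyDH"),
        ("abstraction", "R", "H", "S-GlyDH"),
    ),
    ("h2d", "R-GlyHD"): (
        ("addition", "re", "D", "GlyH_rad"),
        ("abstraction", "R", "D", "R-GlyHD"),
        ("abstraction", "S", "H", "R-GlyHD"),
    ),
    ("d2h", "R-GlyHD"): (
        ("addition", "re", "H", "GlyD_rad"),
        ("abstraction", "S", "H", "R-GlyHD"),
        ("abstraction", "R", "D", "R-GlyHD"),
    ),
    ("d2h", "S-GlyDH"): (
        ("addition", "si", "H", "GlyD_rad"),
        ("abstraction", "R", "H", "S-GlyDH"),
        ("abstraction", "S", "D", "S-GlyDH"),
    ),
}

_DIRECTION_ALIASES = {
    "h2d": "h2d", "H->D": "h2d", "H2D": "h2d", "H→D": "h2d",
    "d2h": "d2h", "D->H": "d2h", "D2H": "d2h", "D→H": "d2h",
}


def _norm_direction(direction: str) -> str:
    try:
        return _DIRECTION_ALIASES[direction]
    except KeyError:
        raise ValueError(f"unknown direction {direction!r}") from None


def pathway_rates(
    records: Iterable[BarrierRecord],
    direction: str,
    intermediate: str,
    T: float = CONSTANTS.T_default,
) -> tuple[float, float, float]:
    """(k1, k−1, k2) Eyring rates of one exchange pathway from a barrier set."""
    direction = _norm_direction(direction)
    by_key = {(r.step_kind, r.site, r.isotope, r.gly_source): r for r in records}
    try:
        steps = _PATHWAY_STEPS[(direction, intermediate)]
    except KeyError:
        raise ValueError(
            f"no pathway ({direction!r}, {intermediate!r})"
        ) from None
    try:
        barriers = [by_key[k].barrier for k in steps]
    except KeyError as exc:
        raise ValueError(f"incomplete barrier table: missing step {exc}") from None
    return tuple(eyring_rate(b, T) for b in barriers)  # type: ignore[return-value]


def exchange_constants(
    form: str | Iterable[BarrierRecord],
    direction: str,
    T: float = CONSTANTS.T_default,
    variant: str = "slow-eigenvalue-approx",
) -> ExchangeConstants:
    """Evaluate both exchange pathways for an enzyme form and direction.

    ``form`` is an enzyme-form name (canonical barriers) or an explicit record
    list.  Directions: ``"h2d"`` (protiated radical in D₂O) or ``"d2h"``
    (deuterated radical in H₂O).
    """
    direction = _norm_direction(direction)
    if isinstance(form, str):
        records = canonical_barriers(form)
        form_name = form
    else:
        records = list(form)
        form_name = records[0].enzyme_form if records else "?"
    results = []
    for intermediate in ("S-GlyDH", "R-GlyHD"):
        k1, km1, k2 = pathway_rates(records, direction, intermediate, T)
        kobs = steady_state_kobs(k1, km1, k2, variant)
        results.append(
            PathwayResult(
                pathway=f"{direction} via {intermediate}",
                k1=k1, k_minus1=km1, k2=k2, k_obs=kobs, formula_variant=variant,
            )
        )
    pair = (results[0], results[1])
    preferred = max(pair, key=lambda p: p.k_obs)
    other = min(pair, key=lambda p: p.k_obs)
    ratio = math.inf if other.k_obs == 0 else preferred.k_obs / other.k_obs
    return ExchangeConstants(
        enzyme_form=form_name, direction=direction, T=T,
        pathways=pair, preferred=preferred, preference_ratio=ratio,
    )


def _block(record: BarrierRecord) -> tuple[str, str]:
    return (record.step_kind, record.site)


def rate_table(
    form: str | Iterable[BarrierRecord], T: float = CONSTANTS.T_default
) -> list[RateEntry]:
    """Elementary Eyring rates and intrinsic KIEs for all 16 steps of a form.

    The iKIE reference of each block (same step kind and face/position) is its
    all-protium step — H transfer involving the fully protiated glycine — so
    the reference row has iKIE exactly 1 and deuterated rows report the
    combined primary/secondary effect relative to it.
    """
    records = canonical_barriers(form) if isinstance(form, str) else list(form)
    refs: dict[tuple[str, str], float] = {}
    for r in records:
        if r.isotope == "H" and r.gly_source in ("GlyH_rad", "GlyH2"):
            refs[_block(r)] = eyring_rate(r.barrier, T)
    entries = []
    for r in records:
        rate = eyring_rate(r.barrier, T)
        ref = refs.get(_block(r))
        ikie = ref / rate if ref is not None else math.nan
        entries.append(RateEntry(record=r, rate=rate, ikie=ikie))
    return entries


def fold_preference(
    barrier_a_kj_mol: float,
    barrier_b_kj_mol: float,
    T: float = CONSTANTS.T_default,
) -> float:
    """Rate ratio k(a)/k(b) = exp((b − a)/RT) of two Eyring steps."""
    if T <= 0:
        raise ValueError("T must be positive")
    return math.exp(
        (barrier_b_kj_mol - barrier_a_kj_mol) * 1000.0 / (CONSTANTS.R * T)
    )
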