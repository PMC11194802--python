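"""The glycyl-radical H/D-transfer reaction network.

A planar glycyl radical (Gly•) exchanges hydrogen atoms with the active-site
cysteine: "addition" steps transfer H or D from the cysteine sulfhydryl to the
*re* or *si* face of the radical, producing a closed (sp³) glycine and a thiyl
radical; "abstraction" steps remove the pro-R or pro-S substituent of a closed
glycine, regenerating the radical.  Because the sulfhydryl proton equilibrates
instantly with solvent, addition steps carry the solvent isotope (weighted by
the deuterium fraction ``solvent_fD``) and abstractions are irreversible with
respect to the isotope removed.

Six glycine states span the network: the two radicals GlyH•/GlyD• and the four
closed states GlyH2, R-GlyHD, S-GlyDH and GlyD2 (enantiomer labels of the
monodeuterated forms; by convention R-GlyHD carries H at pro-S and D at pro-R,
S-GlyDH the converse).  Each elementary step has a Δ(E+thermal) barrier in
kJ/mol and an Eyring rate at temperature T.

Canonical barrier tables are embedded for the three enzyme regimes:
substrate-bound (ES), product-bound (EP) and apoenzyme (APO).  The product of
each addition is stored as explicit data following the pathway analysis rather
than a geometric face→enantiomer rule (the published assignments for additions
to GlyD• are not consistent with the si→pro-S rule that holds for GlyH•).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .constants import CONSTANTS
from .thermo import eyring_rate

__all__ = [
    "GlyState",
    "BarrierRecord",
    "TransferEdge",
    "ExchangeNetwork",
    "GLY_STATES",
    "RADICAL_STATES",
    "CLOSED_STATES",
    "APO_PROS_PENALTY_KJ_MOL",
    "canonical_barriers",
    "load_barrier_table",
    "write_barrier_table",
    "build_network",
    "detailed_balance_check",
    "addition_product",
    "abstraction_product",
]

#: conformational penalty (kJ/mol) for reaching the apoenzyme pro-S geometry;
#: applied to apo si-face additions only when requested (default off — the
#: published apo exchange constants derive from the unpenalised barriers).
APO_PROS_PENALTY_KJ_MOL = 86.8


@dataclass(frozen=True)
class GlyState:
    """One isotopic/redox state of the active-site glycine.

    Radical states carry exactly one Cα substituent (the remaining one);
    closed (sp³) states carry two, identified by their pro-S and pro-R
    occupants.
    """

    label: str
    kind: str                 # "radical" | "closed"
    proS_occupant: str | None  # "H" | "D" | None
    proR_occupant: str | None

    def __post_init__(self) -> None:
        occupants = [o for o in (self.proS_occupant, self.proR_occupant) if o]
        expected = 1 if self.kind == "radical" else 2
        if len(occupants) != expected:
            raise ValueError(
                f"{self.label}: {self.kind} state must have {expected} occupant(s)"
            )


def _mk_states() -> dict[str, GlyState]:
    return {
        s.label: s
        for s in (
            GlyState("GlyH_rad", "radical", "H", None),
            GlyState("GlyD_rad", "radical", "D", None),
            GlyState("GlyH2", "closed", "H", "H"),
            GlyState("R-GlyHD", "closed", "H", "D"),
            GlyState("S-GlyDH", "closed", "D", "H"),
            GlyState("GlyD2", "closed", "D", "D"),
        )
    }


GLY_STATES: dict[str, GlyState] = _mk_states()
RADICAL_STATES = ("GlyH_rad", "GlyD_rad")
CLOSED_STATES = ("GlyH2", "R-GlyHD", "S-GlyDH", "GlyD2")

_FORMS = ("ES", "EP", "APO")
_ADD_SITES = ("re", "si")
_ABS_SITES = ("R", "S")


@dataclass(frozen=True)
class BarrierRecord:
    """One elementary H/D-transfer step and its Δ(E+thermal) barrier.

    ``step_kind`` is "addition" (Cys→Gly) or "abstraction" (Gly→Cys);
    ``site`` is the attacked face (re/si) for additions or the abstracted
    position (R/S) for abstractions; ``isotope`` is the transferred atom;
    ``gly_source`` is the glycine state the step starts from.
    """

    enzyme_form: str
    step_kind: str
    site: str
    isotope: str
    gly_source: str
    barrier: float  # kJ/mol

    def __post_init__(self) -> None:
        if self.enzyme_form not in _FORMS:
            raise ValueError(f"unknown enzyme form {self.enzyme_form!r}")
        if self.step_kind not in ("addition", "abstraction"):
            raise ValueError(f"unknown step kind {self.step_kind!r}")
        sites = _ADD_SITES if self.step_kind == "addition" else _ABS_SITES
        if self.site not in sites:
            raise ValueError(f"site {self.site!r} invalid for {self.step_kind}")
        if self.isotope not in ("H", "D"):
            raise ValueError(f"isotope must be H or D, got {self.isotope!r}")
        if self.gly_source not in GLY_STATES:
            raise ValueError(f"unknown glycine state {self.gly_source!r}")
        if not (self.barrier == self.barrier and abs(self.barrier) < 1e6):
            raise ValueError("barrier must be finite")

    @property
    def key(self) -> tuple[str, str, str, str, str]:
        return (self.enzyme_form, self.step_kind, self.site, self.isotope,
                self.gly_source)


# ---------------------------------------------------------------------------
# Canonical Δ(E+thermal) barriers (kJ/mol) for the three enzyme regimes.
# Keys: (step_kind, site, isotope, gly_source).  Where the two published
# tabulations disagree for ES (si H GlyD_rad and S-H R-GlyHD), the values
# consistent with the printed elementary rates are used; with these the
# forward/reverse detailed-balance residual of the affected column is zero.
# ---------------------------------------------------------------------------

_CANONICAL: dict[str, dict[tuple[str, str, str, str], float]] = {
    "ES": {
        ("addition", "re", "H", "GlyH_rad"): 40.4,
        ("addition", "re", "D", "GlyH_rad"): 43.2,
        ("addition", "re", "H", "GlyD_rad"): 39.8,
        ("addition", "re", "D", "GlyD_rad"): 42.6,
        ("addition", "si", "H", "GlyH_rad"): 62.2,
        ("addition", "si", "D", "GlyH_rad"): 64.8,
        ("addition", "si", "H", "GlyD_rad"): 61.0,
        ("addition", "si", "D", "GlyD_rad"): 64.2,
        ("abstraction", "R", "H", "GlyH2"): 72.2,
        ("abstraction", "R", "D", "R-GlyHD"): 77.4,
        ("abstraction", "R", "H", "S-GlyDH"): 72.4,
        ("abstraction", "R", "D", "GlyD2"): 77.7,
        ("abstraction", "S", "H", "GlyH2"): 95.8,
        ("abstraction", "S", "D", "S-GlyDH"): 101.0,
        ("abstraction", "S", "H", "R-GlyHD"): 95.6,
        ("abstraction", "S", "D", "GlyD2"): 101.4,
    },
    "EP": {
        ("addition", "re", "H", "GlyH_rad"): 38.8,
        ("addition", "re", "D", "GlyH_rad"): 41.5,
        ("addition", "re", "H", "GlyD_rad"): 38.1,
        ("addition", "re", "D", "GlyD_rad"): 40.8,
        ("addition", "si", "H", "GlyH_rad"): 61.9,
        ("addition", "si", "D", "GlyH_rad"): 67.8,
        ("addition", "si", "H", "GlyD_rad"): 61.2,
        ("addition", "si", "D", "GlyD_rad"): 67.1,
        ("abstraction", "R", "H", "GlyH2"): 72.5,
        ("abstraction", "R", "D", "R-GlyHD"): 77.7,
        ("abstraction", "R", "H", "S-GlyDH"): 72.7,
        ("abstraction", "R", "D", "GlyD2"): 78.0,
        ("abstraction", "S", "H", "GlyH2"): 96.4,
        ("abstraction", "S", "D", "S-GlyDH"): 104.7,
        ("abstraction", "S", "H", "R-GlyHD"): 96.6,
        ("abstraction", "S", "D", "GlyD2"): 105.0,
    },
    "APO": {
        ("addition", "re", "H", "GlyH_rad"): 107.0,
        ("addition", "re", "D", "GlyH_rad"): 109.8,
        ("addition", "re", "H", "GlyD_rad"): 106.2,
        ("addition", "re", "D", "GlyD_rad"): 109.0,
        ("addition", "si", "H", "GlyH_rad"): 80.6,
        ("addition", "si", "D", "GlyH_rad"): 80.1,
        ("addition", "si", "H", "GlyD_rad"): 83.1,
        ("addition", "si", "D", "GlyD_rad"): 82.7,
        ("abstraction", "R", "H", "GlyH2"): 99.8,
        ("abstraction", "R", "D", "R-GlyHD"): 105.0,
        ("abstraction", "R", "H", "S-GlyDH"): 99.7,
        ("abstraction", "R", "D", "GlyD2"): 104.9,
        ("abstraction", "S", "H", "GlyH2"): 2.3,
        ("abstraction", "S", "D", "S-GlyDH"): 2.4,
        ("abstraction", "S", "H", "R-GlyHD"): 7.4,
        ("abstraction", "S", "D", "GlyD2"): 7.6,
    },
}

# Product of each addition step, stored as data (see module docstring).
_ADDITION_PRODUCT: dict[tuple[str, str, str], str] = {
    ("re", "H", "GlyH_rad"): "GlyH2",
    ("re", "D", "GlyH_rad"): "R-GlyHD",
    ("si", "H", "GlyH_rad"): "GlyH2",
    ("si", "D", "GlyH_rad"): "S-GlyDH",
    ("re", "H", "GlyD_rad"): "R-GlyHD",
    ("re", "D", "GlyD_rad"): "GlyD2",
    ("si", "H", "GlyD_rad"): "S-GlyDH",
    ("si", "D", "GlyD_rad"): "GlyD2",
}

# Abstracting isotope X at position "site" from a closed state leaves the
# radical whose remaining substituent is the other occupant.
_ABSTRACTION_PRODUCT: dict[tuple[str, str, str], str] = {
    ("R", "H", "GlyH2"): "GlyH_rad",
    ("S", "H", "GlyH2"): "GlyH_rad",
    ("R", "D", "R-GlyHD"): "GlyH_rad",
    ("S", "H", "R-GlyHD"): "GlyD_rad",
    ("R", "H", "S-GlyDH"): "GlyD_rad",
    ("S", "D", "S-GlyDH"): "GlyH_rad",
    ("R", "D", "GlyD2"): "GlyD_rad",
    ("S", "D", "GlyD2"): "GlyD_rad",
}


def addition_product(site: str, isotope: str, gly_source: str) -> str:
    """Closed glycine state produced by adding ``isotope`` at ``site``."""
    try:
        return _ADDITION_PRODUCT[(site, isotope, gly_source)]
    except KeyError:
        raise KeyError(f"no addition step ({site}, {isotope}, {gly_source})") from None


def abstraction_product(site: str, isotope: str, gly_source: str) -> str:
    """Radical state produced by abstracting ``isotope`` at ``site``."""
    try:
        return _ABSTRACTION_PRODUCT[(site, isotope, gly_source)]
    except KeyError:
        raise KeyError(
            f"no abstraction step ({site}, {isotope}, {gly_source})"
        ) from None


def canonical_barriers(enzyme_form: str) -> list[BarrierRecord]:
    """The 16 canonical barrier records for an enzyme regime (ES, EP, APO)."""
    if enzyme_form not in _CANONICAL:
        raise ValueError(f"unknown enzyme form {enzyme_form!r}; expected one of {_FORMS}")
    return [
        BarrierRecord(enzyme_form, kind, site, iso, src, barrier)
        for (kind, site, iso, src), barrier in _CANONICAL[enzyme_form].items()
    ]


# ---------------------------------------------------------------------------
# CSV schema: enzyme_form,step_kind,site,isotope,gly_source,barrier_kj_mol
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["enzyme_form", "step_kind", "site", "isotope", "gly_source",
                "barrier_kj_mol"]


def load_barrier_table(path: str | Path | io.TextIOBase) -> list[BarrierRecord]:
    """Read and validate a barrier CSV (``#`` comments allowed)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"barrier table missing column(s): {', '.join(missing)}")
    records: list[BarrierRecord] = []
    seen: dict[tuple, int] = {}
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            barrier = float(row["barrier_kj_mol"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {rownum}: non-numeric barrier {row['barrier_kj_mol']!r}"
            ) from None
        try:
            rec = BarrierRecord(
                str(row["enzyme_form"]).strip(), str(row["step_kind"]).strip(),
                str(row["site"]).strip(), str(row["isotope"]).strip(),
                str(row["gly_source"]).strip(), barrier,
            )
        except ValueError as exc:
            raise ValueError(f"row {rownum}: {exc}") from None
        if rec.key in seen:
            raise ValueError(
                f"row {rownum}: duplicate record {rec.key} (first at row {seen[rec.key]})"
            )
        seen[rec.key] = rownum
        records.append(rec)
    return records


def write_barrier_table(records: Iterable[BarrierRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "enzyme_form": r.enzyme_form, "step_kind": r.step_kind,
                "site": r.site, "isotope": r.isotope, "gly_source": r.gly_source,
                "barrier_kj_mol": r.barrier,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransferEdge:
    """A directed network edge with its (solvent-weighted) Eyring rate."""

    from_state: str
    to_state: str
    record: BarrierRecord
    rate: float  # s^-1


@dataclass(frozen=True)
class ExchangeNetwork:
    """All H/D-transfer edges among the six glycine states at temperature T."""

    nodes: tuple[str, ...]
    edges: tuple[TransferEdge, ...]
    T: float
    solvent_fD: float
    apo_proS_penalty: float = 0.0

    def rate_matrix(self):
        """Dense generator matrix K (column-stochastic: dp/dt = K p)."""
        import numpy as np

        idx = {s: i for i, s in enumerate(self.nodes)}
        k = np.zeros((len(self.nodes), len(self.nodes)))
        for e in self.edges:
            k[idx[e.to_state], idx[e.from_state]] += e.rate
            k[idx[e.from_state], idx[e.from_state]] -= e.rate
        return k


def build_network(
    records: Iterable[BarrierRecord],
    T: float = CONSTANTS.T_default,
    solvent_fD: float = 1.0,
    apo_proS_penalty: float = 0.0,
) -> ExchangeNetwork:
    """Assemble the exchange network from a complete 16-record barrier set.

    Addition edges transferring D are weighted by ``solvent_fD`` and those
    transferring H by ``1 − solvent_fD`` (the sulfhydryl isotope is slaved to
    the solvent); abstraction edges are unweighted.  ``apo_proS_penalty``
    (kJ/mol) is added to apoenzyme si-face addition barriers, modelling the
    conformational cost of presenting the si face.
    """
    if not 0.0 <= solvent_fD <= 1.0:
        raise ValueError("solvent_fD must be within [0, 1]")
    records = list(records)
    forms = {r.enzyme_form for r in records}
    if len(forms) != 1:
        raise ValueError(f"records must belong to a single enzyme form, got {forms}")
    form = forms.pop()
    expected = set(_CANONICAL[form].keys())
    have = {(r.step_kind, r.site, r.isotope, r.gly_source) for r in records}
    if have != expected:
        missing = sorted(expected - have)
        extra = sorted(have - expected)
        parts = []
        if missing:
            parts.append(f"missing steps: {missing}")
        if extra:
            parts.append(f"unexpected steps: {extra}")
        raise ValueError(f"incomplete barrier set for {form}: " + "; ".join(parts))

    edges = []
    for rec in records:
        barrier = rec.barrier
        if rec.step_kind == "addition":
            if form == "APO" and rec.site == "si":
                barrier = barrier + apo_proS_penalty
            weight = solvent_fD if rec.isotope == "D" else 1.0 - solvent_fD
            to_state = addition_product(rec.site, rec.isotope, rec.gly_source)
        else:
            weight = 1.0
            to_state = abstraction_product(rec.site, rec.isotope, rec.gly_source)
        rate = weight * eyring_rate(barrier, T)
        edges.append(TransferEdge(rec.gly_source, to_state, rec, rate))
    return ExchangeNetwork(
        nodes=tuple(GLY_STATES), edges=tuple(edges), T=T,
        solvent_fD=solvent_fD, apo_proS_penalty=apo_proS_penalty,
    )


# Forward/reverse pairing through a common transition state: each addition
# column shares its TS with the abstraction column computed with the same
# isotope-substitution pattern.
_FORWARD_REVERSE_PAIRS: list[tuple[tuple[str, str, str], tuple[str, str, str]]] = [
    (("re", "H", "GlyH_rad"), ("R", "H", "GlyH2")),
    (("re", "D", "GlyH_rad"), ("R", "D", "R-GlyHD")),
    (("re", "H", "GlyD_rad"), ("R", "H", "S-GlyDH")),
    (("re", "D", "GlyD_rad"), ("R", "D", "GlyD2")),
    (("si", "H", "GlyH_rad"), ("S", "H", "GlyH2")),
    (("si", "D", "GlyH_rad"), ("S", "D", "S-GlyDH")),
    (("si", "H", "GlyD_rad"), ("S", "H", "R-GlyHD")),
    (("si", "D", "GlyD_rad"), ("S", "D", "GlyD2")),
]


def detailed_balance_check(
    records: Iterable[BarrierRecord],
    intermediate_energies: Mapping[tuple[str, str, str], float],
    reactant_energy: float = 0.0,
    tolerance: float = 0.5,
) -> dict[tuple[str, str, str], tuple[float, bool]]:
    """Thermodynamic-consistency residuals of paired forward/reverse barriers.

    For each addition step (key ``(site, isotope, gly_source)``) with forward
    barrier ΔE_f from the reactant state and reverse barrier ΔE_r from the
    thiyl intermediate, consistency requires
    ΔE_r − ΔE_f = E(reactant) − E(intermediate).  ``intermediate_energies``
    maps the forward key to the intermediate energy on the same scale as
    ``reactant_energy`` (kJ/mol).  Returns ``{key: (residual, flagged)}``;
    pairs with |residual| > ``tolerance`` are flagged.
    """
    by_key = {}
    for r in records:
        step = (r.site, r.isotope, r.gly_source)
        by_key[(r.step_kind, *step)] = r
    out: dict[tuple[str, str, str], tuple[float, bool]] = {}
    for fwd_key, rev_key in _FORWARD_REVERSE_PAIRS:
        if ("addition", *fwd_key) not in by_key and ("abstraction", *rev_key) not in by_key:
            continue
        try:
            fwd = by_key[("addition", *fwd_key)]
            rev = by_key[("abstraction", *rev_key)]
        except KeyError as exc:
            raise ValueError(f"unmatched forward/reverse pair: missing {exc}") from None
        if fwd_key not in intermediate_energies:
            raise ValueError(f"no intermediate energy supplied for {fwd_key}")
        residual = (rev.barrier - fwd.barrier) - (
            reactant_energy - intermediate_energies[fwd_key]
        )
        out[fwd_key] = (residual, abs(residual) > tolerance)
    if not out:
        raise ValueError("no forward/reverse pairs found in records")
    return out
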