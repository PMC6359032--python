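"""Antioxidant-mechanism thermodynamics.

The three radical-scavenging routes of a phenolic/alcoholic O–H site are
characterised by five enthalpy differences (all kcal/mol):

    HAT     (one step)   BDE = H(RO•) + H(H•) − H(ROH)
    SET-PT  (two steps)  IP  = H(ROH•+) + H(e−) − H(ROH)
                         PDE = H(RO•) + H(H+) − H(ROH•+)
    SPLET   (two steps)  PA  = H(RO−) + H(H+) − H(ROH)
                         ETE = H(RO•) + H(e−) − H(RO−)

They obey the closure identity

    IP + PDE = PA + ETE = BDE + [H(H+) + H(e−) − H(H•)]

which in the gas phase evaluates to BDE + 314.53 kcal/mol with the
commonly accepted reference enthalpies. The SET route shares IP with
SET-PT step 1 and is reported through IP rather than as a separate branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import ContractError, Medium, MediumError, ReactikitError

QUANTITIES = ("BDE", "IP", "PDE", "PA", "ETE")

#: first-step quantity per mechanism
MECHANISM_FIRST_STEP = {"HAT": "BDE", "SET-PT": "IP", "SPLET": "PA"}


class InferenceError(ReactikitError):
    """A cycle-completion request is under-determined."""


@dataclass(frozen=True)
class SpeciesEnthalpies:
    """Enthalpies (kcal/mol) of the four species of one O–H site: parent
    ROH, radical cation ROH•+, radical RO•, anion RO−."""

    molecule: str
    medium: str
    site: str
    H_ROH: float
    H_cation: float
    H_radical: float
    H_anion: float

    def __post_init__(self):
        for name in ("H_ROH", "H_cation", "H_radical", "H_anion"):
            v = getattr(self, name)
            if v is None or v != v:
                raise ContractError(f"missing enthalpy {name} for site {self.site}")


@dataclass
class MechanismProfile:
    """BDE/IP/PDE/PA/ETE of one site (kcal/mol) plus closure diagnostics."""

    molecule: str
    medium: str
    site: str
    BDE: float
    IP: float
    PDE: float
    PA: float
    ETE: float
    closure_residual: float = 0.0   # IP + PDE − PA − ETE
    cycle_residual: float = 0.0     # IP + PDE − BDE − K, K = H(H+)+H(e−)−H(H•)
    preferred: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {q: getattr(self, q) for q in QUANTITIES}


def mechanism_profile(s: SpeciesEnthalpies, m: Medium) -> MechanismProfile:
    """Compute the five cycle quantities of one site from species enthalpies."""
    if not m.has_references:
        raise MediumError(
            f"medium {m.name!r} lacks reference enthalpies for the cycle")
    bde = s.H_radical + m.H_hydrogen_atom - s.H_ROH
    ip = s.H_cation + m.H_electron - s.H_ROH
    pde = s.H_radical + m.H_proton - s.H_cation
    pa = s.H_anion + m.H_proton - s.H_ROH
    ete = s.H_radical + m.H_electron - s.H_anion
    profile = MechanismProfile(
        molecule=s.molecule, medium=s.medium, site=s.site,
        BDE=bde, IP=ip, PDE=pde, PA=pa, ETE=ete,
        closure_residual=ip + pde - pa - ete,
        cycle_residual=ip + pde - bde - m.cycle_constant,
    )
    profile.preferred = preferred_mechanism(profile)[0]
    return profile


def complete_cycle(known: Mapping[str, float],
                   m: Medium | None = None) -> dict[str, float]:
    """Infer missing cycle quantities from a known subset.

    Uses the two independent identities IP + PDE − BDE = K and
    PA + ETE − BDE = K (K = H(H+) + H(e−) − H(H•), available only when the
    medium carries reference enthalpies) plus their K-free consequence
    IP + PDE = PA + ETE. Returns the newly derived quantities only; raises
    :class:`InferenceError` when nothing new is derivable.
    """
    vals: dict[str, float] = {}
    for q, v in known.items():
        if q not in QUANTITIES:
            raise ContractError(f"unknown cycle quantity {q!r}")
        vals[q] = float(v)
    K = m.cycle_constant if (m is not None and m.has_references) else None

    def have(*qs):
        return all(q in vals for q in qs)

    changed = True
    while changed:
        changed = False
        # K-free identity: IP + PDE = PA + ETE
        rules = [
            ("ETE", ("IP", "PDE", "PA"), lambda: vals["IP"] + vals["PDE"] - vals["PA"]),
            ("PA", ("IP", "PDE", "ETE"), lambda: vals["IP"] + vals["PDE"] - vals["ETE"]),
            ("IP", ("PA", "ETE", "PDE"), lambda: vals["PA"] + vals["ETE"] - vals["PDE"]),
            ("PDE", ("PA", "ETE", "IP"), lambda: vals["PA"] + vals["ETE"] - vals["IP"]),
        ]
        if K is not None:
            rules += [
                ("PDE", ("BDE", "IP"), lambda: vals["BDE"] - vals["IP"] + K),
                ("IP", ("BDE", "PDE"), lambda: vals["BDE"] - vals["PDE"] + K),
                ("BDE", ("IP", "PDE"), lambda: vals["IP"] + vals["PDE"] - K),
                ("ETE", ("BDE", "PA"), lambda: vals["BDE"] - vals["PA"] + K),
                ("PA", ("BDE", "ETE"), lambda: vals["BDE"] - vals["ETE"] + K),
                ("BDE", ("PA", "ETE"), lambda: vals["PA"] + vals["ETE"] - K),
            ]
        for target, needs, rule in rules:
            if target not in vals and have(*needs):
                vals[target] = rule()
                changed = True

    derived = {q: v for q, v in vals.items() if q not in known}
    if not derived:
        missing = [q for q in QUANTITIES if q not in vals]
        raise InferenceError(
            f"cannot derive any of {missing} from {sorted(known)}"
            + ("" if K is not None else " without medium reference enthalpies"))
    return derived


def preferred_mechanism(p: MechanismProfile) -> tuple[tuple[str, ...], dict[str, float]]:
    """Thermodynamically preferred mechanism by first-step energy.

    Compares {HAT: BDE, SET-PT: IP, SPLET: PA}; returns the label(s) with
    the minimum first-step energy (exact ties return every tied label) and
    the full first-step energy map.
    """
    first_steps = {mech: getattr(p, q) for mech, q in MECHANISM_FIRST_STEP.items()}
    lowest = min(first_steps.values())
    winners = tuple(mech for mech, v in first_steps.items() if v == lowest)
    return winners, first_steps


def rank_sites(profiles: Sequence[MechanismProfile],
               quantity: str = "BDE") -> list[MechanismProfile]:
    """Sort site profiles ascending by one cycle quantity; ties by site label."""
    if quantity not in QUANTITIES:
        raise ContractError(f"unknown cycle quantity {quantity!r}")
    if not profiles:
        raise ContractError("rank_sites requires at least one site")
    return sorted(profiles, key=lambda p: (getattr(p, quantity), p.site))
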