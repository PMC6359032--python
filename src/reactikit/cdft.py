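"""Conceptual-DFT reactivity descriptors.

Global indices (hardness, softness, electronegativity, chemical potential,
electrophilicity) in the Koopmans-style frontier-orbital approximation,
condensed Fukui functions from Hirshfeld charge triplets of the N, N±1
electron states, and the NBO second-order perturbative stabilisation
formula E(2) = q_i F(i,j)² / (ε_j − ε_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .core_io import ContractError, ReactikitError
from .units import HARTREE_TO_KCAL


class DomainError(ReactikitError):
    """Input outside the mathematical domain of a descriptor."""


@dataclass(frozen=True)
class OrbitalSummary:
    """Frontier orbital energies of one molecule in one medium, in eV."""

    molecule: str
    medium: str
    E_HOMO: float
    E_LUMO: float

    def __post_init__(self):
        if not self.E_HOMO < self.E_LUMO:
            raise DomainError(
                f"E_HOMO ({self.E_HOMO}) must lie below E_LUMO ({self.E_LUMO})")


@dataclass(frozen=True)
class GlobalIndices:
    """Global reactivity indices, all in eV except softness (eV⁻¹).

    Egap = E_LUMO − E_HOMO, hardness η = Egap/2, softness s = 1/(2η),
    electronegativity χ = −(E_LUMO + E_HOMO)/2, chemical potential μ = −χ,
    electrophilicity ω = μ²/(2η).
    """

    Egap: float
    eta: float
    s: float
    chi: float
    mu: float
    omega: float


def global_indices(o: OrbitalSummary) -> GlobalIndices:
    """Compute the six global indices from a frontier-orbital summary."""
    egap = o.E_LUMO - o.E_HOMO
    eta = egap / 2.0
    s = 1.0 / (2.0 * eta)
    chi = -(o.E_LUMO + o.E_HOMO) / 2.0
    mu = -chi
    omega = mu * mu / (2.0 * eta)
    return GlobalIndices(Egap=egap, eta=eta, s=s, chi=chi, mu=mu, omega=omega)


@dataclass(frozen=True)
class ChargeTriplet:
    """Hirshfeld charges of one atom in the N, N+1 and N−1 electron states (e)."""

    atom: int | str
    q_N: float
    q_Nplus1: float
    q_Nminus1: float

    def __post_init__(self):
        for name in ("q_N", "q_Nplus1", "q_Nminus1"):
            v = getattr(self, name)
            if v is None or v != v:  # None or NaN
                raise ContractError(f"charge state {name} missing for atom {self.atom}")


@dataclass(frozen=True)
class FukuiVector:
    """Condensed Fukui indices of one atom: f⁻ (electrophilic attack),
    f⁺ (nucleophilic attack), f⁰ (radical attack), in e."""

    atom: int | str
    f_minus: float
    f_plus: float
    f_zero: float


def condensed_fukui(t: ChargeTriplet) -> FukuiVector:
    """f⁻ = q_{N−1} − q_N, f⁺ = q_N − q_{N+1}, f⁰ = (q_{N−1} − q_{N+1})/2."""
    f_minus = t.q_Nminus1 - t.q_N
    f_plus = t.q_N - t.q_Nplus1
    # (q_{N-1} - q_{N+1})/2, written so f0 = (f- + f+)/2 holds bit-exactly
    f_zero = (f_minus + f_plus) / 2.0
    return FukuiVector(atom=t.atom, f_minus=f_minus, f_plus=f_plus, f_zero=f_zero)


@dataclass(frozen=True)
class RankedAtom:
    atom: int | str
    value: float
    tied: bool


def rank_fukui(vectors: Sequence[FukuiVector],
               mode: Literal["f-", "f+", "f0"] = "f-") -> list[RankedAtom]:
    """Sort atoms ascending by the chosen Fukui index.

    Ties are broken by input order (stable sort) and flagged on every member
    of the tied group.
    """
    if not vectors:
        raise ContractError("rank_fukui requires at least one atom")
    attr = {"f-": "f_minus", "f+": "f_plus", "f0": "f_zero"}[mode]
    order = sorted(range(len(vectors)), key=lambda i: getattr(vectors[i], attr))
    values = [getattr(vectors[i], attr) for i in order]
    ranked = []
    for pos, i in enumerate(order):
        v = values[pos]
        tied = (pos > 0 and values[pos - 1] == v) or \
               (pos + 1 < len(values) and values[pos + 1] == v)
        ranked.append(RankedAtom(atom=vectors[i].atom, value=v, tied=tied))
    return ranked


@dataclass(frozen=True)
class PerturbationEntry:
    """One donor→acceptor NBO interaction: occupancy q_i, off-diagonal Fock
    element F(i,j) and diagonal elements ε_i, ε_j, all in hartree."""

    donor: str
    acceptor: str
    q_i: float
    F_ij: float
    eps_i: float
    eps_j: float

    def __post_init__(self):
        if self.q_i < 0:
            raise ContractError("orbital occupancy q_i must be non-negative")
        if self.eps_j == self.eps_i:
            raise ContractError("degenerate diagonal elements (eps_j == eps_i)")


def e2_stabilization(p: PerturbationEntry) -> float:
    """Second-order stabilisation energy E(2) in kcal/mol."""
    gap = p.eps_j - p.eps_i
    if gap <= 0:
        raise DomainError(
            "donor→acceptor entry requires eps_j > eps_i "
            f"(got gap {gap})")
    e2_hartree = p.q_i * p.F_ij ** 2 / gap
    return e2_hartree * HARTREE_TO_KCAL
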