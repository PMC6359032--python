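"""QTAIM bond-critical-point energetics and hydrogen-bond classification.

At a bond critical point the local virial relation ¼∇²ρ = 2G + V ties the
density Laplacian to the kinetic (G ≥ 0) and potential (V < 0) energy
densities. The total energy density is H = G + V; the hydrogen-bond
interaction energy is estimated as E_HB = ½V. Hydrogen bonds are graded on
the Rozas scale: weak (∇²ρ > 0, H > 0, |E_HB| < 12 kcal/mol), medium
(∇²ρ > 0, H < 0, 12 ≤ |E_HB| < 24) and strong (∇²ρ < 0, H < 0,
|E_HB| ≥ 24); closed-shell hydrogen bonding additionally shows
ρ ∈ (0.002, 0.04) and ∇²ρ ∈ (0.02, 0.15) a.u.

E_HB is computed in a.u. and reported in kJ/mol (the scale the reference
tables print), while the Rozas thresholds are applied to its magnitude in
kcal/mol (the scale the classification was published on).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cdft import DomainError
from .core_io import ContractError, MoleculeGeometry
from .units import HARTREE_TO_KCAL, HARTREE_TO_KJ, KCAL_TO_KJ

#: Rozas |E_HB| thresholds, kcal/mol
WEAK_MEDIUM_THRESHOLD_KCAL = 12.0
MEDIUM_STRONG_THRESHOLD_KCAL = 24.0

#: qualitative closed-shell hydrogen-bond windows, a.u.
RHO_RANGE = (0.002, 0.04)
LAP_RANGE = (0.02, 0.15)


class GeometryError(ContractError):
    """Degenerate atomic geometry (coincident atoms)."""


@dataclass
class BCPRecord:
    """Topological properties and derived energetics at one bond critical point."""

    bond: str
    rho: float            # a.u.
    lap: float            # ∇²ρ, a.u.
    V: float              # a.u.
    G: float              # a.u.
    H_BCP: float          # G + V, a.u.
    E_HB: float           # ½V, kJ/mol
    virial_residual: float  # ¼∇²ρ − 2G − V, a.u.
    hb_class: str = "unclassified"
    in_qualitative_range: bool = False
    diagnostics: str = ""


def bcp_energetics(rho: float, lap: float, V: float, G: float) -> dict[str, float]:
    """Derived energetics at a BCP: H_BCP (a.u.), E_HB (kJ/mol), virial residual.

    The residual ¼∇²ρ − 2G − V is zero for exact fields; on rounded table
    data it measures print consistency.
    """
    if G < 0:
        raise DomainError(f"kinetic energy density G must be >= 0 (got {G})")
    h_bcp = G + V
    e_hb_au = 0.5 * V
    residual = 0.25 * lap - 2.0 * G - V
    return {
        "H_BCP": h_bcp,
        "E_HB": e_hb_au * HARTREE_TO_KJ,
        "E_HB_kcal": e_hb_au * HARTREE_TO_KCAL,
        "virial_residual": residual,
    }


def classify_strength(lap: float, h_bcp: float, e_hb: float,
                      unit: str = "kJ/mol") -> tuple[str, bool, str]:
    """Rozas class from the Laplacian sign, H sign and |E_HB| magnitude.

    ``unit`` names the unit E_HB is supplied in ('a.u.', 'kcal/mol' or
    'kJ/mol'); the class is invariant to that choice. Returns
    (class, consistent, diagnostics).
    """
    unit_key = unit.strip().lower()
    to_kcal = {"a.u.": HARTREE_TO_KCAL, "au": HARTREE_TO_KCAL,
               "kcal/mol": 1.0, "kj/mol": 1.0 / KCAL_TO_KJ}
    if unit_key not in to_kcal:
        raise ContractError(f"unknown E_HB unit {unit!r}")
    mag_kcal = abs(e_hb) * to_kcal[unit_key]

    if lap > 0 and h_bcp > 0:
        sign_class = "weak"
    elif lap > 0 and h_bcp < 0:
        sign_class = "medium"
    elif lap < 0 and h_bcp < 0:
        sign_class = "strong"
    else:
        return ("unclassified", False,
                f"sign pattern lap={lap:+.3g}, H={h_bcp:+.3g} matches no class")

    if mag_kcal < WEAK_MEDIUM_THRESHOLD_KCAL:
        mag_class = "weak"
    elif mag_kcal < MEDIUM_STRONG_THRESHOLD_KCAL:
        mag_class = "medium"
    else:
        mag_class = "strong"

    if sign_class == mag_class:
        return (sign_class, True, "")
    return ("unclassified", False,
            f"sign pattern suggests {sign_class} but |E_HB| = "
            f"{mag_kcal:.2f} kcal/mol suggests {mag_class}")


def classify_hbond(record: BCPRecord) -> BCPRecord:
    """Attach the Rozas class and the qualitative ρ/∇²ρ range flag in place."""
    cls, _, diag = classify_strength(record.lap, record.H_BCP, record.E_HB,
                                     unit="kJ/mol")
    record.hb_class = cls
    record.diagnostics = diag
    record.in_qualitative_range = (
        RHO_RANGE[0] < record.rho < RHO_RANGE[1]
        and LAP_RANGE[0] < record.lap < LAP_RANGE[1])
    return record


def evaluate_bcp(bond: str, rho: float, lap: float, V: float, G: float) -> BCPRecord:
    """Full per-point pipeline: energetics then classification."""
    d = bcp_energetics(rho, lap, V, G)
    record = BCPRecord(bond=bond, rho=rho, lap=lap, V=V, G=G,
                       H_BCP=d["H_BCP"], E_HB=d["E_HB"],
                       virial_residual=d["virial_residual"])
    return classify_hbond(record)


def recover_G(lap: float, V: float) -> float:
    """Kinetic energy density implied by the virial relation: G = (¼∇²ρ − V)/2."""
    return (0.25 * lap - V) / 2.0


@dataclass(frozen=True)
class HBondGeometry:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # H...A, Å
    angle: float     # D–H...A, degrees


def hbond_geometry(g: MoleculeGeometry, donor: int, hydrogen: int,
                   acceptor: int) -> HBondGeometry:
    """H...A distance and D–H...A angle (vertex at H) from 1-based indices."""
    if len({donor, hydrogen, acceptor}) != 3:
        raise ContractError("donor, hydrogen and acceptor must be distinct")
    by_index = {a.index: a for a in g.atoms}
    try:
        d = by_index[donor].position
        h = by_index[hydrogen].position
        a = by_index[acceptor].position
    except KeyError as exc:
        raise ContractError(f"atom index {exc.args[0]} not in molecule") from exc
    v_hd = d - h
    v_ha = a - h
    n_hd = np.linalg.norm(v_hd)
    n_ha = np.linalg.norm(v_ha)
    if n_hd == 0 or n_ha == 0:
        raise GeometryError("coincident atoms in hydrogen-bond triple")
    cosang = float(np.dot(v_hd, v_ha) / (n_hd * n_ha))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return HBondGeometry(donor=donor, hydrogen=hydrogen, acceptor=acceptor,
                         distance=float(n_ha), angle=angle)
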