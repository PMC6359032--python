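"""Unit constants and converters.

Internal convention: energies in hartree, lengths in Bohr for all density
work; Å at XYZ boundaries, eV / kcal/mol / kJ/mol at table boundaries.
"""

from __future__ import annotations

HARTREE_TO_EV = 27.2114
HARTREE_TO_KCAL = 627.509
HARTREE_TO_KJ = 2625.50
BOHR_TO_ANGSTROM = 0.529177
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

KCAL_TO_KJ = HARTREE_TO_KJ / HARTREE_TO_KCAL


def hartree_to_ev(x: float) -> float:
    return x * HARTREE_TO_EV


def ev_to_hartree(x: float) -> float:
    return x / HARTREE_TO_EV


def hartree_to_kcal(x: float) -> float:
    return x * HARTREE_TO_KCAL


def kcal_to_hartree(x: float) -> float:
    return x / HARTREE_TO_KCAL


def hartree_to_kj(x: float) -> float:
    return x * HARTREE_TO_KJ


def kj_to_hartree(x: float) -> float:
    return x / HARTREE_TO_KJ


def angstrom_to_bohr(x: float) -> float:
    return x * ANGSTROM_TO_BOHR


def bohr_to_angstrom(x: float) -> float:
    return x * BOHR_TO_ANGSTROM


def kcal_to_kj(x: float) -> float:
    return x * KCAL_TO_KJ


def kj_to_kcal(x: float) -> float:
    return x / KCAL_TO_KJ
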