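"""Seeded generators for every input species the pipeline consumes.

The generators work backwards from targets: prescribed Fukui vectors,
cycle quantities (BDE/IP/PA) or hydrogen-bond classes are inverted through
the exact defining relations, so the corresponding analysis stage recovers
them to machine precision when noise is zero. Randomness enters only
through nuisance values (baseline charges, parent enthalpies, in-class
property draws) and optional Gaussian noise.

Reproducibility contract: every record k of a generation seeded with s
draws from the independent substream ``SeedSequence(s, spawn_key=(k,))``,
so outputs are bit-stable under reruns and adding records never perturbs
earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aim import BCPRecord, evaluate_bcp
from .cdft import ChargeTriplet, FukuiVector
from .core_io import AtomRecord, ContractError, Medium, MoleculeGeometry
from .thermo import SpeciesEnthalpies


class SpecError(ContractError):
    """A synthesis request is internally infeasible."""


@dataclass
class SynthSpec:
    """Declarative request used by the CLI `synth` subcommand."""

    seed: int
    n_records: int = 1
    targets: list = field(default_factory=list)
    noise: dict[str, float] = field(default_factory=dict)


def _rng(seed: int, record: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(record,)))


#: donor, hydrogen, acceptor (1-based) of each toy geometry's annotated motif
TOY_MOTIFS = {
    "hbonded_dimer": (1, 2, 4),
    "intramolecular_chain": (1, 2, 5),
}


def toy_geometry(kind: str, seed: int = 0) -> MoleculeGeometry:
    """Small O–H...O test systems with a guaranteed hydrogen-bond motif.

    ``hbonded_dimer`` is a water-dimer-like pair annotated with two
    fragments (donor/acceptor); ``intramolecular_chain`` is a single
    5-atom chain whose hydroxyl hydrogen points back at a chain oxygen.
    Both keep the motif inside the geometric window H...A ∈ (1.6, 2.4) Å,
    D–H...A angle > 140° for every seed (the jitter is small against the
    window margins). Motif indices are in :data:`TOY_MOTIFS`.
    """
    rng = _rng(seed, 0)
    if kind == "hbonded_dimer":
        base = np.array([
            [0.000, 0.000, 0.000],   # O1 donor
            [0.960, 0.000, 0.000],   # H2 (donor H, points at O4)
            [-0.240, 0.928, 0.000],  # H3
            [2.860, 0.050, 0.000],   # O4 acceptor
            [3.300, 0.600, 0.700],   # H5
            [3.300, -0.300, -0.800],  # H6
        ])
        jitter = rng.normal(0.0, 0.02, size=base.shape)
        jitter[1] = 0.0  # keep the donor hydrogen on the axis
        coords = base + jitter
        elements = ["O", "H", "H", "O", "H", "H"]
        fragments = {"donor": (1, 2, 3), "acceptor": (4, 5, 6)}
        name = f"hbonded_dimer_seed{seed}"
    elif kind == "intramolecular_chain":
        base = np.array([
            [0.000, 0.000, 0.000],   # O1
            [0.960, 0.000, 0.000],   # H2
            [0.500, 1.250, 0.000],   # C3
            [1.900, 1.550, 0.000],   # C4
            [2.800, 0.300, 0.000],   # O5 acceptor of H2
        ])
        jitter = rng.normal(0.0, 0.02, size=base.shape)
        jitter[1] = 0.0
        jitter[4] = 0.0
        coords = base + jitter
        elements = ["O", "H", "C", "C", "O"]
        fragments = {"chain": (1, 2, 3, 4, 5)}
        name = f"intramolecular_chain_seed{seed}"
    else:
        raise SpecError(f"unknown toy geometry kind {kind!r}")
    atoms = [AtomRecord(el, pos, i + 1)
             for i, (el, pos) in enumerate(zip(elements, coords))]
    return MoleculeGeometry(name=name, atoms=atoms, fragments=fragments)


def synth_charge_triplets(targets: Sequence[FukuiVector], seed: int = 0,
                          q_scale: float = 0.15) -> list[ChargeTriplet]:
    """Charge triplets whose condensed Fukui functions equal ``targets``.

    The neutral-state charge is a seeded nuisance draw; the ionic states
    follow exactly from q_{N−1} = q_N + f⁻ and q_{N+1} = q_N − f⁺.
    """
    out = []
    for k, t in enumerate(targets):
        rng = _rng(seed, k)
        q_n = float(rng.normal(-0.2, q_scale))
        out.append(ChargeTriplet(atom=t.atom, q_N=q_n,
                                 q_Nminus1=q_n + t.f_minus,
                                 q_Nplus1=q_n - t.f_plus))
    return out


def synth_enthalpy_set(molecule: str, site: str, medium: Medium,
                       BDE: float, IP: float, PA: float,
                       seed: int = 0) -> SpeciesEnthalpies:
    """Species enthalpies realising prescribed BDE, IP, PA in a medium.

    The parent enthalpy is a seeded nuisance value; radical, cation and
    anion enthalpies are solved from the defining relations, so the cycle
    closure (and the implied PDE and ETE) holds identically.
    """
    rng = _rng(seed, 0)
    h_roh = float(rng.normal(-1000.0, 100.0))
    return SpeciesEnthalpies(
        molecule=molecule, medium=medium.name, site=site,
        H_ROH=h_roh,
        H_radical=BDE + h_roh - medium.H_hydrogen_atom,
        H_cation=IP + h_roh - medium.H_electron,
        H_anion=PA + h_roh - medium.H_proton,
    )


#: per-class sampling boxes: V window (a.u.) and G as a multiple of |V|.
#: Chosen so the Rozas sign and magnitude conditions hold over the whole box:
#: weak keeps |E_HB| below 12 kcal/mol with H > 0, medium lands in the
#: 12–24 band with H < 0 but 2G + V > 0, strong sits beyond 24 with 2G+V < 0.
_CLASS_BOXES = {
    "weak": {"V": (-0.030, -0.015), "G_over_V": (1.05, 1.30),
             "rho": (0.005, 0.035), "lap_sign": 1},
    "medium": {"V": (-0.070, -0.042), "G_over_V": (0.60, 0.90),
               "rho": (0.030, 0.060), "lap_sign": 1},
    "strong": {"V": (-0.400, -0.200), "G_over_V": (0.10, 0.40),
               "rho": (0.150, 0.300), "lap_sign": -1},
}


def synth_bcp_records(classes: Sequence[str], seed: int = 0,
                      lap_noise: float = 0.0,
                      lap_sign: int | None = None) -> list[BCPRecord]:
    """Bond-critical-point records with prescribed hydrogen-bond classes.

    (ρ, G, V) are drawn inside the target class's region and the Laplacian
    is set to 4(2G + V) so the local virial residual is exactly zero
    (Gaussian noise of σ = ``lap_noise`` may then be added to ∇²ρ).
    ``lap_sign``, if given, must match every requested class's Laplacian
    sign; an impossible combination (e.g. strong with ∇²ρ > 0) raises
    :class:`SpecError`.
    """
    out = []
    for k, cls in enumerate(classes):
        box = _CLASS_BOXES.get(cls)
        if box is None:
            raise SpecError(f"unknown hydrogen-bond class {cls!r}")
        if lap_sign is not None and lap_sign != box["lap_sign"]:
            raise SpecError(
                f"class {cls!r} requires sign(∇²ρ) = {box['lap_sign']:+d}; "
                f"requested {lap_sign:+d} is infeasible")
        rng = _rng(seed, k)
        v = float(rng.uniform(*box["V"]))
        g = abs(v) * float(rng.uniform(*box["G_over_V"]))
        rho = float(rng.uniform(*box["rho"]))
        lap = 4.0 * (2.0 * g + v)
        if lap_noise > 0:
            lap += float(rng.normal(0.0, lap_noise))
        out.append(evaluate_bcp(bond=f"synthetic-{cls}-{k}",
                                rho=rho, lap=lap, V=v, G=g))
    return out
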