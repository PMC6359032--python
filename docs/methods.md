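# Methods

`reactikit` analyses the reactivity and radical-scavenging thermodynamics of
small polyol/amide antioxidants — its reference system is the pair of sialic
acids Neu5Gc and Neu5Ac across gas phase and six food-relevant solvents —
from *tabular electronic-structure summaries* rather than wavefunctions. A
quantum-chemistry engine produces frontier orbital energies, Hirshfeld
charges, species enthalpies and bond-critical-point properties once; every
derived quantity here is then cheap, exact arithmetic that can be tested and
audited independently of that engine.

## Conceptual-DFT indices

Given frontier orbital energies in eV, the global descriptors use the
frontier-orbital (Koopmans-style) approximation throughout:

- E_gap = E_LUMO − E_HOMO, hardness η = E_gap/2, softness s = 1/(2η)
- electronegativity χ = −(E_LUMO + E_HOMO)/2, chemical potential μ = −χ
- electrophilicity ω = μ²/(2η), reported in eV

No ΔSCF variant is offered; the reference tables are defined on this
approximation and mixing conventions would silently shift every index. The
verification tolerance against the reference table is ±0.002 eV (or eV⁻¹):
the tables are printed to 3–4 decimals and their own rounding produces
last-digit drift (e.g. the benzene row's χ computes to 3.956 against a
printed 3.955).

Condensed Fukui functions come from Hirshfeld charge triplets of the N,
N±1 electron states: f⁻ = q_{N−1} − q_N (electrophilic attack),
f⁺ = q_N − q_{N+1} (nucleophilic attack), f⁰ = (f⁻ + f⁺)/2 (radical
attack). f⁰ is computed from f⁻ and f⁺ so the averaging identity holds
bit-exactly, not merely to rounding. Site rankings sort ascending with
stable tie-breaking on input order; exact ties are flagged rather than
silently ordered. The NBO second-order stabilisation
E(2) = q_i·F(i,j)²/(ε_j − ε_i) is evaluated in hartree and reported in
kcal/mol; entries with ε_j ≤ ε_i are rejected as mis-ordered
donor/acceptor pairs.

## Antioxidant thermodynamic cycles

Per abstractable O–H site, five enthalpy differences (kcal/mol)
characterise the three scavenging routes:

    BDE = H(RO•)   + H(H•) − H(ROH)      (HAT)
    IP  = H(ROH•+) + H(e−) − H(ROH)      (SET / SET-PT step 1)
    PDE = H(RO•)   + H(H+) − H(ROH•+)    (SET-PT step 2)
    PA  = H(RO−)   + H(H+) − H(ROH)      (SPLET step 1)
    ETE = H(RO•)   + H(e−) − H(RO−)      (SPLET step 2)

These satisfy IP + PDE = PA + ETE = BDE + K with
K = H(H+) + H(e−) − H(H•). Gas-phase reference enthalpies ship as defaults
(−312.30, 0.75, 1.48 kcal/mol, hence K = 314.53); solvent references are
literature-dependent and must be supplied as configuration, so the package
never guesses them. `complete_cycle` propagates the two identities to a
fixpoint from any known subset; note that {BDE, IP, PDE} and {BDE, PA, ETE}
each pin one identity twice and leave the other branch under-determined —
they are reported as inference errors, not silently split.

The preferred mechanism compares first-step energies only
({HAT: BDE, SET-PT: IP, SPLET: PA}) and returns all labels on an exact
tie. SET shares its first step with SET-PT and is reported through IP
rather than as a fourth branch. Printed-table verification uses a
0.05 kcal/mol tolerance: the tables carry two decimals through a chain of
rounded sums.

Five of the 91 printed site rows violate the closure identity by amounts
(−0.23, ±2.00, −10.00 kcal/mol) that exceed any rounding explanation and
look like single-cell typographical slips; they are carried in the fixture
with an explicit `closure_anomaly` flag and excluded from assertions
instead of being corrected (no principled way exists to decide *which*
cell is wrong).

## QTAIM energetics and hydrogen-bond classification

At a bond critical point the local virial relation ¼∇²ρ = 2G + V holds
exactly for consistent fields; on printed (rounded) rows its residual is
asserted below 5×10⁻⁴ a.u. and doubles as a typo detector — it is what
confirms that the acetic-acid row's printed ρ = 0.2266 and G = 0.2262 are
decimal-point slips for 0.02266/0.02262. The total energy density is
H = G + V and the hydrogen-bond energy estimate E_HB = ½V.

Unit convention: E_HB is computed in a.u. and *reported in kJ/mol*,
because that is the scale the reference table actually prints
(½·(−0.02557)·2625.50 = −33.57 against a printed −33.56), even though the
accompanying text says kcal/mol. The Rozas strength thresholds, published
on the kcal/mol scale, are applied to |E_HB| in kcal/mol: weak below 12,
medium 12–24 (with ∇²ρ > 0, H < 0), strong above 24 (with ∇²ρ < 0,
H < 0). Sign pattern and magnitude are checked independently; a
contradiction (e.g. a weak sign pattern with a strong-range magnitude)
yields `unclassified` with diagnostics rather than a forced label. The
separate qualitative closed-shell window ρ ∈ (0.002, 0.04),
∇²ρ ∈ (0.02, 0.15) a.u. is reported as a boolean flag, not a gate.

## Promolecular IGM grid engine

The density surrogate is a promolecule: a superposition of spherical
free-atom densities ρ_el(r) = Σ_k c_k e^{−α_k r}. The packaged shell table
(H–Ar, `data/atomic_density.csv`) is built from Slater-rule screened
exponents, α = 2(Z−s)/n per shell, with each coefficient normalising the
pure exponential to the shell's electron count (c = N_e α³/8π); for
hydrogen this reproduces the exact 1s density e^{−2r}/π. These densities
are deliberately simple — positive, monotone, analytic — and are *not* fit
to molecular densities; absolute δg/RDG magnitudes on real molecules are
qualitative. The table is a plain CSV so users can substitute their own
fits. Gradients and Hessians are closed-form derivatives of the shells
(no finite differences; the finite-difference comparison lives in the
tests as an oracle).

Derived fields:

- RDG: S = |∇ρ| / (2(3π²)^{1/3} ρ^{4/3}); voxels with ρ ≤ 10⁻¹⁰ a.u. are
  masked (S diverges as ρ → 0), never raised.
- IGM descriptor: δg = |∇ρ^IGM| − |∇ρ| with ∇ρ^IGM the component-wise sum
  of *absolute* per-atom gradient contributions, hence δg ≥ 0 with equality
  wherever no interatomic cancellation occurs (single atoms: identically
  zero). With a fragment partition, the inter-fragment gradient keeps
  signed sums within fragments and absolute sums across them; δg_inter is
  its excess over |∇ρ| and δg_intra = δg − δg_inter. Atoms outside every
  named fragment count as singleton fragments, so an all-singleton
  partition gives δg_inter = δg.
- sign(λ₂)ρ with eigenvalues sorted ascending (standard NCI convention);
  λ₂ = 0 returns +ρ with a zero-flag.
- Scatter data pairs sign(λ₂)ρ with δg per voxel in deterministic
  z-fastest order, default window ±0.05 a.u.

Grids default to 0.2 Bohr spacing (the reference setting) with 4 Bohr
padding; the van-der-Waals surface is extracted at ρ = 0.001 e/bohr³ as
the set of voxels at-or-above the isovalue with a face neighbour below it.
The BCP locator runs damped Newton on ∇ρ = 0 from the internuclear
midpoint (step cap 0.2 Bohr, halving on non-descent of |∇ρ|²,
convergence |∇ρ| < 10⁻⁸ a.u., ≤ 200 iterations); non-convergence is
reported in the result object, not raised.

No claim is made of reproducing wavefunction-based NCI plots numerically:
the promolecular fields support property-based testing and qualitative
interaction maps only.

## Synthetic data

The generators exist to make every stage testable without a
quantum-chemistry run, and they work backwards from targets through the
exact defining relations: charge triplets from prescribed Fukui vectors,
species enthalpies from prescribed (BDE, IP, PA), and (ρ, G, V) draws
inside the Rozas class regions with ∇²ρ = 4(2G + V) so the virial residual
is exactly zero. Zero-noise outputs therefore invert to their targets at
machine precision — that is a designed identity, and passing those tests
demonstrates the algebra is implemented consistently, not that the
pipeline would agree with any particular quantum-chemistry engine.
Nuisance draws (baseline charges ~N(−0.2, 0.15), parent enthalpies
~N(−1000, 100) kcal/mol) are scaled to look like Hirshfeld charges and
species enthalpies of a mid-sized organic molecule. The toy geometries
(water-dimer-like pair; 5-atom hydroxyl chain) keep a D–H...A motif inside
the window H...A ∈ (1.6, 2.4) Å, angle > 140° for every seed because the
coordinate jitter (σ = 0.02 Å, motif-defining atoms pinned) is small
against the window margins. Every record k draws from
`SeedSequence(seed, spawn_key=(k,))`, so generation is bit-reproducible
and appending records never perturbs earlier ones.

## Fixture verification

`verify_paper_tables` recomputes every derivable cell of the packaged
reference tables: the six derived orbital-index columns (±0.002 eV), BCP
energetics (H to 10⁻⁵ a.u. against the printed column, E_HB to
0.02 kJ/mol, virial residual below 5×10⁻⁴ a.u.) and the cycle closures
(0.05 kcal/mol; gas rows additionally against K = 314.53 and a PDE
re-derivation from BDE + IP). Known print anomalies — the two
decimal-point slips, one H cell inconsistent with its own printed G + V by
1.3×10⁻⁵ a.u. (beyond the ±1.05×10⁻⁵ reachable by 5-decimal rounding
alone), and the five closure-violating rows — are reported as *flagged*,
never as passes or failures, keeping the audit trail visible. Fixtures
store the printed strings verbatim alongside the corrected parse so every
such decision is inspectable in the CSV itself.

## Problem sizes and limitations

The shipped analyses are desk-scale by design: tables of at most ~100
rows and grids of ~2×10⁵ voxels (a toy dimer at 0.2 Bohr), which run in
about a second on one core. Known limitations: no wavefunction-based
densities (so no quantitative NCI/ESP reproduction), no ring/cage critical
points, no kinetics or pKa — the thermodynamic preference among HAT/
SET-PT/SPLET says nothing about barriers — and solvent-phase cycle checks
are limited to reference-free identities unless the user supplies solvent
reference enthalpies.
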