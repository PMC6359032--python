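"""Promolecular-density grid engine for non-covalent interaction analysis.

The promolecular density is a superposition of spherical free-atom
densities, each modelled as a sum of exponential shells
ρ_el(r) = Σ_k c_k exp(−α_k r). Because the model is analytic, the density
gradient and Hessian are evaluated in closed form — no finite differences.

On top of the fields the module computes:

* the reduced density gradient  S = |∇ρ| / (2 (3π²)^{1/3} ρ^{4/3}),
  small where non-covalent interactions flatten the density;
* the independent-gradient-model descriptor
  δg = |∇ρ^IGM| − |∇ρ|, where ∇ρ^IGM sums the *absolute values* of the
  per-atom gradient components and therefore ignores interatomic gradient
  cancellation; δg ≥ 0, peaking at interaction critical points. With a
  fragment partition, δg splits into an inter-fragment part (signed sums
  within fragments, absolute sums across) and the intramolecular remainder;
* sign(λ₂)ρ, the density signed by the middle Hessian eigenvalue
  (negative: attraction; positive: steric crowding), and the δg-vs-sign(λ₂)ρ
  scatter data used for NCI-style plots;
* a damped-Newton bond-critical-point locator on the promolecular density.

All lengths are Bohr and densities a.u. throughout this module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import ContractError, GridField, MoleculeGeometry, ReactikitError
from .units import ANGSTROM_TO_BOHR

#: Eq-22 prefactor of the reduced density gradient
RDG_PREFACTOR = 2.0 * (3.0 * np.pi ** 2) ** (1.0 / 3.0)

#: densities below this are masked from RDG / δg (the RDG diverges as ρ→0)
DENSITY_FLOOR = 1e-10

DEFAULT_GRID_SPACING = 0.2   # Bohr
DEFAULT_GRID_PADDING = 4.0   # Bohr beyond the molecular extent
VDW_ISO = 0.001              # e/bohr³ van der Waals isosurface


class ModelError(ReactikitError):
    """The atomic density model lacks a required element."""


@dataclass
class AtomicDensityModel:
    """Spherical exponential-shell free-atom densities, element → shells.

    Each shell is a (coefficient, exponent) pair in a.u. / Bohr⁻¹ with both
    entries positive, so every atomic density is positive and monotonically
    decreasing in r.
    """

    shells: dict[str, list[tuple[float, float]]]

    def __post_init__(self):
        for el, shell_list in self.shells.items():
            for c, a in shell_list:
                if not (c > 0 and a > 0):
                    raise ContractError(
                        f"element {el}: shell coefficients and exponents must "
                        f"be positive (got c={c}, alpha={a})")

    def shells_for(self, element: str) -> list[tuple[float, float]]:
        try:
            return self.shells[element]
        except KeyError:
            raise ModelError(
                f"element {element!r} missing from the atomic density model")

    def rho_el(self, element: str, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, a in self.shells_for(element):
            out += c * np.exp(-a * r)
        return out


def load_density_model(path=None) -> AtomicDensityModel:
    """Load shell parameters from a CSV table (element, coefficient, exponent).

    With no path, the packaged table (H–Ar, Slater-rule screened exponents
    with shells normalised to their electron counts) is used.
    """
    if path is None:
        source = resources.files("reactikit.data").joinpath("atomic_density.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    shells: dict[str, list[tuple[float, float]]] = {}
    reader = csv.DictReader(filter(lambda l: not l.startswith("#"),
                                   text.splitlines()))
    for row in reader:
        shells.setdefault(row["element"], []).append(
            (float(row["coefficient"]), float(row["exponent"])))
    return AtomicDensityModel(shells=shells)


@dataclass
class FieldTriple:
    """ρ, ∇ρ and the Hessian of ρ at a batch of points, plus the per-atom
    gradient contributions the IGM descriptor needs."""

    rho: np.ndarray          # (n,)
    grad: np.ndarray         # (n, 3)
    hessian: np.ndarray      # (n, 3, 3)
    atom_grads: np.ndarray   # (natoms, n, 3)

    @property
    def grad_norm(self) -> np.ndarray:
        return np.linalg.norm(self.grad, axis=-1)


def promolecular_field(g: MoleculeGeometry, model: AtomicDensityModel,
                       points) -> FieldTriple:
    """Evaluate ρ, ∇ρ, ∇∇ρ of the promolecular density at given points (Bohr).

    For a shell f(r) = c e^{−αr} centred at R, with u the unit vector from R:
    ∇f = f'(r) u and ∇∇f = f''(r) u uᵀ + (f'(r)/r)(I − u uᵀ).
    All contributions are additive over atoms and shells.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    centers = g.positions_bohr()
    elements = g.elements()
    rho = np.zeros(n)
    hess = np.zeros((n, 3, 3))
    atom_grads = np.zeros((len(elements), n, 3))
    eye = np.eye(3)[None]
    for ai, (el, R) in enumerate(zip(elements, centers)):
        model.shells_for(el)  # raise early on missing elements
        d = pts - R
        r = np.linalg.norm(d, axis=1)
        r_safe = np.maximum(r, 1e-12)
        u = d / r_safe[:, None]
        f = np.zeros(n)
        fp = np.zeros(n)
        fpp = np.zeros(n)
        for c, a in model.shells_for(el):
            e = c * np.exp(-a * r)
            f += e
            fp -= a * e
            fpp += a * a * e
        rho += f
        atom_grads[ai] = fp[:, None] * u
        uuT = u[:, :, None] * u[:, None, :]
        hess += fpp[:, None, None] * uuT \
            + (fp / r_safe)[:, None, None] * (eye - uuT)
    grad = atom_grads.sum(axis=0)
    return FieldTriple(rho=rho, grad=grad, hessian=hess, atom_grads=atom_grads)


def rdg_field(rho, grad) -> np.ndarray:
    """Reduced density gradient S = |∇ρ| / (2 (3π²)^{1/3} ρ^{4/3}).

    Accepts the gradient as vectors (…, 3) or as precomputed norms. Points
    with ρ below the density floor are masked to NaN rather than raised.
    """
    rho = np.asarray(rho, dtype=float)
    grad = np.asarray(grad, dtype=float)
    gnorm = np.linalg.norm(grad, axis=-1) if grad.shape != rho.shape else grad
    with np.errstate(divide="ignore", invalid="ignore"):
        s = gnorm / (RDG_PREFACTOR * rho ** (4.0 / 3.0))
    return np.where(rho > DENSITY_FLOOR, s, np.nan)


def _fragment_groups(g: MoleculeGeometry) -> list[np.ndarray]:
    """Fragment membership as 0-based atom position arrays; atoms outside
    every named fragment become singleton fragments."""
    pos_of_index = {a.index: i for i, a in enumerate(g.atoms)}
    groups = []
    assigned: set[int] = set()
    for members in g.fragments.values():
        rows = np.array([pos_of_index[i] for i in members], dtype=int)
        groups.append(rows)
        assigned.update(rows.tolist())
    for i in range(len(g.atoms)):
        if i not in assigned:
            groups.append(np.array([i], dtype=int))
    return groups


def delta_g(g: MoleculeGeometry, model: AtomicDensityModel, points,
            fragments: bool | Mapping[str, Sequence[int]] = True,
            field: FieldTriple | None = None) -> dict[str, np.ndarray]:
    """IGM descriptor δg = |∇ρ^IGM| − |∇ρ| with an intra/inter partition.

    ∇ρ^IGM sums per-atom gradient components as absolute values. The
    inter-fragment gradient keeps signed sums within each fragment and
    absolute sums across fragments, so δg_inter captures only cancellation
    *between* fragments; δg_intra = δg − δg_inter. ``fragments`` may be an
    explicit mapping (overriding the geometry's annotations) or a boolean
    enabling/disabling the geometry's own fragments.
    """
    if isinstance(fragments, Mapping):
        g = MoleculeGeometry(g.name, list(g.atoms),
                             {k: tuple(v) for k, v in fragments.items()})
    ft = field if field is not None else promolecular_field(g, model, points)
    true_norm = ft.grad_norm
    igm_vec = np.abs(ft.atom_grads).sum(axis=0)
    dg = np.linalg.norm(igm_vec, axis=-1) - true_norm
    out = {"delta_g": dg}
    if fragments is not False:
        groups = _fragment_groups(g)
        inter_vec = np.zeros_like(ft.grad)
        for rows in groups:
            inter_vec += np.abs(ft.atom_grads[rows].sum(axis=0))
        dg_inter = np.linalg.norm(inter_vec, axis=-1) - true_norm
        out["delta_g_inter"] = dg_inter
        out["delta_g_intra"] = dg - dg_inter
    return out


def signed_lambda2_density(hessian, rho):
    """sign(λ₂)·ρ with λ₂ the middle Hessian eigenvalue (ascending order).

    Accepts a single symmetric 3×3 matrix or a batch (n, 3, 3). A vanishing
    λ₂ yields +ρ with the accompanying zero-flag set. Returns
    (signed_rho, lambda2_zero_flag).
    """
    H = np.asarray(hessian, dtype=float)
    single = H.ndim == 2
    if single:
        H = H[None]
    if H.shape[-2:] != (3, 3):
        raise ContractError("hessian must be 3x3 (or a batch thereof)")
    if not np.allclose(H, np.swapaxes(H, -1, -2), atol=1e-10):
        raise ContractError("hessian must be symmetric")
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    lam2 = np.linalg.eigvalsh(H)[..., 1]
    zero = lam2 == 0.0
    signed = np.where(zero, rho_arr, np.sign(lam2) * rho_arr)
    if single:
        return float(signed[0]), bool(zero[0])
    return signed, zero


def scatter_table(signed_rho, y, x_range=(-0.05, 0.05), mask=None):
    """NCI-style scatter data: (sign(λ₂)ρ, δg-or-S) pairs per unmasked voxel.

    Input arrays are flattened in z-fastest (C) order, so the output row
    order is deterministic. Points with x outside ``x_range`` or where
    ``mask`` is False (or y is NaN) are dropped.
    """
    import pandas as pd

    x = np.asarray(signed_rho, dtype=float).reshape(-1)
    yv = np.asarray(y, dtype=float).reshape(-1)
    keep = (x >= x_range[0]) & (x <= x_range[1]) & ~np.isnan(yv)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool).reshape(-1)
    return pd.DataFrame({"sign_lambda2_rho": x[keep], "y": yv[keep]})


# ---------------------------------------------------------------------------
# Grids

@dataclass
class GridSpec:
    origin: np.ndarray
    spacing: np.ndarray
    dims: tuple[int, int, int]

    def points(self) -> np.ndarray:
        nx, ny, nz = self.dims
        ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.spacing

    def field(self, values: np.ndarray, quantity: str) -> GridField:
        return GridField(self.origin, self.spacing, self.dims,
                         np.asarray(values).reshape(self.dims), quantity)


def molecular_grid(g: MoleculeGeometry,
                   spacing: float = DEFAULT_GRID_SPACING,
                   padding: float = DEFAULT_GRID_PADDING) -> GridSpec:
    """Regular grid covering the molecule plus ``padding`` Bohr on each side."""
    if len(g) == 0:
        raise ContractError("cannot grid an empty molecule")
    pos = g.positions_bohr()
    lo = pos.min(axis=0) - padding
    hi = pos.max(axis=0) + padding
    dims = tuple(int(np.floor((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return GridSpec(origin=lo, spacing=np.full(3, float(spacing)), dims=dims)


def vdw_surface_mask(rho_grid: np.ndarray, iso: float = VDW_ISO) -> np.ndarray:
    """Voxels on the ρ = iso van der Waals surface.

    A voxel belongs to the surface when its density is ≥ iso and at least
    one face neighbour falls below iso; nonempty whenever the grid density
    straddles the isovalue.
    """
    rho = np.asarray(rho_grid, dtype=float)
    inside = rho >= iso
    surface = np.zeros_like(inside)
    for axis in range(3):
        for shift in (1, -1):
            neighbour = np.roll(inside, shift, axis=axis)
            # roll wraps around; edge voxels compare against "outside"
            edge = np.zeros_like(inside)
            sl = [slice(None)] * 3
            sl[axis] = 0 if shift == 1 else -1
            neighbour[tuple(sl)] = False
            surface |= inside & ~neighbour
    return surface


def igm_grid_analysis(g: MoleculeGeometry, model: AtomicDensityModel,
                      spacing: float = DEFAULT_GRID_SPACING,
                      padding: float = DEFAULT_GRID_PADDING,
                      x_range=(-0.05, 0.05)):
    """Full grid pipeline: ρ, RDG, δg (with partition), sign(λ₂)ρ, scatter.

    Returns a dict of :class:`GridField` objects under keys rho, rdg,
    delta_g (+ delta_g_intra / delta_g_inter when fragments are annotated),
    sign_lambda2_rho, plus the scatter DataFrame under 'scatter' and the
    GridSpec under 'grid'.
    """
    spec = molecular_grid(g, spacing, padding)
    pts = spec.points()
    ft = promolecular_field(g, model, pts)
    s = rdg_field(ft.rho, ft.grad)
    dg = delta_g(g, model, pts, fragments=bool(g.fragments), field=ft)
    signed, _ = signed_lambda2_density(ft.hessian, ft.rho)
    masked = ft.rho <= DENSITY_FLOOR
    out = {
        "grid": spec,
        "rho": spec.field(ft.rho, "rho"),
        "rdg": spec.field(s, "rdg"),
        "sign_lambda2_rho": spec.field(signed, "sign_lambda2_rho"),
    }
    for key, arr in dg.items():
        out[key] = spec.field(np.where(masked, np.nan, arr), key)
    out["scatter"] = scatter_table(signed, np.where(masked, np.nan, dg["delta_g"]),
                                   x_range=x_range)
    return out


# ---------------------------------------------------------------------------
# Promolecular BCP search

@dataclass
class BCPSearchResult:
    position: np.ndarray
    converged: bool
    iterations: int
    rho: float
    grad: np.ndarray
    grad_norm: float
    hessian: np.ndarray

    @property
    def signature(self) -> int:
        """Sum of Hessian eigenvalue signs; a bond point is (3,−1) → −1."""
        return int(np.sum(np.sign(np.linalg.eigvalsh(self.hessian))))


def locate_bcp(g: MoleculeGeometry, model: AtomicDensityModel,
               atom_a: int, atom_b: int,
               step_cap: float = 0.2, tol: float = 1e-8,
               max_iter: int = 200) -> BCPSearchResult:
    """Find the ∇ρ = 0 saddle between two atoms of the promolecular density.

    Damped Newton iteration started at the internuclear midpoint: the Newton
    step −H⁻¹∇ρ is capped at ``step_cap`` Bohr and halved while it fails to
    reduce |∇ρ|². Non-convergence is reported in the result, not raised.
    """
    if atom_a == atom_b:
        raise ContractError("atom_a and atom_b must differ")
    by_index = {a.index: a for a in g.atoms}
    try:
        Ra = by_index[atom_a].position * ANGSTROM_TO_BOHR
        Rb = by_index[atom_b].position * ANGSTROM_TO_BOHR
    except KeyError as exc:
        raise ContractError(f"atom index {exc.args[0]} not in molecule") from exc
    if np.allclose(Ra, Rb):
        raise ContractError("atoms coincide; no internuclear axis")

    x = 0.5 * (Ra + Rb)
    converged = False
    it = 0
    ft = promolecular_field(g, model, x[None])
    for it in range(1, max_iter + 1):
        gvec = ft.grad[0]
        gnorm = float(np.linalg.norm(gvec))
        if gnorm < tol:
            converged = True
            break
        H = ft.hessian[0]
        try:
            step = -np.linalg.solve(H, gvec)
        except np.linalg.LinAlgError:
            step = -gvec
        slen = np.linalg.norm(step)
        if slen > step_cap:
            step *= step_cap / slen
        # damp: halve until |grad|^2 decreases (or give up after 20 halvings)
        obj = gnorm ** 2
        for _ in range(20):
            trial = x + step
            ft_trial = promolecular_field(g, model, trial[None])
            if float(np.linalg.norm(ft_trial.grad[0])) ** 2 < obj:
                break
            step *= 0.5
        x = x + step
        ft = promolecular_field(g, model, x[None])
    gvec = ft.grad[0]
    return BCPSearchResult(
        position=x, converged=converged, iterations=it,
        rho=float(ft.rho[0]), grad=gvec,
        grad_norm=float(np.linalg.norm(gvec)), hessian=ft.hessian[0])
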