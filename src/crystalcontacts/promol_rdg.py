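"""Promolecular electron density, reduced density gradient and critical points.

A geometry-only stand-in for wavefunction-based NCI analysis: the molecular
density is approximated as a sum of spherical free-atom densities, each
modelled as a short sum of exponentials rho_atom(r) = sum_k c_k exp(-r/zeta_k)
(atomic units).  Gradients and Hessians are analytic, so the reduced density
gradient

    s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))

and the sign(lambda2)-signed density can be evaluated on grids, and density
critical points located by damped Newton iteration.  The default per-element
parameters come from a Slater-screened shell model (shells grouped into at
most three terms, coefficients normalised to the shell electron counts); they
are shipped as a data file and can be overridden.  This module makes no
quantitative claim against correlated ab initio RDG fields — its contracts are
structural (symmetry, derivative consistency, critical-point signatures,
presence/absence of interaction troughs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

BOHR_PER_ANGSTROM = 1.8897259886
_RDG_PREFACTOR = 2.0 * (3.0 * np.pi**2) ** (1.0 / 3.0)


class ConvergenceError(RuntimeError):
    """Newton search failed; carries the last iterate as ``last_point``."""

    def __init__(self, message: str, last_point: np.ndarray):
        super().__init__(message)
        self.last_point = np.asarray(last_point)


@dataclass(frozen=True)
class AtomicDensityModel:
    """Element -> [(coefficient, decay length bohr), ...] with provenance."""

    terms: dict[str, tuple[tuple[float, float], ...]]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        for el, pairs in self.terms.items():
            for c, zeta in pairs:
                if c <= 0 or zeta <= 0:
                    raise ValueError(
                        f"density term for {el} must have positive c and zeta")

    def __getitem__(self, element: str):
        try:
            return self.terms[element]
        except KeyError:
            raise KeyError(f"element {element!r} not covered by density model "
                           f"({self.provenance})") from None

    def electron_count(self, element: str) -> float:
        """Integral of the atomic density: 8 pi sum c_k zeta_k^3."""
        return float(sum(8.0 * np.pi * c * z**3 for c, z in self[element]))


# Slater-rule effective charges grouped into <=3 exponential terms per element:
# (electrons, decay length zeta = n*/(2 Z_eff) in bohr).
_SLATER_SHELLS: dict[str, tuple[tuple[float, float], ...]] = {
    "H":  ((1, 0.5000),),
    "C":  ((2, 0.0877), (4, 0.3077)),
    "N":  ((2, 0.0746), (5, 0.2564)),
    "O":  ((2, 0.0649), (6, 0.2198)),
    "F":  ((2, 0.0575), (7, 0.1923)),
    "S":  ((2, 0.0318), (8, 0.0835), (6, 0.2752)),
    "Cl": ((2, 0.0301), (8, 0.0778), (7, 0.2459)),
    "Br": ((10, 0.0250), (18, 0.0800), (7, 0.2434)),
    "I":  ((10, 0.0210), (26, 0.0900), (7, 0.2593)),
}


def slater_density_model() -> AtomicDensityModel:
    """Default promolecular parameters from the Slater-screened shell model."""
    terms = {
        el: tuple((n / (8.0 * np.pi * z**3), z) for n, z in shells)
        for el, shells in _SLATER_SHELLS.items()
    }
    return AtomicDensityModel(terms, provenance="Slater-screened shell model (synthetic)")


def load_density_model(source=None) -> AtomicDensityModel:
    """Load a density model from JSON ({element: [[c, zeta], ...]}), or the default."""
    if source is None:
        path = resources.files("crystalcontacts.data") / "promolecular_density.json"
        data = json.loads(path.read_text())
    else:
        data = json.loads(source) if isinstance(source, str) and source.lstrip().startswith("{") \
            else json.loads(open(source).read())
    prov = data.pop("_provenance", "file")
    return AtomicDensityModel(
        {el: tuple((float(c), float(z)) for c, z in pairs) for el, pairs in data.items()},
        provenance=prov)


@dataclass
class FieldSample:
    """Promolecular field at one spatial point (atomic units)."""

    point: np.ndarray          # cartesian angstrom (as given)
    rho: float
    grad: np.ndarray           # d rho / d x, a.u. (per bohr)
    hessian_eigs: np.ndarray   # lambda1 <= lambda2 <= lambda3
    s: float                   # reduced density gradient
    slr: float                 # sign(lambda2) * rho


def _field_arrays(points_bohr: np.ndarray, centers_bohr: np.ndarray,
                  params: list[tuple[np.ndarray, np.ndarray]]):
    """Vectorised rho, gradient and Hessian over N points (all bohr / a.u.)."""
    n = len(points_bohr)
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    for center, (cs, zs) in zip(centers_bohr, params):
        dvec = points_bohr - center          # (n, 3)
        r = np.linalg.norm(dvec, axis=1)     # (n,)
        if np.any(r < 1e-8):
            raise ValueError("field point coincides with a nucleus (density cusp)")
        u = dvec / r[:, None]
        expo = np.exp(-r[:, None] / zs)      # (n, k)
        f = expo @ cs                        # sum_k c exp(-r/z)
        fp = -(expo @ (cs / zs))             # radial first derivative
        fpp = expo @ (cs / zs**2)
        rho += f
        grad += fp[:, None] * u
        uu = u[:, :, None] * u[:, None, :]
        hess += fpp[:, None, None] * uu + (fp / r)[:, None, None] * (eye - uu)
    return rho, grad, hess


def _atom_params(elements, model: AtomicDensityModel):
    out = []
    for el in elements:
        pairs = model[el]
        cs = np.array([c for c, _ in pairs])
        zs = np.array([z for _, z in pairs])
        out.append((cs, zs))
    return out


def promol_eval(point, elements, coords, model: AtomicDensityModel | None = None) -> FieldSample:
    """Evaluate the promolecular field at one cartesian point (angstrom in, a.u. out)."""
    model = model if model is not None else slater_density_model()
    point = np.asarray(point, dtype=float)
    centers = np.asarray(coords, dtype=float) * BOHR_PER_ANGSTROM
    rho, grad, hess = _field_arrays(point[None, :] * BOHR_PER_ANGSTROM, centers,
                                    _atom_params(elements, model))
    eigs = np.linalg.eigvalsh(hess[0])
    return FieldSample(point=point, rho=float(rho[0]), grad=grad[0],
                       hessian_eigs=eigs,
                       s=rdg(float(rho[0]), float(np.linalg.norm(grad[0]))),
                       slr=float(np.sign(eigs[1]) * rho[0]))


def rdg(rho: float, grad_norm: float) -> float:
    """Reduced density gradient s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))."""
    if rho <= 0:
        raise ValueError("rho must be positive for the reduced density gradient")
    return grad_norm / (_RDG_PREFACTOR * rho ** (4.0 / 3.0))


@dataclass(frozen=True)
class CriticalPoint:
    """A stationary point of the promolecular density."""

    point: np.ndarray       # cartesian angstrom
    rank: int
    signature: int          # sum of Hessian eigenvalue signs: -1 => bond CP, +1 => ring CP
    rho: float

    @property
    def kind(self) -> str:
        return {-3: "nuclear-like", -1: "bond", 1: "ring", 3: "cage"}.get(
            self.signature, "degenerate")


def find_cp(start, elements, coords, model: AtomicDensityModel | None = None,
            grad_tol: float = 1e-10, max_steps: int = 200,
            trust_radius: float = 0.3) -> CriticalPoint:
    """Locate a density critical point by damped Newton iteration on grad rho.

    Steps are capped at ``trust_radius`` bohr.  Convergence requires
    |grad rho| < ``grad_tol``; failure after ``max_steps`` raises
    :class:`ConvergenceError` carrying the last point.
    """
    model = model if model is not None else slater_density_model()
    centers = np.asarray(coords, dtype=float) * BOHR_PER_ANGSTROM
    start = np.asarray(start, dtype=float)
    if np.min(np.linalg.norm(np.asarray(coords) - start, axis=1)) > 5.0:
        raise ValueError("start point must lie within 5 A of some atom")
    params = _atom_params(elements, model)
    x = start * BOHR_PER_ANGSTROM
    for _ in range(max_steps):
        rho, grad, hess = _field_arrays(x[None, :], centers, params)
        g = grad[0]
        if np.linalg.norm(g) < grad_tol:
            eigs = np.linalg.eigvalsh(hess[0])
            signature = int(np.sum(np.sign(eigs)))
            return CriticalPoint(point=x / BOHR_PER_ANGSTROM, rank=int(np.sum(np.abs(eigs) > 1e-14)),
                                 signature=signature, rho=float(rho[0]))
        try:
            step = -np.linalg.solve(hess[0], g)
        except np.linalg.LinAlgError:
            step = -g
        norm = np.linalg.norm(step)
        if norm > trust_radius:
            step *= trust_radius / norm
        x = x + step
    raise ConvergenceError(
        f"critical-point search did not converge in {max_steps} steps",
        x / BOHR_PER_ANGSTROM)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned evaluation grid: origin (angstrom), shape, spacing (angstrom)."""

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    spacing: float = 0.1


def default_grid(coords, margin: float = 2.0, spacing: float = 0.1) -> GridSpec:
    """Bounding-box grid over the assembly plus ``margin`` on every side."""
    coords = np.asarray(coords, dtype=float)
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    shape = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), shape=shape, spacing=spacing)


def grid_points(spec: GridSpec) -> np.ndarray:
    """Grid points in deterministic C order (x fastest-varying last)."""
    axes = [spec.origin[k] + spec.spacing * np.arange(spec.shape[k]) for k in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


def scatter_profile(elements, coords, model: AtomicDensityModel | None = None,
                    grid: GridSpec | None = None,
                    exclusion_radius: float = 0.3) -> np.ndarray:
    """(sign(lambda2)·rho, s) pairs over an evaluation grid.

    One row per grid point in deterministic traversal order; points within
    ``exclusion_radius`` angstrom of a nucleus are dropped (density cusps, not
    intermolecular territory).  Low-s troughs at negative sign(lambda2)·rho
    appear iff a hydrogen-bond-like contact is present in the box.
    """
    model = model if model is not None else slater_density_model()
    grid = grid if grid is not None else default_grid(coords)
    pts = grid_points(grid)
    if len(pts) == 0:
        raise ValueError("empty evaluation grid")
    coords = np.asarray(coords, dtype=float)
    dmin = np.min(np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2), axis=1)
    pts = pts[dmin > exclusion_radius]
    rho, grad, hess = _field_arrays(pts * BOHR_PER_ANGSTROM,
                                    coords * BOHR_PER_ANGSTROM,
                                    _atom_params(elements, model))
    eigs = np.linalg.eigvalsh(hess)
    gnorm = np.linalg.norm(grad, axis=1)
    s = gnorm / (_RDG_PREFACTOR * rho ** (4.0 / 3.0))
    slr = np.sign(eigs[:, 1]) * rho
    return np.stack([slr, s], axis=1)


def rdg_point_region_counts(pairs: np.ndarray, cut: float = 0.01,
                            s_max: float = 1.0, rho_max: float = 0.05) -> dict[str, int]:
    """Count scatter points per NCI region (blue/green/red).

    Only low-gradient points (s <= s_max) at non-covalent densities
    (|sign(lambda2)·rho| <= rho_max) are informative: atomic cores and
    covalent bonds exceed the density cap, while for an isolated promolecular
    atom s grows like rho^(-1/3) and stays above the RDG cap everywhere
    outside the core, so a non-interacting geometry yields empty counts.
    """
    from .qtaim import rdg_point_class

    pairs = np.asarray(pairs)
    counts = {"blue": 0, "green": 0, "red": 0}
    for slr, s in pairs:
        if s <= s_max and abs(slr) <= rho_max:
            counts[rdg_point_class(s, slr, cut)] += 1
    return counts


def write_scatter_csv(pairs: np.ndarray) -> str:
    """Serialize scatter pairs as a two-column CSV (slr, s), a.u."""
    lines = ["slr,s"]
    for slr, s in pairs:
        lines.append(f"{slr:.8e},{s:.8e}")
    return "\n".join(lines) + "\n"


def write_grid_text(spec: GridSpec, values: np.ndarray) -> str:
    """Cube-like plain-text export: header then one value per line in grid order."""
    ox, oy, oz = spec.origin
    nx, ny, nz = spec.shape
    lines = [f"# promolecular grid: origin {ox:.4f} {oy:.4f} {oz:.4f} A, "
             f"shape {nx} {ny} {nz}, spacing {spec.spacing:.4f} A",
             f"{nx} {ny} {nz} {spec.spacing:.6f}"]
    lines += [f"{v:.8e}" for v in np.asarray(values).ravel()]
    return "\n".join(lines) + "\n"
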