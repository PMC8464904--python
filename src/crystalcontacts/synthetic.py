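"""Synthetic inputs with known ground truth.

Three generators stand in for raw experiment/quantum-chemistry outputs:

* toy crystals (CIF text) with contacts planted at exact distances and angles
  under real space-group symmetry, plus a machine-readable answer manifest;
* class-conditional QTAIM critical-point tables whose classification flags
  hold by construction, with a controllable virial-noise level;
* supramolecular energy manifests engineered to reproduce target interaction
  energies exactly.

Toy molecules are minimal planted-geometry fragments (a brominated methyl for
halogen contacts, a four-atom amide fragment for the R2,2(8) double hydrogen
bond), not full oxindoles: the tests need geometry, not chemistry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crystal_io import (
    AtomSite,
    CrystalStructure,
    GeometryError,
    UnitCell,
    cart_to_frac,
    parse_symop,
    write_cif,
)
from .qtaim import HARTREE_TO_KCAL, RHO_REGIME_THRESHOLD, BCPRecord, EnergyManifest

P1_OPS = ("x,y,z",)
PBAR1_OPS = ("x,y,z", "-x,-y,-z")
P21C_OPS = ("x,y,z", "-x,1/2+y,1/2-z", "-x,-y,-z", "x,1/2-y,1/2+z")


@dataclass(frozen=True)
class PlantedContact:
    """One contact the toy crystal must realise exactly."""

    kind: str                  # "X...X" or "N-H...O"
    distance: float            # target contact distance, angstrom
    theta: float | None = None # C-X...X angle for halogen contacts, degrees


@dataclass(frozen=True)
class CrystalSpec:
    """Recipe for a toy crystal: cell, operators and planted contacts."""

    cell: UnitCell
    symop_codes: tuple[str, ...] = PBAR1_OPS
    planted: tuple[PlantedContact, ...] = ()
    name: str = "toy"


def _check_feasible(spec: CrystalSpec) -> None:
    cell = spec.cell
    inv = np.linalg.inv(cell.orthogonalization_matrix)
    perp = 1.0 / np.linalg.norm(inv, axis=1)
    for pc in spec.planted:
        # the dimer (contact + two molecule extents ~4 A) must fit well inside
        # the cell so lattice translates cannot introduce shorter copies
        if pc.distance + 8.0 > perp.min():
            raise GeometryError(
                f"planted {pc.kind} contact at {pc.distance} A infeasible in a cell "
                f"with minimum perpendicular width {perp.min():.2f} A")
        if pc.distance <= 0:
            raise GeometryError("planted distance must be positive")


def _halogen_dimer_sites(distance: float, theta: float) -> tuple[list[AtomSite], list[np.ndarray]]:
    """Br-C(H3) fragment whose inversion image realises Br...Br' = distance
    with C-Br...Br' = Br...Br'-C = theta (inversion forces the symmetry)."""
    th = math.radians(theta)
    br = np.array([distance / 2.0, 0.0, 0.0])
    u = np.array([-math.cos(th), math.sin(th), 0.0])  # angle(u, -x) = theta
    c = br + 1.90 * u
    # methyl hydrogens pointing away from the contact axis
    hdirs = [np.array([math.cos(a), 0.35, math.sin(a)]) for a in (0.4, 2.5, 4.6)]
    sites = [AtomSite("Br1", "Br", np.zeros(3)), AtomSite("C1", "C", np.zeros(3))]
    carts = [br, c]
    for k, hd in enumerate(hdirs, start=1):
        hd = hd / np.linalg.norm(hd)
        sites.append(AtomSite(f"H{k}", "H", np.zeros(3)))
        carts.append(c + 1.09 * hd)
    return sites, carts


def _amide_dimer_sites(d_ha: float) -> tuple[list[AtomSite], list[np.ndarray]]:
    """Planar H-N-C=O fragment whose inversion image forms the double
    N-H...O hydrogen-bonded ring with H...O' = d_ha and a 180 deg N-H...O'."""
    n_o = 2.257            # N...O separation compatible with C bridging both
    dy = 2.2               # lateral offset between the two antiparallel H-bonds
    dx = math.sqrt(n_o**2 - dy**2)
    x_h = (1.0 - d_ha - dx) / 2.0
    n = np.array([x_h - 1.0, dy / 2.0, 0.0])
    h = np.array([x_h, dy / 2.0, 0.0])
    o = np.array([-x_h - d_ha, -dy / 2.0, 0.0])
    # C on the intersection of circles r=1.35 about N and r=1.23 about O,
    # on the side away from the partner molecule
    a = (n_o**2 + 1.35**2 - 1.23**2) / (2.0 * n_o)
    b = math.sqrt(1.35**2 - a**2)
    axis = (o - n) / n_o
    perp = np.array([axis[1], -axis[0], 0.0])
    c = n + a * axis + b * perp
    if c[0] > n[0]:
        c = n + a * axis - b * perp
    sites = [AtomSite("N1", "N", np.zeros(3)), AtomSite("H1", "H", np.zeros(3)),
             AtomSite("C1", "C", np.zeros(3)), AtomSite("O1", "O", np.zeros(3))]
    return sites, [n, h, c, o]


def make_toy_crystal(spec: CrystalSpec, seed: int = 0) -> tuple[str, dict]:
    """Build CIF text plus an answer manifest for a toy-crystal spec.

    The manifest records every planted contact (class, labels, distance,
    angles, expected halogen type / ring motif) so tests never re-derive
    ground truth from the fixture itself.  Raises before writing when the
    planting is geometrically infeasible.
    """
    _check_feasible(spec)
    cell = spec.cell
    sites: list[AtomSite] = []
    answers: dict = {"name": spec.name, "seed": seed, "contacts": []}
    if len(spec.planted) > 1:
        raise GeometryError("toy crystals plant at most one contact motif")

    if not spec.planted:
        s, carts = _amide_dimer_sites(2.6)  # inert fragment, no short contacts
        center = np.array([cell.a, cell.b, cell.c]) * 0.25
        for site, cart in zip(s, carts):
            site.frac = cart_to_frac(cell, cart + center)
            sites.append(site)
    else:
        pc = spec.planted[0]
        if "-x,-y,-z" not in [c.replace(" ", "") for c in spec.symop_codes]:
            raise GeometryError("planted dimer contacts need an inversion operator")
        if pc.kind == "X...X":
            if pc.theta is None:
                raise GeometryError("X...X planting needs a theta angle")
            s, carts = _halogen_dimer_sites(pc.distance, pc.theta)
            answers["contacts"].append({
                "contact_class": "X...X", "label_i": "Br1", "label_j": "Br1",
                "d": round(pc.distance, 3), "theta1": pc.theta, "theta2": pc.theta,
                "halogen_type": "Type I"})  # theta1 = theta2 forced by inversion
        elif pc.kind == "N-H...O":
            s, carts = _amide_dimer_sites(pc.distance)
            answers["contacts"].append({
                "contact_class": "N-H...O", "label_i": "H1", "label_j": "O1",
                "d": round(pc.distance, 3), "angle_dha": 180.0})
            answers["motif"] = "R2,2(8)"
        else:
            raise GeometryError(f"unsupported planted contact kind {pc.kind!r}")
        for site, cart in zip(s, carts):
            site.frac = cart_to_frac(cell, cart)  # inversion centre at origin
            sites.append(site)

    structure = CrystalStructure(
        cell=cell, symops=[parse_symop(c) for c in spec.symop_codes],
        sites=sites, name=spec.name)
    return write_cif(structure), answers


# ---------------------------------------------------------------------------
# class-conditional BCP tables


@dataclass(frozen=True)
class BCPGeneratorSpec:
    """Distribution parameters for synthetic critical-point records.

    The hydrogen-bond class draws rho from U(1e-2, 3e-2) a.u., the vdW class
    from U(1e-3, 9e-3); ring points reuse the vdW density range with positive
    lambda2.  G is proportional to rho with a class factor (from the observed
    G/rho ranges of the two regimes); V = -G/r with r = |G/V| ~ U(1.1, 1.7),
    so non-covalency and closed-shell character hold by construction.  The
    Laplacian is derived from the local virial identity with relative noise
    ``virial_noise``; classification fields stay exact so audit tests and
    classification tests remain independent.
    """

    rho_range_hb: tuple[float, float] = (1e-2, 3e-2)
    rho_range_vdw: tuple[float, float] = (1e-3, 9e-3)
    g_factor_hb: float = 1.3
    g_factor_vdw: float = 0.8
    g_factor_jitter: float = 0.15
    ratio_range: tuple[float, float] = (1.1, 1.7)
    virial_noise: float = 0.0
    rho_regime_threshold: float = RHO_REGIME_THRESHOLD


_CLASS_SETTINGS = {
    "HB": {"attractive": True},
    "vdW": {"attractive": True},
    "ring": {"attractive": False},
}


def make_bcp_table(spec: BCPGeneratorSpec, n_per_class: int,
                   seed: int = 0) -> tuple[list[BCPRecord], pd.DataFrame]:
    """Generate records plus a separate ground-truth label table.

    Labels: ``klass`` (generating class HB/vdW/ring), the planted
    ``attractive``/``closed_shell``/``noncovalent`` flags, and ``regime``
    assigned from the drawn rho against the configured threshold (the density
    regime is definitional in rho, so overlapping class ranges stay honest).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for klass in ("HB", "vdW", "ring"):
        lo, hi = (spec.rho_range_hb if klass == "HB" else spec.rho_range_vdw)
        gf = spec.g_factor_hb if klass == "HB" else spec.g_factor_vdw
        attractive = _CLASS_SETTINGS[klass]["attractive"]
        for k in range(n_per_class):
            rho = rng.uniform(lo, hi)
            g = gf * rho * (1.0 + spec.g_factor_jitter * rng.uniform(-1, 1))
            ratio = rng.uniform(*spec.ratio_range)
            v = -g / ratio
            lap = 4.0 * (2.0 * g + v)
            if spec.virial_noise > 0:
                lap *= 1.0 + spec.virial_noise * rng.uniform(-1, 1)
            lam2 = -rho if attractive else rho
            records.append(BCPRecord(
                dimer_id=f"syn-{klass}", cp_index=k + 1, rho=rho, lap=lap,
                G=g, V=v, lambda2=lam2,
                contact_type="HB" if klass == "HB" else "XB"))
            labels.append({
                "dimer_id": f"syn-{klass}", "cp_index": k + 1, "klass": klass,
                "attractive": attractive,
                "closed_shell": True,     # lap > 0 and H = G(1 - 1/r) > 0 since r > 1
                "noncovalent": True,      # |G/V| = r > 1 by construction
                "regime": ("hydrogen-bond" if rho >= spec.rho_regime_threshold
                           else "vdW"),
            })
    return records, pd.DataFrame(labels)


# ---------------------------------------------------------------------------
# energy manifests


@dataclass(frozen=True)
class ManifestSpec:
    """Targets for a synthetic supramolecular energy manifest, kcal/mol."""

    eint: float
    eint_bsse: float | None = None
    baseline_range: tuple[float, float] = (-600.0, -300.0)  # monomer totals, hartree


def make_energy_manifest(spec: ManifestSpec, seed: int = 0) -> EnergyManifest:
    """Engineer hartree totals so ``interaction_energy`` recovers the targets.

    Monomer baselines are arbitrary draws; the dimer total and counterpoise
    correction are solved from the targets, so the round trip is exact to
    floating-point (well under 1e-9 kcal/mol).
    """
    rng = np.random.default_rng(seed)
    m1, m2 = rng.uniform(*spec.baseline_range, size=2)
    e_dimer = m1 + m2 + spec.eint / HARTREE_TO_KCAL
    bsse = 0.0
    if spec.eint_bsse is not None:
        bsse = (spec.eint_bsse - spec.eint) / HARTREE_TO_KCAL
    return EnergyManifest(e_dimer=e_dimer, e_mon1=m1, e_mon2=m2,
                          bsse_correction=bsse, units="hartree")


def manifest_to_json(manifest: EnergyManifest) -> str:
    return json.dumps({
        "units": manifest.units, "e_dimer": manifest.e_dimer,
        "e_mon1": manifest.e_mon1, "e_mon2": manifest.e_mon2,
        "bsse_correction": manifest.bsse_correction}, indent=1)
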