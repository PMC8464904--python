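"""Short intermolecular contact detection and classification.

Screens a crystal for atom pairs closer than the sum of their van der Waals
radii, classifies each contact by the elements and covalent environment
involved (Br...Br, N-H...O, C-H...O, C-H...F, C-H...Br, ...), types
halogen-halogen contacts as Type I / quasi / Type II from the two C-X...X
angles, measures hydrogen-bond geometry, detects graph-set ring motifs such as
the amide R2,2(8) dimer ring, and fits least-squares molecular planes for
pi-stacking metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .crystal_io import (
    CrystalStructure,
    EnvironmentImage,
    GeometryError,
    bond_matrix,
    detect_molecules,
    expand_environment,
)

log = logging.getLogger(__name__)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: Bondi (1964) van der Waals radii, angstrom.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98, "Se": 1.90,
}

#: |theta1 - theta2| at or below this marks a symmetric (Type I) halogen contact, deg.
TYPE1_MAX_ASYMMETRY = 15.0
#: |theta1 - theta2| at or above this marks a sigma-hole (Type II) contact, deg.
TYPE2_MIN_ASYMMETRY = 30.0

#: Minimum D-H...A angle for a contact to count as a hydrogen bond, deg.
HBOND_MIN_ANGLE = 110.0


@dataclass(frozen=True)
class RadiiTable:
    """Element -> vdW radius (angstrom) with a provenance label."""

    radii: dict[str, float]
    provenance: str = "custom"

    def __post_init__(self) -> None:
        missing = {"H", "C", "N", "O", "F", "Br"} - set(self.radii)
        if missing:
            raise ValueError(f"radii table must cover H,C,N,O,F,Br; missing {sorted(missing)}")
        bad = {el: r for el, r in self.radii.items() if not 0.5 < r < 3.0}
        if bad:
            raise ValueError(f"implausible vdW radii (outside 0.5-3.0 A): {bad}")

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element]
        except KeyError:
            raise KeyError(f"element {element!r} missing from vdW radii table "
                           f"({self.provenance})") from None


def bondi_radii() -> RadiiTable:
    return RadiiTable(dict(BONDI_RADII), provenance="Bondi 1964")


def vdw_gap(d: float, elem_i: str, elem_j: str,
            radii: RadiiTable | None = None) -> float:
    """Distance minus vdW radii sum, angstrom, rounded to 3 decimals.

    Negative values mark "short" contacts.
    """
    if d <= 0:
        raise GeometryError("contact distance must be positive")
    radii = radii if radii is not None else bondi_radii()
    return round(d - (radii[elem_i] + radii[elem_j]), 3)


@dataclass
class Contact:
    """A typed intermolecular atom pair with symmetry provenance.

    ``theta1``/``theta2`` (C-X1...X2 and X1...X2-C angles, degrees) and
    ``halogen_type`` are populated only when both atoms are halogens.
    """

    label_i: str
    label_j: str
    elem_i: str
    elem_j: str
    symcode: str
    d: float
    vdw_gap: float
    contact_class: str
    theta1: float | None = None
    theta2: float | None = None
    halogen_type: str = "n/a"


def classify_halogen_contact(theta1: float, theta2: float) -> str:
    """Type a halogen-halogen contact from its two C-X...X angles.

    Symmetric geometries (|t1 - t2| <= 15 deg) are dispersion-type Type I;
    strongly asymmetric ones (>= 30 deg) are sigma-hole Type II; the band in
    between is labelled quasi.
    """
    for t in (theta1, theta2):
        if not 0.0 <= t <= 180.0:
            raise GeometryError(f"angle {t} outside [0, 180] degrees")
    asym = abs(theta1 - theta2)
    if asym <= TYPE1_MAX_ASYMMETRY:
        return "Type I"
    if asym >= TYPE2_MIN_ASYMMETRY:
        return "Type II"
    return "quasi"


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    u, v = a - vertex, b - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise GeometryError("coincident points in angle computation")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosang))


def hbond_geometry(D, H, A) -> tuple[float, float, float]:
    """Hydrogen-bond geometry for donor D, hydrogen H, acceptor A (cartesian).

    Returns (d_HA, d_DA, D-H...A angle at H in degrees).
    """
    D, H, A = (np.asarray(p, dtype=float) for p in (D, H, A))
    d_ha = float(np.linalg.norm(A - H))
    d_da = float(np.linalg.norm(A - D))
    if d_ha < 1e-9 or d_da < 1e-9 or np.linalg.norm(H - D) < 1e-9:
        raise GeometryError("coincident points in hydrogen-bond geometry")
    return d_ha, d_da, _angle(D, H, A)


def is_hydrogen_bond(d_ha: float, angle: float, elem_a: str,
                     radii: RadiiTable | None = None,
                     min_angle: float = HBOND_MIN_ANGLE) -> bool:
    """True when H...A is within the vdW sum and the D-H...A angle is open enough."""
    radii = radii if radii is not None else bondi_radii()
    return d_ha <= radii["H"] + radii[elem_a] and angle >= min_angle


# ---------------------------------------------------------------------------
# contact search


def _contact_class(elem_i: str, donor_i: str | None,
                   elem_j: str, donor_j: str | None) -> str:
    """Classify by elements and covalent environment (donor = atom bonded to H)."""
    if elem_i in HALOGENS and elem_j in HALOGENS:
        return "X...X"
    for eh, dh, ea in ((elem_i, donor_i, elem_j), (elem_j, donor_j, elem_i)):
        if eh != "H":
            continue
        if ea == "O":
            return "N-H...O" if dh == "N" else "C-H...O"
        if ea == "F":
            return "C-H...F"
        if ea == "Br":
            return "C-H...Br"
    return "other"


def find_short_contacts(structure: CrystalStructure, tol: float = 0.0,
                        radii: RadiiTable | None = None) -> list[Contact]:
    """Find intermolecular contacts with vdw_gap <= tol, classified and deduplicated.

    Intramolecular pairs are excluded.  A pair seen both as (i, j under op S)
    and (j, i under S^-1) is reported once, in canonical lexicographic order on
    (label_i, label_j, symcode).  Halogen-halogen contacts carry the two
    C-X...X angles and a Type I / quasi / Type II label.
    """
    if tol < 0:
        raise GeometryError("contact tolerance must be >= 0")
    radii = radii if radii is not None else bondi_radii()
    if all(s.element != "H" for s in structure.sites):
        log.warning("structure %s has no hydrogen sites: H-dependent contact "
                    "classes are unavailable", structure.name)
    mol_ids = detect_molecules(structure)
    adj = bond_matrix(structure.cell, structure.sites)
    # covalent neighbour element of each H (its donor), and of each halogen
    attached: list[str | None] = []
    attached_idx: list[int | None] = []
    for i in range(len(structure.sites)):
        nbr = np.nonzero(adj[i])[0]
        attached.append(structure.sites[nbr[0]].element if len(nbr) else None)
        attached_idx.append(int(nbr[0]) if len(nbr) else None)

    max_r = max(radii[s.element] for s in structure.sites)
    images = expand_environment(structure, radius=2 * max_r + max(tol, 0.0) + 0.1)
    asym_cart = np.array([structure.cart(i) for i in range(len(structure.sites))])

    found: dict[tuple, Contact] = {}
    for img in images:
        j = img.site_index
        sj = structure.sites[j]
        for i, si in enumerate(structure.sites):
            if img.is_original and mol_ids[i] == mol_ids[j]:
                continue  # intramolecular (same molecule, same image)
            if img.is_original and i >= j:
                continue
            d = float(np.linalg.norm(img.cart - asym_cart[i]))
            if d < 1e-6:
                continue  # image coincides with the atom itself (special position)
            gap = vdw_gap(d, si.element, sj.element, radii)
            if gap > tol:
                continue
            symcode = img.symcode(structure)
            op = structure.symops[img.op_index]
            # canonical representation: compare with the swapped description
            inv_code = op.inverse().triplet(
                tuple(-np.rint(op.inverse().rot @ np.array(img.shift)).astype(int)))
            key_fwd = (si.label, sj.label, symcode)
            key_rev = (sj.label, si.label, inv_code)
            key = min(key_fwd, key_rev)
            if key in found:
                continue
            cls = _contact_class(si.element, attached[i], sj.element, attached[j])
            contact = Contact(label_i=si.label, label_j=sj.label,
                              elem_i=si.element, elem_j=sj.element,
                              symcode=symcode, d=round(d, 3), vdw_gap=gap,
                              contact_class=cls)
            if cls == "X...X":
                ci, cj = attached_idx[i], attached_idx[j]
                if ci is not None and cj is not None:
                    c_i = asym_cart[ci]
                    op_img = structure.symops[img.op_index]
                    cj_frac = op_img.apply(structure.sites[cj].frac) + np.array(img.shift)
                    c_j = structure.cell.orthogonalization_matrix @ cj_frac
                    contact.theta1 = round(_angle(c_i, asym_cart[i], img.cart), 2)
                    contact.theta2 = round(_angle(asym_cart[i], img.cart, c_j), 2)
                    contact.halogen_type = classify_halogen_contact(
                        contact.theta1, contact.theta2)
            found[key] = contact
    return [found[k] for k in sorted(found)]


# ---------------------------------------------------------------------------
# ring motifs


@dataclass(frozen=True)
class MotifDescriptor:
    """Etter graph-set descriptor for a hydrogen-bond motif."""

    donors: int
    acceptors: int
    ring_size: int

    @property
    def notation(self) -> str:
        if self.ring_size == 0:
            return "D"
        return f"R{self.acceptors},{self.donors}({self.ring_size})"


DISCRETE_MOTIF = MotifDescriptor(donors=0, acceptors=0, ring_size=0)


def ring_motif(graph: nx.Graph, hbond_edges: list[tuple]) -> MotifDescriptor:
    """Graph-set descriptor of the smallest ring containing all given H-bond edges.

    ``graph`` holds one node per atom of the dimer with a string ``element``
    attribute; its edges are the covalent bonds.  ``hbond_edges`` are
    (hydrogen, acceptor) node pairs.  When no cycle through all hydrogen-bond
    edges exists (e.g. a single hydrogen bond), the discrete descriptor ``D``
    is returned.
    """
    if len(hbond_edges) < 1:
        raise GeometryError("ring_motif needs at least one hydrogen-bond edge")
    g = graph.copy()
    for h, a in hbond_edges:
        g.add_edge(h, a, hbond=True)
    if len(hbond_edges) == 1:
        return DISCRETE_MOTIF

    hb_set = {frozenset(e) for e in hbond_edges}
    best: list | None = None
    for cycle in nx.simple_cycles(g, length_bound=16):
        edges = {frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
                 for k in range(len(cycle))}
        if hb_set <= edges and (best is None or len(cycle) < len(best)):
            best = cycle
    if best is None:
        return DISCRETE_MOTIF
    ring_nodes = set(best)
    donors = len({h for h, _ in hbond_edges if h in ring_nodes})
    acceptors = len({a for _, a in hbond_edges if a in ring_nodes})
    return MotifDescriptor(donors=donors, acceptors=acceptors, ring_size=len(best))


def dimer_graph(elements: list[str], coords: np.ndarray,
                tol: float = 0.4) -> nx.Graph:
    """Covalent-bond graph of a molecular assembly from cartesian coordinates."""
    from .crystal_io import COVALENT_RADII

    coords = np.asarray(coords, dtype=float)
    g = nx.Graph()
    for idx, el in enumerate(elements):
        g.add_node(idx, element=el)
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            cut = COVALENT_RADII[elements[i]] + COVALENT_RADII[elements[j]] + tol
            if np.linalg.norm(coords[i] - coords[j]) <= cut:
                g.add_edge(i, j)
    return g


# ---------------------------------------------------------------------------
# plane metrics


def _plane_fit(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane: returns (centroid, unit normal = smallest principal axis)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centroid = points.mean(axis=0)
    _, svals, vt = np.linalg.svd(points - centroid)
    if svals[1] < 1e-8 * max(svals[0], 1e-300):
        raise GeometryError("collinear point set: plane is undefined")
    return centroid, vt[2]


def plane_metrics(mol1: np.ndarray, mol2: np.ndarray) -> tuple[float, float]:
    """Interplanar angle (deg, folded to [0, 90]) and mean separation (angstrom).

    The separation is the mean absolute distance of ``mol2`` points from the
    least-squares plane of ``mol1``.
    """
    c1, n1 = _plane_fit(mol1)
    _, n2 = _plane_fit(mol2)
    cosang = abs(float(np.clip(np.dot(n1, n2), -1.0, 1.0)))
    angle = math.degrees(math.acos(cosang))
    sep = float(np.mean(np.abs((np.asarray(mol2, dtype=float) - c1) @ n1)))
    return angle, sep
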