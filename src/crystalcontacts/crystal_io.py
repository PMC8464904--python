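"""Crystal structure I/O and symmetry plumbing.

Reads a small-molecule CIF subset (cell, symmetry operators, atom sites),
expands the crystalline environment around the asymmetric unit, converts
between fractional and cartesian frames and partitions atoms into covalently
bonded molecules.  Coordinates are kept fractional internally; distances are
reported in angstroms.

CIF documents are parsed with :mod:`gemmi.cif`; symmetry triplets and
space-group names go through :class:`gemmi.Op` / :func:`gemmi.find_spacegroup_by_name`
so no symmetry symbol tables are maintained here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


class CifParseError(ValueError):
    """Raised when a CIF document is missing a required block or value."""


class GeometryError(ValueError):
    """Raised for degenerate cells or infeasible geometric requests."""


#: Cordero et al. (2008) single-bond covalent radii, angstrom.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Se": 1.20, "Br": 1.20,
    "I": 1.39,
}

#: Bonding tolerance added to the covalent-radii sum, angstrom.
BOND_TOLERANCE = 0.4

#: Guard against runaway symmetry expansion, angstrom.
MAX_EXPANSION_RADIUS = 15.0


# ---------------------------------------------------------------------------
# unit cell


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise GeometryError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise GeometryError("degenerate cell: volume <= 0")

    @property
    def volume(self) -> float:
        """Cell volume from the standard triclinic closed form, cubic angstrom."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise GeometryError("degenerate cell: volume <= 0")
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """Matrix M with cart = M @ frac (crystallographic convention, c* along z)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    def metric_tensor(self) -> np.ndarray:
        """G = M^T M; squared distance between fractional points is dx^T G dx."""
        m = self.orthogonalization_matrix
        return m.T @ m


def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Convert fractional coordinates to cartesian angstrom."""
    return cell.orthogonalization_matrix @ np.asarray(frac, dtype=float)


def cart_to_frac(cell: UnitCell, cart) -> np.ndarray:
    """Convert cartesian angstrom to fractional coordinates."""
    return np.linalg.solve(cell.orthogonalization_matrix, np.asarray(cart, dtype=float))


def distance(cell: UnitCell, frac_i, frac_j) -> float:
    """Crystallographic distance (angstrom) between two fractional points."""
    d = np.asarray(frac_j, dtype=float) - np.asarray(frac_i, dtype=float)
    return float(np.linalg.norm(cell.orthogonalization_matrix @ d))


# ---------------------------------------------------------------------------
# symmetry operators


@dataclass(frozen=True)
class SymOp:
    """Crystallographic symmetry operator acting on fractional coordinates."""

    rot: np.ndarray  # 3x3, integer-valued
    tran: np.ndarray  # 3-vector, cell fractions

    def __post_init__(self) -> None:
        rot = np.asarray(self.rot, dtype=float)
        tran = np.asarray(self.tran, dtype=float)
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "tran", tran)
        det = round(np.linalg.det(rot))
        if det not in (1, -1):
            raise GeometryError(f"symmetry rotation determinant must be +-1, got {det}")

    def apply(self, frac) -> np.ndarray:
        return self.rot @ np.asarray(frac, dtype=float) + self.tran

    def inverse(self) -> "SymOp":
        rinv = np.linalg.inv(self.rot)
        return SymOp(np.rint(rinv), -rinv @ self.tran)

    def triplet(self, shift=(0, 0, 0)) -> str:
        """Canonical 'x,y,z'-style code, optionally with an added lattice shift."""
        op = gemmi.Op()
        op.rot = [[int(round(v)) * gemmi.Op.DEN for v in row] for row in self.rot]
        op.tran = [int(round((t + s) * gemmi.Op.DEN)) for t, s in zip(self.tran, shift)]
        return op.triplet()

    def is_identity(self) -> bool:
        return np.array_equal(self.rot, np.eye(3)) and np.allclose(self.tran % 1.0, 0.0)

    def __eq__(self, other) -> bool:
        return (isinstance(other, SymOp)
                and np.array_equal(self.rot, other.rot)
                and np.allclose(self.tran, other.tran, atol=1e-9))

    def __hash__(self) -> int:
        return hash(self.triplet())


def parse_symop(code: str) -> SymOp:
    """Parse a symmetry code like ``"2 - x, -y, 1 - z"`` into a :class:`SymOp`.

    Unicode minus signs, en-dashes and arbitrary spacing are tolerated.
    """
    cleaned = code.replace("−", "-").replace("–", "-").strip()
    try:
        op = gemmi.Op(cleaned)
    except (RuntimeError, ValueError) as exc:
        raise CifParseError(f"malformed symmetry code {code!r}: {exc}") from exc
    den = float(gemmi.Op.DEN)
    return SymOp(np.array(op.rot, dtype=float) / den, np.array(op.tran, dtype=float) / den)


# ---------------------------------------------------------------------------
# structures


@dataclass
class AtomSite:
    """One atom of the asymmetric unit, in fractional coordinates."""

    label: str
    element: str
    frac: np.ndarray
    molecule_id: int | None = None

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if self.element not in COVALENT_RADII:
            raise CifParseError(
                f"unknown element symbol {self.element!r} for site {self.label!r}")


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operators + asymmetric-unit atom sites."""

    cell: UnitCell
    symops: list[SymOp]
    sites: list[AtomSite]
    name: str = ""

    def __post_init__(self) -> None:
        n_id = sum(1 for op in self.symops if op.is_identity())
        if n_id != 1:
            raise GeometryError(f"identity operator must appear exactly once, found {n_id}")
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise CifParseError("site labels must be unique")

    def cart(self, i: int) -> np.ndarray:
        return frac_to_cart(self.cell, self.sites[i].frac)


@dataclass(frozen=True)
class EnvironmentImage:
    """A symmetry image of an asymmetric-unit atom, with provenance."""

    site_index: int
    op_index: int
    shift: tuple[int, int, int]
    frac: np.ndarray
    cart: np.ndarray

    @property
    def is_original(self) -> bool:
        return self.op_index == 0 and self.shift == (0, 0, 0)

    def symcode(self, structure: CrystalStructure) -> str:
        return structure.symops[self.op_index].triplet(self.shift)


# ---------------------------------------------------------------------------
# CIF reading / writing


def _as_number(text: str) -> float:
    """Parse a CIF number, stripping a standard-uncertainty suffix like 4.286(2)."""
    val = gemmi.cif.as_number(text)
    if math.isnan(val):
        raise CifParseError(f"non-numeric CIF value {text!r}")
    return val


_CELL_TAGS = {
    "a": "_cell_length_a", "b": "_cell_length_b", "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha", "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}

_SYMOP_TAGS = ("_space_group_symop_operation_xyz", "_symmetry_equiv_pos_as_xyz")
_SG_NAME_TAGS = ("_space_group_name_H-M_alt", "_symmetry_space_group_name_H-M")


def parse_cif(text: str, name: str | None = None) -> CrystalStructure:
    """Parse a CIF 1.1 subset document into a :class:`CrystalStructure`.

    Requires cell parameters and an atom_site loop.  Symmetry comes from an
    explicit operator loop when present; otherwise a Hermann-Mauguin
    space-group name is resolved through gemmi's space-group table.  With
    neither, P1 (identity only) is assumed.
    """
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise CifParseError(f"unreadable CIF document: {exc}") from exc
    if len(doc) == 0:
        raise CifParseError("CIF document contains no data block")
    block = doc[0]

    cell_kwargs = {}
    for attr, tag in _CELL_TAGS.items():
        raw = block.find_value(tag)
        if raw is None:
            if attr in ("a", "b", "c"):
                raise CifParseError(f"missing cell block: no {tag} in CIF")
            continue
        cell_kwargs[attr] = _as_number(raw)
    cell = UnitCell(**cell_kwargs)

    symops: list[SymOp] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        codes = list(col)
        if codes:
            symops = [parse_symop(gemmi.cif.as_string(c)) for c in codes]
            break
    if not symops:
        for tag in _SG_NAME_TAGS:
            raw = block.find_value(tag)
            if raw is not None:
                sg_name = gemmi.cif.as_string(raw)
                sg = gemmi.find_spacegroup_by_name(sg_name)
                if sg is None:
                    raise CifParseError(f"unrecognized space-group name {sg_name!r}")
                den = float(gemmi.Op.DEN)
                symops = [
                    SymOp(np.array(op.rot, dtype=float) / den,
                          np.array(op.tran, dtype=float) / den)
                    for op in sg.operations()
                ]
                break
    if not symops:
        symops = [parse_symop("x,y,z")]

    tags = ["_atom_site_label", "_atom_site_type_symbol",
            "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"]
    table = block.find(tags)
    if len(table) == 0:
        raise CifParseError("missing atom_site loop in CIF")
    sites = []
    for row in table:
        sites.append(AtomSite(
            label=gemmi.cif.as_string(row[0]),
            element=gemmi.cif.as_string(row[1]),
            frac=np.array([_as_number(row[k]) for k in (2, 3, 4)]),
        ))
    return CrystalStructure(cell=cell, symops=symops, sites=sites,
                            name=name if name is not None else block.name)


def write_cif(structure: CrystalStructure) -> str:
    """Serialize a structure back to the same CIF subset (fixture writer)."""
    c = structure.cell
    lines = [f"data_{structure.name or 'crystal'}"]
    for tag, val in zip(_CELL_TAGS.values(), (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)):
        lines.append(f"{tag}   {val:.6f}")
    lines += ["loop_", "_space_group_symop_operation_xyz"]
    lines += [f"  '{op.triplet()}'" for op in structure.symops]
    lines += ["loop_", "_atom_site_label", "_atom_site_type_symbol",
              "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z"]
    for s in structure.sites:
        lines.append(f"  {s.label} {s.element} "
                     f"{s.frac[0]:.6f} {s.frac[1]:.6f} {s.frac[2]:.6f}")
    return "\n".join(lines) + "\n"


def read_xyz(text: str) -> tuple[list[str], np.ndarray, str]:
    """Read an XYZ document; returns (elements, cartesian angstrom Nx3, comment)."""
    lines = text.splitlines()
    if not lines:
        raise CifParseError("empty XYZ document")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise CifParseError("XYZ first line must be the atom count") from exc
    if len(lines) < n + 2:
        raise CifParseError(f"XYZ declares {n} atoms but has {len(lines) - 2} atom lines")
    comment = lines[1] if len(lines) > 1 else ""
    elements, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        elements.append(parts[0])
        coords.append([float(x) for x in parts[1:4]])
    return elements, np.array(coords, dtype=float), comment


def write_xyz(elements, coords, comment: str = "") -> str:
    coords = np.asarray(coords, dtype=float)
    lines = [str(len(elements)), comment]
    for el, xyz in zip(elements, coords):
        lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# environment expansion


def expand_environment(structure: CrystalStructure, radius: float,
                       max_radius: float = MAX_EXPANSION_RADIUS) -> list[EnvironmentImage]:
    """Generate all symmetry/lattice images within ``radius`` of the asymmetric unit.

    Every returned image carries provenance (operator index + lattice shift) so
    downstream contacts can be reported with crystallographic symmetry codes.
    The original asymmetric-unit atoms are included (op 0, zero shift).
    """
    if radius <= 0:
        raise GeometryError("expansion radius must be positive")
    if radius > max_radius:
        raise GeometryError(
            f"expansion radius {radius} A exceeds the configured cap {max_radius} A")

    cell = structure.cell
    m = cell.orthogonalization_matrix
    asym_frac = np.array([s.frac for s in structure.sites])
    asym_cart = asym_frac @ m.T
    tree = cKDTree(asym_cart)

    # conservative shift block: radius plus asymmetric-unit extent, over the
    # perpendicular widths of the cell slabs
    inv = np.linalg.inv(m)
    perp = 1.0 / np.linalg.norm(inv, axis=1)  # d-spacing of (100),(010),(001)
    extent = np.ptp(asym_cart, axis=0).max() if len(asym_cart) > 1 else 0.0
    nmax = np.ceil((radius + extent) / perp).astype(int) + 1

    images: list[EnvironmentImage] = []
    for op_idx, op in enumerate(structure.symops):
        base = asym_frac @ op.rot.T + op.tran
        for sa in range(-nmax[0], nmax[0] + 1):
            for sb in range(-nmax[1], nmax[1] + 1):
                for sc in range(-nmax[2], nmax[2] + 1):
                    shift = (sa, sb, sc)
                    frac = base + np.array(shift, dtype=float)
                    cart = frac @ m.T
                    near = tree.query_ball_point(cart, radius)
                    for site_idx, neighbours in enumerate(near):
                        if not neighbours:
                            continue
                        images.append(EnvironmentImage(
                            site_index=site_idx, op_index=op_idx, shift=shift,
                            frac=frac[site_idx], cart=cart[site_idx]))
    # deduplicate images that coincide in space (special positions)
    unique: dict[tuple, EnvironmentImage] = {}
    for img in images:
        key = (img.site_index, tuple(np.round(img.frac, 6)))
        if key not in unique or img.is_original:
            unique[key] = img
    return sorted(unique.values(),
                  key=lambda im: (im.site_index, im.op_index, im.shift))


# ---------------------------------------------------------------------------
# molecule detection


def bond_matrix(cell: UnitCell, sites: list[AtomSite],
                tol: float = BOND_TOLERANCE) -> np.ndarray:
    """Boolean covalent-bond adjacency within the asymmetric unit.

    Atoms are bonded when the minimum-image distance does not exceed the sum of
    their Cordero covalent radii plus ``tol``.
    """
    n = len(sites)
    m = cell.orthogonalization_matrix
    radii = np.array([COVALENT_RADII[s.element] for s in sites])
    frac = np.array([s.frac for s in sites])
    adj = np.zeros((n, n), dtype=bool)
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)])
    for i in range(n):
        d = frac[None, :, :] + shifts[:, None, :] - frac[i]
        dist = np.linalg.norm(d @ m.T, axis=2).min(axis=0)
        cut = radii[i] + radii + tol
        adj[i] = (dist <= cut) & (np.arange(n) != i)
    return adj | adj.T


def detect_molecules(structure: CrystalStructure,
                     tol: float = BOND_TOLERANCE) -> list[int]:
    """Assign molecule ids (connected covalent components) to every site.

    Components are labelled deterministically: the molecule containing the
    lowest site index gets id 0, the next unseen lowest index id 1, and so on.
    Isolated atoms become singleton molecules.  Ids are written back onto the
    sites and also returned.
    """
    n = len(structure.sites)
    if n == 0:
        return []
    adj = bond_matrix(structure.cell, structure.sites, tol)
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    _, labels = connected_components(graph, directed=False)
    relabel: dict[int, int] = {}
    out = []
    for idx in range(n):
        lab = labels[idx]
        if lab not in relabel:
            relabel[lab] = len(relabel)
        out.append(relabel[lab])
    for site, mid in zip(structure.sites, out):
        site.molecule_id = mid
    return out
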