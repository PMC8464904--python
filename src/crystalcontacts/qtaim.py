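"""QTAIM bond-critical-point energetics for intermolecular contacts.

Ingests tables of critical-point properties (electron density rho, Laplacian,
Lagrangian kinetic energy density G, potential energy density V, second
Hessian eigenvalue lambda2 — all in atomic units), audits them against the
local virial identity (1/4)·del2(rho) = 2G + V, classifies each contact
(closed-shell, non-covalent, attractive, density regime), and estimates
per-contact and per-dimer interaction energies with four literature schemes:

===========  ============================================  =================
scheme       estimator (a.u. in, kcal/mol out)             reference rule
===========  ============================================  =================
``HB``       0.5 · V                                       Espinosa
``a``        0.58 · V                                      Tsirelson
``b``        0.57 · (−G)                                   Tsirelson
``c``        0.375 · V                                     Bauza
``d``        −(0.128·G² − 0.824·G + 1.66)  [kcal/mol]      Kuznetsov
===========  ============================================  =================

Dimer sums apply a single scheme uniformly, except scheme ``d`` which mixes by
contact type: hydrogen-bond-type BCPs (N-H...O, C-H...O) use the Espinosa rule
while halogen-involving BCPs use the Kuznetsov quadratic.  Supramolecular
interaction energies E_int = E_dimer − (E_mon1 + E_mon2) with counterpoise
BSSE correction are book-kept alongside.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Hartree -> kcal/mol, applied exactly once at output.
HARTREE_TO_KCAL = 627.5095

#: rho (a.u.) separating the hydrogen-bond regime (~1e-2) from the vdW regime (~1e-3).
RHO_REGIME_THRESHOLD = 5e-3

#: Default relative tolerance for the local virial audit.
VIRIAL_TOL_REL = 0.02
#: Absolute tolerance (a.u.) for printed-H vs G+V: half-ulps of 3-decimal x1e-2 inputs.
H_PRINT_TOL = 1.5e-5

#: Fitted range guard for the Kuznetsov quadratic, a.u.
KUZNETSOV_G_RANGE = (0.0, 0.1)

SCHEMES = ("HB", "a", "b", "c", "d")
_V_COEFF = {"HB": 0.5, "a": 0.58, "c": 0.375}

_REQUIRED_COLUMNS = ("dimer_id", "cp_index", "rho", "lap", "G", "V",
                     "lambda2", "contact_type")


class SchemeError(ValueError):
    """Raised for unknown schemes or estimator inputs outside the fitted range."""


@dataclass
class BCPRecord:
    """One critical point's QTAIM scalars, atomic units.

    ``contact_type`` is ``"HB"`` for hydrogen-bond-type acceptor contacts
    (N-H...O, C-H...O) and ``"XB"`` for halogen-involving contacts.  The total
    energy density H and the |G/V| ratio are always derived, never read;
    printed values of either may be attached for auditing.
    """

    dimer_id: str
    cp_index: int
    rho: float
    lap: float
    G: float
    V: float
    lambda2: float
    contact_type: str = "XB"
    contact: str = ""
    h_printed: float | None = None
    ratio_printed: float | None = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"rho must be positive (dimer {self.dimer_id} "
                             f"CP {self.cp_index})")
        if self.G < 0:
            raise ValueError(f"G must be non-negative (dimer {self.dimer_id})")
        if self.V > 0:
            raise ValueError(f"V must be non-positive (dimer {self.dimer_id})")
        if self.contact_type not in ("HB", "XB"):
            raise ValueError(f"contact_type must be HB or XB, got {self.contact_type!r}")

    @property
    def H(self) -> float:
        """Total energy density H = G + V (derived)."""
        return self.G + self.V

    @property
    def ratio(self) -> float:
        """|G/V| (derived); > 1 marks a fully non-covalent interaction."""
        return abs(self.G / self.V)


@dataclass(frozen=True)
class InteractionClass:
    """QTAIM classification flags for one critical point."""

    closed_shell: bool  # del2(rho) > 0 and H > 0
    noncovalent: bool   # |G/V| > 1
    attractive: bool    # lambda2 < 0
    regime: str         # "hydrogen-bond" (rho ~ 1e-2) or "vdW" (rho ~ 1e-3)


@dataclass
class DimerEnergyTable:
    """Per-dimer energy summary, kcal/mol.  None marks an unavailable field."""

    dimer_id: str
    eint: float | None = None
    eint_bsse: float | None = None
    econt_hb: float | None = None
    econt_a: float | None = None
    econt_b: float | None = None
    econt_c: float | None = None
    econt_d: float | None = None

    def econt(self, scheme: str) -> float | None:
        return getattr(self, "econt_hb" if scheme == "HB" else f"econt_{scheme}")


@dataclass
class EnergyManifest:
    """Monomer/dimer electronic totals for the supramolecular bookkeeping.

    All energies in hartree; ``units`` must say so explicitly.  The
    counterpoise correction is stored with the sign convention that adding it
    makes the interaction energy less negative (bsse_correction >= 0 for a
    normal overbinding correction).
    """

    e_dimer: float
    e_mon1: float
    e_mon2: float
    bsse_correction: float = 0.0
    units: str = "hartree"

    def __post_init__(self) -> None:
        if self.units != "hartree":
            raise ValueError(f"energy manifest units must be 'hartree', got {self.units!r}")


# ---------------------------------------------------------------------------
# loading


_SCALE_RE = re.compile(r"^(?P<name>\w+?)\s*[x×]\s*10\^?\(?(?P<exp>[-−+]?\d+)\)?$")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Resolve scaling suffixes in column headers, e.g. ``"rho x10-2"``."""
    out = df.copy()
    rename, scale = {}, {}
    for col in df.columns:
        m = _SCALE_RE.match(str(col).strip())
        if m:
            rename[col] = m.group("name")
            scale[m.group("name")] = 10.0 ** int(m.group("exp").replace("−", "-"))
    out = out.rename(columns=rename)
    for name, factor in scale.items():
        out[name] = pd.to_numeric(out[name]) * factor
    return out


def load_bcp_table(source) -> list[BCPRecord]:
    """Load BCP records from a CSV file path, file object, or CSV text.

    Required columns: dimer_id, cp_index, rho, lap, G, V, lambda2,
    contact_type (all values a.u.).  Optional: contact, H_printed,
    ratio_printed.  Column headers may carry scaling suffixes such as
    ``rho x10-2``, which are resolved on load.  H and |G/V| are derived, never
    read.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, comment="#")
    df = _normalize_columns(df)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"BCP table is missing required columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        numeric = {}
        for col in ("rho", "lap", "G", "V", "lambda2"):
            try:
                numeric[col] = float(row[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {row[col]!r} in column {col!r}, row {idx}"
                ) from None
        records.append(BCPRecord(
            dimer_id=str(row["dimer_id"]), cp_index=int(row["cp_index"]),
            contact=str(row.get("contact", "")),
            contact_type=str(row["contact_type"]),
            h_printed=float(row["H_printed"]) if "H_printed" in df.columns else None,
            ratio_printed=(float(row["ratio_printed"])
                           if "ratio_printed" in df.columns else None),
            **numeric,
        ))
    return records


_MULTIWFN_CP_RE = re.compile(r"CP\s+(?P<idx>\d+)")
_MULTIWFN_FIELDS = {
    "rho": re.compile(r"Density of all electrons:\s*(?P<v>[-+0-9.ED]+)"),
    "lap": re.compile(r"Laplacian of electron density:\s*(?P<v>[-+0-9.ED]+)"),
    "G": re.compile(r"Lagrangian kinetic energy G\(r\):\s*(?P<v>[-+0-9.ED]+)"),
    "V": re.compile(r"Potential energy density V\(r\):\s*(?P<v>[-+0-9.ED]+)"),
}
_MULTIWFN_EIG_RE = re.compile(
    r"Eigenvalues of Hessian:\s*(?P<l1>[-+0-9.ED]+)\s+(?P<l2>[-+0-9.ED]+)\s+(?P<l3>[-+0-9.ED]+)")


def load_multiwfn_cp_text(text: str, dimer_id: str,
                          contact_type: str = "XB") -> list[BCPRecord]:
    """Parse a Multiwfn-style critical-point property text block.

    The dialect (documented in the README): blocks starting with a header line
    containing ``CP  <n>``, followed by ``Density of all electrons:``,
    ``Laplacian of electron density:``, ``Lagrangian kinetic energy G(r):``,
    ``Potential energy density V(r):`` lines and an ``Eigenvalues of Hessian:``
    line whose middle value is lambda2.  Fortran ``D`` exponents accepted.
    """
    records = []
    chunks = re.split(r"-{4,}", text)
    pending_idx = None
    for chunk in chunks:
        m = _MULTIWFN_CP_RE.search(chunk)
        fields = {}
        for name, pattern in _MULTIWFN_FIELDS.items():
            fm = pattern.search(chunk)
            if fm:
                fields[name] = float(fm.group("v").replace("D", "E"))
        em = _MULTIWFN_EIG_RE.search(chunk)
        if m and not fields:
            pending_idx = int(m.group("idx"))
            continue
        if fields:
            if len(fields) < 4 or em is None:
                raise ValueError("incomplete critical-point block in CP text")
            idx = int(m.group("idx")) if m else (pending_idx or len(records) + 1)
            records.append(BCPRecord(
                dimer_id=dimer_id, cp_index=idx, contact_type=contact_type,
                lambda2=float(em.group("l2").replace("D", "E")), **fields))
            pending_idx = None
    return records


def load_reference_bcp_table() -> list[BCPRecord]:
    """Packaged MP2/def2-TZVP BCP table for the eight oxindole dimers."""
    path = resources.files("crystalcontacts.data") / "bcp_table_mp2.csv"
    return load_bcp_table(str(path))


def load_reference_energies() -> pd.DataFrame:
    """Packaged per-dimer published energies (kcal/mol), NaN where masked."""
    path = resources.files("crystalcontacts.data") / "dimer_energies_mp2.csv"
    return pd.read_csv(str(path), comment="#")


def load_reference_contacts() -> pd.DataFrame:
    """Packaged short-contact table for structures 1 and 2 (angstrom)."""
    path = resources.files("crystalcontacts.data") / "short_contacts.csv"
    return pd.read_csv(str(path), comment="#")


# ---------------------------------------------------------------------------
# audit and classification


def audit_bcp(record: BCPRecord, tol_rel: float = VIRIAL_TOL_REL,
              tol_h: float = H_PRINT_TOL) -> list[str]:
    """Consistency flags for one record; an empty list means it passes.

    ``virial_mismatch``: the local virial identity del2(rho) = 4·(2G + V)
    fails beyond ``tol_rel`` relative to |del2(rho)|.  ``H_mismatch``: a
    printed H disagrees with G + V beyond printing-rounding tolerance.  The
    audit never raises.
    """
    flags = []
    expected_lap = 4.0 * (2.0 * record.G + record.V)
    denom = max(abs(record.lap), 1e-12)
    if abs(record.lap - expected_lap) > tol_rel * denom:
        flags.append("virial_mismatch")
    if record.h_printed is not None and abs(record.h_printed - record.H) > tol_h:
        flags.append("H_mismatch")
    return flags


def audit_table(records: list[BCPRecord], **kwargs) -> dict[tuple[str, int], list[str]]:
    """Audit every record; returns only the entries that raised flags."""
    out = {}
    for rec in records:
        flags = audit_bcp(rec, **kwargs)
        if flags:
            out[(rec.dimer_id, rec.cp_index)] = flags
    return out


def classify_bcp(record: BCPRecord,
                 rho_regime_threshold: float = RHO_REGIME_THRESHOLD) -> InteractionClass:
    """QTAIM classification: closed-shell, non-covalent, attractive, density regime."""
    return InteractionClass(
        closed_shell=record.lap > 0 and record.H > 0,
        noncovalent=record.ratio > 1.0,
        attractive=record.lambda2 < 0,
        regime=("hydrogen-bond" if record.rho >= rho_regime_threshold else "vdW"),
    )


# ---------------------------------------------------------------------------
# contact-energy schemes


def contact_energy(record: BCPRecord, scheme: str) -> float:
    """Single-contact interaction energy (kcal/mol) under one estimator scheme.

    Schemes HB/a/c scale V; scheme b scales −G; both are converted from
    hartree.  Scheme d evaluates the Kuznetsov quadratic with G in a.u. and
    yields kcal/mol directly, negated (the fit targets −E).
    """
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme in _V_COEFF:
        return _V_COEFF[scheme] * record.V * HARTREE_TO_KCAL
    if scheme == "b":
        return -0.57 * record.G * HARTREE_TO_KCAL
    g = record.G
    lo, hi = KUZNETSOV_G_RANGE
    if not lo <= g <= hi:
        raise SchemeError(
            f"scheme d: G = {g} a.u. outside the fitted range [{lo}, {hi}]")
    return -(0.128 * g * g - 0.824 * g + 1.66)


def _mixed_scheme_d(record: BCPRecord) -> float:
    """Scheme-d contribution: Espinosa rule for HB-typed BCPs, Kuznetsov for XB."""
    if record.contact_type == "HB":
        return contact_energy(record, "HB")
    return contact_energy(record, "d")


def dimer_contact_sums(records: list[BCPRecord],
                       dimer_id: str | None = None) -> DimerEnergyTable:
    """Per-dimer contact-energy sums over attractive (lambda2 < 0) BCPs only.

    Schemes HB/a/b/c apply their coefficient uniformly to every attractive
    BCP; scheme d mixes the Espinosa rule (HB-typed) with the Kuznetsov
    quadratic (XB-typed).  With no attractive BCPs all energy fields stay None
    and the reason is logged.
    """
    if dimer_id is None:
        ids = {r.dimer_id for r in records}
        if len(ids) != 1:
            raise ValueError(f"records span several dimers: {sorted(ids)}")
        dimer_id = ids.pop()
    attractive = [r for r in records if classify_bcp(r).attractive]
    table = DimerEnergyTable(dimer_id=dimer_id)
    if not attractive:
        log.warning("dimer %s has no attractive BCPs (lambda2 < 0): "
                    "contact energies unavailable", dimer_id)
        return table
    table.econt_hb = sum(contact_energy(r, "HB") for r in attractive)
    table.econt_a = sum(contact_energy(r, "a") for r in attractive)
    table.econt_b = sum(contact_energy(r, "b") for r in attractive)
    table.econt_c = sum(contact_energy(r, "c") for r in attractive)
    table.econt_d = sum(_mixed_scheme_d(r) for r in attractive)
    return table


def all_dimer_sums(records: list[BCPRecord]) -> list[DimerEnergyTable]:
    """Contact-energy sums per dimer, in first-appearance order."""
    order: list[str] = []
    grouped: dict[str, list[BCPRecord]] = {}
    for rec in records:
        if rec.dimer_id not in grouped:
            order.append(rec.dimer_id)
            grouped[rec.dimer_id] = []
        grouped[rec.dimer_id].append(rec)
    return [dimer_contact_sums(grouped[d], d) for d in order]


def apply_report_mask(table: DimerEnergyTable,
                      records: list[BCPRecord]) -> DimerEnergyTable:
    """Blank fields the published layout prints as dashes (report layer only).

    Dimers without any HB-typed attractive BCP do not report an EcontHB column;
    dimers whose attractive BCPs are all HB-typed report only EcontHB and the
    Bauza column.
    """
    attractive = [r for r in records
                  if r.dimer_id == table.dimer_id and classify_bcp(r).attractive]
    types = {r.contact_type for r in attractive}
    masked = DimerEnergyTable(**vars(table))
    if "HB" not in types:
        masked.econt_hb = None
    if types == {"HB"}:
        masked.econt_a = masked.econt_b = masked.econt_d = None
    return masked


# ---------------------------------------------------------------------------
# supramolecular bookkeeping


def interaction_energy(manifest: EnergyManifest) -> tuple[float, float]:
    """(E_int, E_int(BSSE)) in kcal/mol from hartree totals.

    E_int = E_dimer − (E_mon1 + E_mon2); the counterpoise correction is added
    on top (making the result less negative for a positive correction).
    """
    for name in ("e_dimer", "e_mon1", "e_mon2"):
        if getattr(manifest, name) is None:
            raise ValueError(f"energy manifest is missing {name}")
    eint = (manifest.e_dimer - (manifest.e_mon1 + manifest.e_mon2)) * HARTREE_TO_KCAL
    eint_bsse = eint + manifest.bsse_correction * HARTREE_TO_KCAL
    return eint, eint_bsse


def load_energy_manifest(source) -> EnergyManifest:
    """Read a JSON energy manifest (hartree totals per species)."""
    if isinstance(source, (str, Path)) and not str(source).lstrip().startswith("{"):
        text = Path(source).read_text()
    else:
        text = str(source)
    data = json.loads(text)
    return EnergyManifest(
        e_dimer=data["e_dimer"], e_mon1=data["e_mon1"], e_mon2=data["e_mon2"],
        bsse_correction=data.get("bsse_correction", 0.0),
        units=data.get("units", "unspecified"))


def rank_dimers(tables: list[DimerEnergyTable]) -> list[DimerEnergyTable]:
    """Order dimers by E_int(BSSE) ascending (most negative = strongest first).

    Stable; ties broken lexicographically by dimer id.
    """
    missing = [t.dimer_id for t in tables if t.eint_bsse is None]
    if missing:
        raise ValueError(f"E_int(BSSE) missing for dimers: {missing}")
    return sorted(tables, key=lambda t: (t.eint_bsse, t.dimer_id))


# ---------------------------------------------------------------------------
# RDG scatter regions


#: |sign(lambda2)·rho| (a.u.) below which a scatter point reads as vdW ("green").
RDG_SLR_CUT = 0.01


def rdg_point_class(s: float, slr: float, cut: float = RDG_SLR_CUT) -> str:
    """NCI scatter-region label for one (RDG, sign(lambda2)·rho) point.

    ``blue``: strongly attractive (slr < −cut, hydrogen-bond-like);
    ``green``: van der Waals (|slr| <= cut); ``red``: repulsive (slr > cut).
    """
    if s < 0:
        raise ValueError("the reduced density gradient is non-negative")
    if slr < -cut:
        return "blue"
    if slr > cut:
        return "red"
    return "green"
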