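# Methods

## Scope and model

The package treats a molecular crystal as a unit cell, a list of symmetry
operators acting on fractional coordinates, and an asymmetric unit of atom
sites. All geometry is carried fractionally; cartesian frames use the
standard crystallographic orthogonalisation (a along x, b in the xy plane),
and distances are reported in ångströms to 3 decimals, matching the precision
of published contact tables. Standard uncertainties in parentheses are
stripped on input, never stored.

Three layers sit on top:

* **contact screening** — a contact is "short" when
  d ≤ r_vdW(i) + r_vdW(j) + tol, with tol defaulting to 0 (the strict
  less-than-vdW criterion) and Bondi (1964) radii
  (H 1.20, C 1.70, N 1.55, O 1.52, F 1.47, Br 1.85 Å); the table is
  swappable. Covalent connectivity (for molecule partitioning and for
  identifying the atom bonded to a halogen or hydrogen) uses Cordero (2008)
  radii plus a 0.4 Å tolerance, the common crystallographic convention.
* **QTAIM energetics** — operates purely on tabulated critical-point scalars;
  no wavefunctions are evaluated. The total energy density H = G + V and the
  ratio |G/V| are always re-derived from G and V rather than read, so printed
  derived columns can be audited instead of trusted.
* **promolecular NCI** — a geometry-only approximation of reduced-density-
  gradient analysis, detailed below.

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| contact tolerance | 0.0 | Å | strict "below vdW sum" screening |
| bonding tolerance | 0.4 | Å | Cordero radii convention |
| Type I max asymmetry | 15 | deg | symmetric-contact convention (Cavallo-style); sources rarely state thresholds |
| Type II min asymmetry | 30 | deg | as above; the band between is "quasi" |
| H-bond angle minimum | 110 | deg | admits bent C-H···O contacts while excluding side-on geometries |
| ρ regime threshold | 5×10⁻³ | a.u. | midpoint separating "ρ ≈ 10⁻²" (hydrogen-bond regime) from "ρ ≈ 10⁻³" (vdW regime) language |
| virial audit tolerance | 2% | relative | see below |
| printed-H audit tolerance | 1.5×10⁻⁵ | a.u. | sum of half-ulps of 3-decimal ×10⁻² inputs |
| hartree→kcal/mol | 627.5095 | — | applied exactly once, at output |
| Kuznetsov G guard | [0, 0.1] | a.u. | quadratic fit range; outside it the estimator is extrapolation |
| RDG slr cut | 0.01 | a.u. | blue/green/red region boundary on sign(λ₂)ρ |
| expansion radius cap | 15 | Å | guards runaway symmetry expansion |

## Energy schemes and the mixed scheme-d rule

Per-contact estimates (kcal/mol) from a single BCP: 0.5·V (Espinosa,
hydrogen bonds), 0.58·V and 0.57·(−G) (Tsirelson), 0.375·V (Bauzá), and the
Kuznetsov quadratic −(0.128·G² − 0.824·G + 1.66) which takes G in a.u. and
returns kcal/mol directly — the unit convention was fixed by requiring the
packaged reference dimers to reproduce their published sums, and is guarded
by the fit-range check on G.

Dimer sums include only attractive critical points (λ₂ < 0); positive-λ₂
rows are ring critical points inside dimer ring motifs and carry no pairwise
energy. Schemes HB/a/b/c apply their coefficient uniformly to every
attractive point, which makes the column ratios exact
(E_cont^c = 0.75·E_cont^HB, E_cont^a = 1.16·E_cont^HB) — a deliberate
consequence locked in by tests. Scheme d is the one type-aware scheme:
hydrogen-bond-type points (N-H···O, C-H···O acceptors) use the Espinosa rule
and halogen-involving points (Br···Br, C-H···Br, C-F···H) use the Kuznetsov
quadratic. The published table's dash pattern (no EcontHB column for pure
halogen dimers, no a/b/d columns for pure hydrogen-bond dimers) is treated
as a report-layer mask, applied only at output; the computation always fills
every field it can.

## The virial audit

In atomic units the local virial theorem gives (1/4)∇²ρ = 2G + V at every
point of the density, so a self-consistent table must satisfy
∇²ρ = 4(2G + V) up to printing rounding. With inputs printed to 3 decimals
at ×10⁻² scale, rounding can move 4(2G+V) by about 6×10⁻⁵ a.u., well under
1% of typical Laplacians here; the default 2% relative tolerance therefore
passes every rounding-limited row while catching order-of-magnitude and
missing-digit typos. On the packaged reference table the audit isolates
exactly three cells (one Laplacian an order of magnitude too small, two
potential-energy densities apparently missing a leading zero); the fixtures
keep the printed values and the audit is the mechanism that marks them. The
same two V cells are the only rows whose *derived* |G/V| drops below 1 while
the printed ratio column stays above 1 — consistent with the missing-zero
reading.

## Promolecular RDG approximation

The promolecular density is a sum of spherical atomic terms
ρ_at(r) = Σ c_k·exp(−r/ζ_k) with at most three terms per element. The
default parameters are a Slater-screened shell model built by this package
(synthetic, not fitted to reference densities): shells get decay lengths
ζ = n*/2Z_eff from Slater's screening rules, grouped core/mid/valence, with
coefficients c = N/(8πζ³) normalising each term to its electron count; the
parameters ship as a JSON data file and can be overridden. Gradients and
Hessians are analytic, which makes the RDG field and Newton critical-point
searches cheap and exactly consistent with the density.

Properties that hold for such fields and are tested numerically: the
internuclear s-minimum coincides with the (3,−1) critical point; an isolated
atom has s ∝ ρ^(−1/3)/ζ, so outside the core no point combines low s with
non-covalent density — interaction troughs are therefore unambiguous.
Region counting for scatter summaries uses an NCI-style density cap
(|sign(λ₂)ρ| ≤ 0.05 a.u.) and an RDG cap (s ≤ 1) so cores and covalent
bonds never masquerade as contacts.

This layer is explicitly an approximation: no quantitative agreement with
correlated ab initio RDG values is claimed, and all of its guarantees are
structural (derivative consistency to 1e−6 relative, critical-point
signatures, equivariance under rigid motions, presence/absence of troughs).

## Synthetic data: what it emulates and what it does not

* **Toy crystals** plant one contact motif with exact geometry under real
  space-group operators: a Br-CH₃ fragment whose inversion image realises a
  Br···Br contact at a chosen distance and C-Br···Br angle (inversion forces
  θ₁ = θ₂, i.e. Type I), and a four-atom amide fragment whose inversion image
  forms the double N-H···O ring (R²₂(8), 180° donor angles by construction).
  Molecules are minimal planted-geometry fragments, not oxindoles: recovery
  tests need exact geometric ground truth, not chemistry. Feasibility (the
  dimer must fit well inside the cell) is checked before writing; every
  fixture ships a machine-readable answer manifest so tests never re-derive
  ground truth from the fixture itself. Generated text is byte-identical
  under a fixed seed.
* **BCP tables** draw ρ per class (hydrogen-bond U(1e−2, 3e−2), vdW and ring
  U(1e−3, 9e−3) a.u.), G = f·ρ with class factors f_HB = 1.3 and
  f_vdW = 0.8 (±15% jitter) taken from the observed G/ρ ranges of the two
  regimes, V = −G/r with r ~ U(1.1, 1.7), λ₂ sign by class, and the
  Laplacian from the virial identity with optional multiplicative noise on
  the Laplacian only — so audit tests and classification tests stay
  independent. Because the vdW density range genuinely straddles the regime
  threshold (as real tables do), the regime ground-truth label is assigned
  from the drawn ρ at generation time; attractiveness, closed-shell and
  non-covalency labels are planted by construction and recovered exactly at
  zero noise.
* **Energy manifests** draw arbitrary monomer baselines and solve the dimer
  total and counterpoise correction from the target energies; the round trip
  is exact to floating point.

Passing these tests shows the pipeline's rules are implemented correctly and
are mutually consistent; it does not validate any quantum-chemical claim
about real densities, which enter only through ingested tables.

## Numerical choices and degenerate inputs

Newton critical-point searches damp steps to a 0.3 bohr trust radius, fall
back to steepest descent on singular Hessians, require |∇ρ| < 1e−10 a.u.,
and raise (carrying the last iterate) after 200 steps. Field evaluation
raises at nuclear cusps. Plane fitting uses the smallest principal axis and
rejects collinear point sets; interplanar angles are folded to [0°, 90°].
Contact deduplication canonicalises (i, j, op) against (j, i, op⁻¹) by
lexicographic order on labels and symmetry code, so output ordering is
deterministic and relabel-invariant. Dimer ranking sorts by E_int(BSSE)
ascending with lexicographic tie-breaks. Dimers with no attractive BCPs
yield null energy fields with a logged reason rather than zeros.

Space-group names without an explicit operator loop are resolved through
gemmi's symmetry tables (an explicit xyz loop always wins); this avoids
maintaining any symbol-table dialect here while still accepting the common
"name-only" CIFs. Hydrogen positions are used exactly as given in the file —
no X-H bond-length normalisation — because typical source structures use
riding-model hydrogens.

## Problem sizes

The reference analyses (22 critical points, 8 dimers, 15 published contact
rows) run in well under a second. RDG property tests use 0.2–0.3 Å grids
over small fragments (~10⁴ points); finite-difference derivative checks use
100 random five-atom configurations. These sizes were chosen as the smallest
that exercise every code path with comfortable numerical margins.

## Known limitations

* No anisotropic displacement parameters, disorder, occupancy or powder
  data; no structure refinement.
* Ring-motif analysis is dimer-level only — no extended graph-set analysis.
* The promolecular model ignores charge redistribution entirely, so relative
  trough depths between chemically different contacts are not meaningful.
* Scheme coefficients are literature fits for specific interaction families;
  applying them outside hydrogen/halogen-bond regimes is extrapolation.
* Real-structure geometry tests live in synthetic fixtures: published cell
  metadata ships with the package, but fractional coordinates of the source
  structures do not, so deposited CIFs remain optional external inputs.
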