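# crystalcontacts

Analysis of weak intermolecular interactions in molecular crystals —
halogen bonds, hydrogen bonds and van der Waals contacts — for
crystallographers and computational chemists studying crystal packing.
The package was built around two halogenated oxindole structures
(6-bromooxindole and its 4-fluoro analogue, both P2₁/c) but every component
is generic.

It covers four stages of a typical contact-energetics study:

1. **Short-contact screening** — read a CIF, expand the symmetry environment,
   partition atoms into molecules, and report every intermolecular pair with
   `d < r_vdW(i) + r_vdW(j)` (Bondi radii by default). Halogen···halogen
   contacts are typed from the two C–X···X angles:
   Type I (symmetric dispersion contact, |θ₁ − θ₂| ≤ 15°),
   Type II (σ-hole bond, |θ₁ − θ₂| ≥ 30°), or *quasi* in between.
   Hydrogen-bond dimers are condensed to Etter graph-set ring motifs such as
   the amide R²₂(8) ring.
2. **QTAIM energetics** — ingest bond-critical-point properties
   (ρ, ∇²ρ, G, V, λ₂ in atomic units; CSV or a Multiwfn-style text dialect),
   audit them against the local virial identity ∇²ρ = 4(2G + V), classify each
   point (closed-shell: ∇²ρ > 0 ∧ H > 0; non-covalent: |G/V| > 1; attractive:
   λ₂ < 0), and estimate per-contact energies with four literature schemes:

   | scheme | estimator (a.u. → kcal/mol) |
   |--------|------------------------------|
   | E_HB   | 0.5·V (Espinosa) |
   | E_XB^a | 0.58·V (Tsirelson) |
   | E_XB^b | 0.57·(−G) (Tsirelson) |
   | E_XB^c | 0.375·V (Bauzá) |
   | E_XB^d | −(0.128·G² − 0.824·G + 1.66), kcal/mol directly (Kuznetsov) |

   Per-dimer sums E_cont run over attractive BCPs only; scheme *d* mixes the
   Espinosa rule for hydrogen-bond-type points with the Kuznetsov quadratic
   for halogen-type points. Supramolecular interaction energies
   E_int = E_dimer − (E_mon1 + E_mon2) with counterpoise BSSE correction are
   book-kept alongside (hartree in, kcal/mol out, ×627.5095 applied once).
3. **Promolecular NCI analysis** — a geometry-only reduced-density-gradient
   field s = |∇ρ| / (2(3π²)^⅓ ρ^4/3) over a promolecular density (sum of
   exponential free-atom models with analytic derivatives), sign(λ₂)·ρ
   signing, damped-Newton critical-point search, and scatter/grid export.
4. **Synthetic data** — toy crystals with contacts planted at exact distances
   and angles, class-conditional BCP tables with separately stored ground
   truth, and energy manifests engineered to hit target interaction energies.

## Worked example

```python
import crystalcontacts as cc

records = cc.load_reference_bcp_table()     # packaged MP2/def2-TZVP BCP table
table = cc.dimer_contact_sums([r for r in records if r.dimer_id == "1-BrBr"])
print(f"{table.econt_a:.3f} {table.econt_b:.3f} "
      f"{table.econt_c:.3f} {table.econt_d:.3f}")
```

prints

```
-1.368 -1.831 -0.885 -1.656
```

— the four contact-energy estimates (kcal/mol) for the Br···Br dimer of
6-bromooxindole from its single attractive bond critical point
(V = −0.376×10⁻², G = 0.512×10⁻² a.u.). The spread across schemes (−0.9 to
−1.8 kcal/mol) is the method uncertainty of QTAIM contact estimators; all
agree this Type I halogen contact is weakly attractive.

From a shell, the same pipelines are exposed as subcommands:

```sh
crystalcontacts fixtures brbr -o toy.cif      # synthetic Type I Br...Br crystal
crystalcontacts contacts toy.cif              # Table-style short-contact CSV
crystalcontacts energies path/to/bcp.csv --paper-mask
crystalcontacts audit path/to/bcp.csv         # virial-identity consistency check
crystalcontacts rdg dimer.xyz --spacing 0.2   # NCI scatter + region counts
```

The `contacts` command on the fixture above prints one row:
`X...X,Br1,Br1,"-x,-y,-z",3.525,-0.175,169.60,169.60,Type I`.

### Multiwfn-style CP text dialect

`load_multiwfn_cp_text` reads blocks separated by `----` rules containing a
`CP <n>` header and the lines `Density of all electrons:`, `Laplacian of
electron density:`, `Lagrangian kinetic energy G(r):`, `Potential energy
density V(r):` and `Eigenvalues of Hessian:` (middle eigenvalue = λ₂);
Fortran `D` exponents are accepted.

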