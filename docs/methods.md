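# Methods

## Model

A conformer ensemble is described by relative electronic energies E_i
(kcal/mol, referenced to the global minimum) and optional temperature-indexed
free-energy corrections g_i(T), so that G_i(T) = E_i + g_i(T). Equilibrium
populations are Boltzmann fractions

    p_i(T) = 100 · exp(−G_i/(k_B T)) / Σ_j exp(−G_j/(k_B T))   [percent]

with k_B = 1.98720425864083·10⁻³ kcal mol⁻¹ K⁻¹ (CODATA-derived; the value is
a fixed constant of the package). The exponent is stabilised by subtracting
min G before exponentiation; populations are kept at full precision
internally and only the display layer renders values below 1% as an em dash.
Corrections at unlisted temperatures are linearly interpolated between the
listed ones and held constant outside that range; a conformer with no
corrections at all falls back to g = 0 with a logged warning. Degenerate
free energies are kept as distinct conformers; no symmetry-number weighting
is applied.

Jet cooling is modelled as instantaneous relaxation restricted to low-barrier
pathways. Conversion barriers are classified *low* (ΔG‡ ≤ 2 kcal/mol),
*medium* (2–8) or *high* (≥ 8); both boundary comparisons are inclusive and
both thresholds are configurable. Medium and high barriers carry zero flux —
no partial-conversion rate model is attempted. The low-barrier pairs form an
undirected conversion graph whose connected components are the kinetic
basins; each basin's population at the effective pre-expansion temperature
T_eff (default 450 K, with a ±50 K uncertainty band worth checking by sweep)
is summed and assigned to the basin's sink, the member with the lowest free
energy at the post-expansion reference temperature T_ref (default 10 K; ties
broken by lower electronic energy, then lexicographic id). A sink is
predicted observable when its pooled population exceeds the 8% threshold
(strict comparison).

When explicit barriers are unavailable, the class is predicted from the
four-part structural types: conversions that change the fold class
(folded ↔ extended) or connect differently folded backbones are high;
conversions between conformers of the same side-chain type (swing and
orientation) are low — extended backbones (β, ε, α) interconvert freely and
a terminus change (A1/A2/B) alone is also low; anything else (a side-chain
swing or hydroxyl-orientation change within one fold class) is medium. The
spec for this heuristic leaves the case "both folded, same backbone,
different side-chain type" open; it is classified medium here, consistent
with treating side-chain rearrangement as the medium-barrier motion. Explicit
barrier values always override the heuristic, because π-bonded side chains
are known to lower some inter-family barriers below the heuristic's estimate.

## Structural typing

Typing operates on raw Cartesian geometries of uncapped dipeptides
(H₂N–CHR–CO–NH–CHR′–COOH). Atom roles (amino N₁, peptide-bond N_PB and
carbonyl O_C_PB, C-terminal hydroxyl O_T and carbonyl O_C_T, side-chain
hydroxyl O_S, indole N) are inferred from a covalent bond graph (bond if the
interatomic distance is below the sum of covalent radii plus 0.45 Å).

Hydrogen bonds are geometric: a hydrogen covalently bonded (≤ 1.2 Å) to N or
O counts as a donor; acceptors are all oxygens, nitrogens with an available
lone pair (amide and pyrrole-type nitrogens are excluded — their lone pairs
are delocalised), and aromatic-ring centroids (π acceptors; the centroid of
the heavy-atom ring, nearest ring wins). A contact is a hydrogen bond when
the H···acceptor distance is ≤ 2.8 Å (inclusive; the distance is measured to
the hydrogen, not the donor heavy atom) and the acceptor is at least four
covalent bonds away from the hydrogen. π contacts from a donor attached to
(or inside) the ring itself are excluded.

The four label parts:

* **Terminus** — B when the amino N–H donates to the peptide carbonyl
  (N₁H···OC_PB) and the reverse N_PB_H···N₁ bond is absent; otherwise the A
  family, split A1/A2 by the sign of the amino-swing dihedral
  (C_PB–Cα1–N₁–H, positive → A1). The published account defines A1/A2 only
  through example figures, so the sign convention here is an internal
  calibration of this package; it is self-consistent across the builder, the
  typing code and the tests. Geometries with neither diagnostic bond are
  labelled "U" (untyped) and excluded from barrier prediction.
* **Backbone** — nearest centre on the (φ₂, ψ₂) torus among fixed class
  centres γ_L(−84, 68), γ_D(84, −68), β(−180, 180), ε_L(−75, 160),
  ε_D(75, −160), α_L(60, 45) (conformer-letter convention after Császár and
  Perczel; the centres are constants of this package since the source prints
  none). γ classes are folded (F), the rest extended (E). ψ₂ of the
  C-terminal residue is measured to the hydroxyl oxygen O_T.
* **Swing** — χ₁ (N–Cα–Cβ–Cγ) classified to the nearest of +180° (g+),
  +60° (g−), −60° (a) on the circle, ties toward g+. This is the source
  table's literal mapping; note it conflicts with common gauche nomenclature
  (see Limitations).
* **Orientation** — the sign of a residue-specific dihedral: the phenol
  C–C_ζ–O–H torsion for tyrosine, χ₂ for tryptophan (zero maps to +).

## Spectra

Harmonic line lists are corrected with a single multiplicative scaling factor
(shipped defaults 0.9602 for B3LYP/6-31G** and 0.943 for M062X/6-31G**).
Calibration uses the ratio of means, factor = mean(ν_exp)/mean(ν_raw), so the
scaled mean reproduces the experimental mean exactly; least squares is
deliberately not used. Stick spectra are broadened with Lorentzians
L(ν) = I·(Γ/2)²/((ν−ν₀)² + (Γ/2)²), Γ = FWHM = 20 cm⁻¹ by default, so the
peak height equals the line intensity. Assignments are scored by absolute
deviations per matched pair: matching is by shared mode label when both
sides are fully labelled (unmatched labels are an error), otherwise by an
order-preserving minimal-total-deviation alignment of the frequency-sorted
lists. Report values are rounded half-up to integer cm⁻¹, matching the
field's printed precision; raw floats are retained.

## Synthetic data

`generate_ensemble` emulates the structure of the reference ensembles: a few
folded low-energy conformers (drawn in the lower half of the energy range,
pairwise distinct in backbone/side-chain so they stay kinetically isolated)
and extended side-chain families (default layout 4/3/6/7 members for
g+/+, g+/−, g−/+, g−/−, mirroring the reference system's family sizes).
Extended conformers receive a free-energy correction −b·T/450 with
b = 1.2 kcal/mol by default, which reproduces the qualitative inversion of
real ensembles: folded-dominated near 100 K, extended-dominated at room
temperature and above. Barriers are drawn uniformly from class-consistent
intervals (intra-family low [0, 2], inter-family medium (2, 8), anything
involving a folded conformer high [8, 15]). The ground-truth partition,
sinks and pooled 450 K populations are computed by construction (direct
Boltzmann summation local to the generator) and emitted alongside, so
end-to-end recovery is exact, not statistical. All draws come from one
seeded generator; identical seeds give identical ensembles.

What the generator does *not* emulate: realistic potential-energy surfaces,
correlated energies/barriers, temperature-dependent barrier heights, and
borderline barrier values straddling the class boundaries. Passing the
recovery tests therefore demonstrates correctness of the pooling machinery,
not of the barrier heuristic on real molecules.

The toy geometry builder places atoms by the natural-extension-reference-frame
construction with ideal bond lengths and angles; every named torsion is
realised exactly (well below 1e-3°). Non-bonded contacts closer than 0.7 Å
warn rather than fail, since trial-structure enumeration legitimately visits
clashed combinations.

The 37-row Tyr-Gly reference table is packaged verbatim as CSV (sub-1%
entries stored as missing), with its SHA-256 pinned. Its printed
distributions cannot be regenerated from the printed electronic energies
(the free-energy corrections were never published), so they are data, not a
recomputation target. The published side-chain family memberships and each
family's low-temperature sink are packaged alongside;
`table1_low_t_free_energies()` provides a *synthetic, ordinal* stand-in for
the unpublished 10 K free energies (sink lowest, other members ranked by
electronic energy) so that sink selection is well defined — its magnitudes
carry no physical meaning.

## Numerical and design notes

* Populations sum to 100 within 1e-9 at every temperature; pooling conserves
  mass to the same tolerance.
* The energy-table reader enforces exactly one zero-reference record (the
  global minimum) unless the check is disabled; hartree input is converted
  with 627.5094740631 kcal/mol per hartree and re-referenced.
* Basin reports are JSON with sorted keys: byte-identical for identical
  input.
* The "conformer of interest" filter keeps the union of the ten lowest
  electronic-energy conformers and everything exceeding 1% equilibrium
  concentration at any temperature of a 10–450 K grid (10 K steps by
  default).
* Pooling the packaged reference table over the published family memberships
  gives 14.01/10.75/14.16/16.94% on sinks yg14/yg17/yg31/yg32. The published
  value for the yg31 family is 18%, which its *printed* member list cannot
  reach; the printed list, however, omits yg26 (A2-ε_D(E)-g−/+, 3.72%),
  whose structural type places it in that family — adding it gives 17.88%,
  matching the printed 18%. The type-predicted conversion graph
  (`yg_reference_basins(use_types=True)`) includes yg26 automatically; the
  package nowhere hard-codes 18%.

## Limitations

* The swing-label convention is taken literally from the source (g+ ≈ +180°).
  Under this mapping an N₁–H···π contact to the same residue's ring centroid
  is geometrically impossible at rigid ideal valence geometry (the ring
  centroid lies along the Cβ→Cγ direction, ~5.5 Å from N₁ when χ₁ is anti),
  yet the source pairs "g+" with N₁H···π for several folded and extended
  rows. The toy fixtures therefore demonstrate the γ-turn hydrogen bonds on
  an anti-χ₁ conformer and the π contact on a gauche-χ₁ conformer (the
  pairing the table itself shows for rows like yg26). Real relaxed
  geometries, or a swing convention with g± ≈ ±60°, would reconcile the two.
* Barrier-class prediction is a heuristic; systems with N_PB–H···π bonding
  are known to undercut the medium-barrier estimate, which is why measured
  barriers always take precedence.
* No master-equation or RRKM cooling dynamics: pooling is all-or-nothing per
  barrier class.
* Quantum-chemistry outputs (optimisations, frequencies, transition states)
  are consumed as tables; no log-file parsing is provided.
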