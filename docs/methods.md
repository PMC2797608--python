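# Methods

This note records the models implemented by hkmtkit, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic fixtures do and do not demonstrate.

## Coordinate model and PDB handling

Structures are parsed with gemmi into a plain
`Structure → Chain → Residue → Atom` hierarchy. Author residue
numbering is authoritative throughout — the literature on these
enzymes cites author numbering (GLP Y1124, G9a Y1067, ...) and no
renumbering is ever performed. Insertion codes and negative residue
numbers are accepted; models beyond the first are ignored unless
requested; mmCIF is read through the same entry point, with
fixed-column PDB as the reference dialect.

Alternate locations: analysis operations see one conformer per atom,
the highest-occupancy one (ties resolved toward altloc 'A' — the
deposition convention for the dominant conformer). Deposition
statistics, however, count every ATOM record, so `count_atoms`
exposes an `as-deposited` mode that requires the file to have been
read with `keep_altlocs=True`; mixing the two modes is an error
rather than a silent discrepancy. Category definitions: protein =
the 20 standard amino acids plus MSE (selenomethionine is deposited
as HETATM but is polymer); water = HOH/WAT/H2O/DOD; cofactor
defaults to {SAH, SAM, ZN} — SET-domain HKMTs carry structural zinc
in the Pre-/Post-SET regions, and deposition "cofactor" tallies for
these entries are consistent with the zincs being counted alongside
the adenosyl cofactor. The set is a parameter.

Hydrogens: crystal structures of these enzymes (1.5–2.0 Å) contain
none, so every geometric criterion in the package is heavy-atom
based by construction.

## Iterative weighted superposition

`kabsch_fit` is the closed-form weighted least-squares rigid
superposition via SVD with reflection correction, raising on fewer
than 3 effective points, non-positive total weight, or a collinear/
coincident effective point set (rotation underdetermined).

The iterative loop finds the best "alignable" main-chain core of two
structures:

1. start from the most reliable seed alignment of 15 residues;
2. set weights to 1 (on the seed);
3. perform the weighted superposition and evaluate the RMSD;
4. compute the deviation Dᵢ for each backbone (CA) atom pair;
5. locate D₅₀, the 50th percentile of the deviation array;
6. recompute weights from (Dᵢ, D₅₀);
7. return to step 3 unless 10 iterations have run.

Choices the protocol leaves open, and what this package does:

- **Weight formula.** The protocol text gives
  *Wᵢ = exp(−D₅₀²/Dᵢ²)*, which **increases** with deviation and
  up-weights outliers — the opposite of a core-finding weight and
  almost certainly a transcription inversion of
  *Wᵢ = exp(−Dᵢ²/D₅₀²)*. Both are implemented: `printed` executes the
  text verbatim (with Wᵢ = 0 at Dᵢ = 0 as the continuous limit);
  `inverted` (Wᵢ = 1 at Dᵢ = 0) is the default for every analysis.
  The parameter-recovery results below are meaningful only in
  inverted mode.
- **Pairing.** The protocol does not state how backbone pairs are
  chosen between non-identical proteins. Here residues are paired by
  a global sequence alignment (BLOSUM62, gap open 11 / extend 1, via
  Biopython's PairwiseAligner) and realized as CA-atom pairs.
- **Seed start.** "Most reliable" is undefined in the protocol.
  Candidate windows are contiguous runs of aligned residue pairs with
  complete N/CA/C backbones, ranked by rigid-fit RMSD (quantized at
  1e-6 Å so floating-point dust cannot override the deterministic
  positional tie-break). The first weighted fit uses unit weights on
  the seed window only, so the iteration grows the core outward from
  the anchor; starting instead from an all-ones global fit lets the
  loop split the difference between core and a mobile domain and,
  on roughly a quarter of the two-domain fixtures, converge onto the
  smaller rigid piece.
- **Core selection across seeds.** `superpose` runs the loop from the
  five best seeds and keeps the result whose converged transform
  fits the most pairs within an absolute 1 Å deviation (ties → lower
  weighted RMSD). The absolute threshold matters: total converged
  weight is a poor arbiter because when the loop converges onto a
  minority rigid segment, D₅₀ sits at the majority's deviation and
  the majority retains weight e⁻¹.
- **Percentile.** D₅₀ is the lower median of the sorted deviations
  (deterministic for even counts).
- **Convergence.** Early stop when max |ΔWᵢ| < 1e-4 between
  iterations or when D₅₀ < 1e-12 (perfect core); otherwise the
  printed 10-iteration cap.

`rmsd_between_selections` evaluates a selection-to-selection RMSD
under the transform fitted on the full domains — it never refits on
the selections — pairing atoms residue-by-residue by atom name. For
gatekeeper-residue comparisons (e.g. the Phe pair guarding the
lysine channel in GLP/G9a) the side-chain-only value is the reported
one; whether published per-residue RMSDs used side-chain or all
atoms is unstated, so both can be computed.

Measured on the synthetic study conditions (100 seeded two-domain
fixtures: 40-residue core under a random rigid transform + 0.1 Å
isotropic noise, 17 residues hinged 5 Å): median core-rotation
recovery error ≈ 0.3°, and the hinge's mean weight falls below the
core's in 100/100 runs (`scripts/acceptance.py` recomputes both).

## Interaction criteria

No hydrogen-bond criteria are given in the source protocol; the
package defaults are the common heavy-atom convention: donor–acceptor
(N/O) distance ≤ 3.5 Å and antecedent–donor–acceptor angle ≥ 120°,
where the antecedent is the donor's nearest heavy neighbor in the
same residue. Donor/acceptor capacity comes from per-residue
templates (guanidinium NE/NH1/NH2 all donate; His neutral — no pKa
model; water excluded: only *direct* bonds are analyzed). Unknown
residues are treated conservatively (N/O both capable) with a
warning. Covalent neighbors (same chain, adjacent residues) are
excluded. Published interface counts ("four hydrogen bonds" at the
R-1 arginine, two K4–aspartate bonds) are validated at exactly these
defaults; both thresholds are config keys, and counts of this kind
can shift ±1 under different conventions.

The double-hydrogen-bond motif is a peptide residue whose backbone N
donates to an enzyme backbone O *and* whose backbone O accepts from
an enzyme backbone N, with the two enzyme residues at most 2 apart
in the same chain (a β-bridge). Peptide-chain auto-detection picks
the shortest protein chain under 25 residues, overridable.

Contacts are all cross-selection atom pairs within 4.0 Å, summarized
per unique residue. Salt bridges pair Arg/Lys nitrogens against
Asp/Glu carboxylate oxygens within 3.5 Å, grouped per residue pair.

## Specificity rule

`predicted_max_state = clamp(3 − |restraining tyrosines|, 0, 3)`,
where a restraining tyrosine has its OH oxygen within 3.5 Å
(`hb_cut`) of the methyl-accepting ε-nitrogen. This operationalizes
"hydroxyl hydrogen-bonds to the methyl-accepting nitrogen" without
hydrogens. The channel lining radius is 6.0 Å around the ε-N — no
radius is published; 6 Å keeps the known channel residues (the
gatekeeper Tyr/Phe pair and the catalytic Post-SET tyrosine) inside
for the deposited complexes. Both are config keys.

Tyr→Phe switches delete the hydroxyl; Phe→Tyr places one at the
idealized para position CZ + 1.38 Å along the CG→CZ axis — no
rotamer search, a documented limitation (a real mutant hydroxyl may
relax away from the ideal axis). Switches have toggle semantics, so
switching a residue back restores the original profile exactly. The
rule predicts the maximal achievable product state only; kinetics
are out of scope. When the channel cannot be located (e.g. a
disordered Post-SET, as in PRDM2), the profiler reports
`indeterminate` rather than a state.

## Electrostatics

The reference analyses used a boundary-element Poisson solver inside
a commercial package whose charge set and surface definition are
unpublished. hkmtkit deliberately replaces it with a desk-scale
screened-Coulomb model: formal charges (Arg +1 at the guanidinium
center, Lys +1 at NZ, Asp/Glu −1 at the carboxylate midpoint,
termini +1/−1, His 0) and

    φ(p) = Σᵢ 332.0637 · qᵢ · exp(−κ rᵢ) / (ε rᵢ)   kcal/(mol·e)

with effective dielectric ε = 80 and κ = 0 by default (both
configurable; κ = 0 reduces to bare Coulomb, doubling ε halves φ).
Only sign-level claims — the peptide-binding groove being
electronegative, histone tails electropositive — are meaningful
under this approximation; absolute potential values are never
compared. Display values are clamped at ±5 kcal/(mol·e), the
saturation used for surface coloring.

The surface is a Shrake–Rupley-style dot surface: each atom sphere
at vdW radius + 1.4 Å probe is sampled on a deterministic golden-
spiral lattice at 1.0 dot/Å², keeping dots outside all other
expanded spheres. Points within 0.1 Å of a charge site are skipped
with a warning. The groove score averages the clamped potential over
surface points within 5 Å of the bound peptide (for apo enzymes, a
peptide transferred from a superposed reference complex); the
SUV39H2 groove is scored after removing residues 264–267, which
partially occupy the binding site in that crystal form. The
histone-tail positive-potential counterpart can be shown on an
extended-conformation synthetic peptide, as no isolated tail
structure is deposited.

## Synthetic fixtures: what they emulate and what they do not

Every generator is a pure function of (parameters, seed) —
bit-identical on repetition. Helices are ideal poly-Ala backbones
(φ = −57°, ψ = −47°, standard bond geometry, rise ≈ 1.5 Å/residue).
Two-domain pairs plant a known rotation (uniform axis, 10–170°),
translation, isotropic Gaussian noise (default σ = 0.1 Å,
crystallographic coordinate-error scale), and a 5 Å hinge on 30% of
residues; random 20-letter sequences make the pairing alignment
unambiguous. The β-bridge plants both backbone bonds at ~2.8 Å with
antecedent angles ≈ 125°, with flanking residues pleated away so the
ladder does not propagate; the flipped variant rotates the peptide
180° about its own axis, which preserves composition but breaks the
motif. Channel fixtures place exactly n ∈ {0,1,2} Tyr OH groups at
3.0 Å of the target (others parked at 5.5 Å: lining but not
restraining) around idealized rings.

Because fixtures are built *to* the geometric definitions, passing
tests demonstrate correctness of the implementations and the
internal consistency of the rules — not that real deposited
structures satisfy them. The deposited-entry tests exist for the
latter and require local copies of the entries (`data/pdb/`); the
package performs no network access. PDB's 3-decimal coordinate
precision caps round-trip fidelity, so geometric assertions on
re-read fixtures use a 2×10⁻³ Å tolerance.

## Numerical conventions

- Rotations are validated to det = +1 and orthogonality residual
  < 1e-9 on every fit.
- Rotation-angle differences use atan2(‖axis‖/2, (tr−1)/2), accurate
  near 0°.
- Coulomb constant fixed at 332.0637 kcal·Å/(mol·e²).
- Potential evaluation is chunked to bound the distance-matrix
  footprint on large surfaces.
- Problem sizes in tests and the acceptance script (40+17-residue
  fixtures, 100 recovery runs, ≤10-point brute-force systems,
  0.5–1.0 dots/Å²) were chosen so the full analysis re-runs in
  minutes on a single core while keeping every statistic
  well-resolved.

## Known limitations

- The screened-Coulomb model ignores desolvation, dielectric
  boundaries and counter-ion structure; use it for sign/contrast
  statements only.
- No pKa model: His is neutral, Asp/Glu/Arg/Lys always ionized.
- Phe→Tyr switches use ideal ring geometry without repacking.
- The seed search operates on windows of the global sequence
  alignment; structurally equivalent but non-homologous segments
  (alignment-divergent cores) are not searched.
- No flexible multi-domain alignment: one rigid transform per
  superposition, with mobility expressed only through the weights.
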