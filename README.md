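# hkmtkit

Structural analysis toolkit for SET-domain histone lysine
methyltransferases (HKMTs) — the enzymes (GLP/EHMT1, G9a/EHMT2,
SUV39H2, PRDM2, ...) that deposit mono-, di- or tri-methyl marks on
histone H3 lysine 9. The package re-implements, as tested reusable
code, the computational analyses used to characterize these enzymes
from crystal structures:

- **Iterative weighted superposition.** A weighted Kabsch (SVD) core
  inside the core-finding loop used to compare HKMT structures: start
  from the most reliable 15-residue seed alignment, fit, measure the
  per-pair backbone deviation *Dᵢ*, take its 50th percentile *D₅₀*,
  reweight with *Wᵢ = exp(−Dᵢ²/D₅₀²)*, and repeat up to 10 iterations.
  The formula as printed in the source protocol, *Wᵢ = exp(−D₅₀²/Dᵢ²)*,
  *up-weights* outliers; both variants are implemented (`printed` and
  `inverted`, the latter the analysis default) — see
  `docs/methods.md`.
- **Interface geometry.** Heavy-atom hydrogen-bond detection
  (donor–acceptor ≤ 3.5 Å, antecedent angle ≥ 120°), 4 Å contact
  shells, salt bridges, and the conserved "double hydrogen-bond" motif
  that anchors the substrate lysine backbone to the first I-SET
  β-strand — present in every HKMT ternary complex, always and only at
  the substrate lysine.
- **Methylation-state specificity.** The tyrosine-count rule: the
  maximal product state is `3 − (number of Tyr hydroxyls hydrogen-
  bonding the methyl-accepting ε-nitrogen)`. In-silico Tyr↔Phe switches
  reproduce the classic product-state mutants (a Tyr→Phe switch lets a
  di-methylase tri-methylate; Phe→Tyr confines it to mono).
- **Groove electrostatics.** Formal charges at side-chain group
  centers, a Shrake–Rupley-style dot surface, and a screened-Coulomb
  potential *φ(p) = Σᵢ 332.0637 qᵢ e^(−κrᵢ)/(ε rᵢ)* kcal/(mol·e),
  clamped at ±5 for display, scoring the electronegativity of the
  peptide-binding groove that attracts the basic histone tail.
- **Synthetic fixtures.** Deterministic generators for ideal helices,
  rigid/two-domain pairs with planted transforms, exact hydrogen-bond
  geometries, antiparallel β-bridges (normal and 180°-flipped),
  aromatic-cage channels with 0/1/2 restraining tyrosines, and charge
  clouds with closed-form potential oracles.

## Worked example

```python
from hkmtkit import synthetic_data as synth, superposition as sup
from hkmtkit import interactions as ia, specificity as sp
import numpy as np

# a two-domain pair: 40-residue core moved by a known rigid transform
# (plus 0.1 A noise), 17 trailing residues displaced 5 A as a hinge
a, b, truth = synth.make_two_domain_pair(core_len=40, mobile_len=17,
                                         noise_sigma=0.1, seed=7)
result = sup.superpose(a, b, weight_mode="inverted")

bridge = synth.make_beta_bridge()
motifs = ia.find_double_hbond_motifs(bridge.chain("P"), bridge)

structure, target = synth.make_channel_fixture(1)
profile = sp.profile_channel(structure, target)
switch = sp.ResidueSwitch(profile.restraining_tyrosines[0], "TYR", "PHE")
switched = sp.apply_switch(profile, [switch])
```

prints (via the corresponding report fields):

```
iterations run        : 10
weighted RMSD         : 0.134 A
unweighted RMSD       : 2.768 A
rotation error        : 0.429 deg
mean weight core/hinge: 0.564 / 1.28e-262
double-H-bond motif at: ['P/LYS9']
restraining tyrosines : ['E/TYR100']
predicted max state   : 2 (di)
after Tyr->Phe switch : 3 (tri)
```

Reading: the iterative loop locked onto the 40-residue core (weighted
RMSD 0.13 Å at the planted 0.1 Å noise) while assigning the hinged
residues essentially zero weight; the unweighted RMSD (2.77 Å) shows
what a naive global fit would report. The planted β-bridge shows the
double hydrogen-bond motif exactly at the substrate lysine, and the
one-restraining-tyrosine channel predicts a di-methylase that becomes
a tri-methylase when that tyrosine is switched to phenylalanine.

The same analyses are available from the shell:

```sh
hkmtkit make-fixture --kind two_domain --seed 7 --out a.pdb --out b.pdb --out truth.json
hkmtkit superpose a.pdb b.pdb --weight-mode inverted --out transform.json
hkmtkit hbonds complex.pdb --sel-a "chain P" --sel-b "chain I"
hkmtkit channel complex.pdb --target-chain P --target-resnum 9 --switch 100:TYR>PHE
hkmtkit reproduce --input 3hna.pdb --out-dir report/
```

## Layout

```
src/hkmtkit/
  structure_io.py    PDB/mmCIF parsing, selection, counting, writing
  superposition.py   weighted Kabsch, seed search, iterative loop
  interactions.py    hydrogen bonds, contacts, motifs, salt bridges
  specificity.py     channel profiling, Tyr/Phe switches
  electrostatics.py  charges, dot surface, screened-Coulomb potential
  synthetic_data.py  deterministic fixtures with ground truth
  cli.py             `hkmtkit` console script
docs/methods.md      models, parameters, numerical choices, limitations
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
```
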