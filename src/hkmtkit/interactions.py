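"""Geometric interaction detection: hydrogen bonds, contact shells,
salt bridges, and the substrate-lysine double hydrogen-bond motif.

Deposited X-ray models at these resolutions carry no hydrogens, so all
criteria are heavy-atom based: a hydrogen bond is a donor/acceptor N or
O pair within ``max_da`` (default 3.5 A) whose antecedent-donor-acceptor
angle is at least ``min_angle`` (default 120 degrees). Donor and
acceptor capacity comes from per-residue templates; water is excluded
from bonding partners unless explicitly selected (the analyses concern
direct bonds only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import defaults
from .structure_io import Atom, Chain, Residue, Structure

__all__ = [
    "HydrogenBond", "Contact", "ContactShell", "DoubleHBondMotif", "PolarContact",
    "detect_hbonds", "contact_shell", "find_double_hbond_motifs", "polar_pairs",
    "find_peptide_chain",
]

# heavy-atom donors per residue (beyond the backbone amide N)
SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "SER": {"OG"}, "THR": {"OG1"},
    "TYR": {"OH"}, "TRP": {"NE1"},
}
# heavy-atom acceptors per residue (beyond the backbone carbonyl O/OXT)
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

POSITIVE_GROUPS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}}
NEGATIVE_GROUPS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}

_KNOWN_TEMPLATES = set(SIDECHAIN_DONORS) | set(SIDECHAIN_ACCEPTORS) | {
    "ALA", "CYS", "GLY", "ILE", "LEU", "MET", "PHE", "PRO", "VAL", "MSE",
}


def _is_donor(atom: Atom) -> bool:
    res = atom.residue
    if res is None:
        return False
    if res.is_water:
        return False
    name = res.name
    if name in _KNOWN_TEMPLATES:
        if atom.name == "N" and name != "PRO":
            return True
        return atom.name in SIDECHAIN_DONORS.get(name, ())
    # unknown residue template: treat N and O conservatively as capable
    warnings.warn(f"no donor template for residue {name}; treating N/O conservatively",
                  stacklevel=3)
    return atom.element in {"N", "O"}


def _is_acceptor(atom: Atom) -> bool:
    res = atom.residue
    if res is None:
        return False
    if res.is_water:
        return False
    name = res.name
    if name in _KNOWN_TEMPLATES:
        if atom.name in {"O", "OXT"}:
            return True
        return atom.name in SIDECHAIN_ACCEPTORS.get(name, ())
    return atom.element in {"N", "O"}


def _antecedent(atom: Atom) -> Atom | None:
    """Nearest covalently-plausible heavy neighbor in the same residue."""
    res = atom.residue
    if res is None:
        return None
    best, best_d = None, np.inf
    for other in res.atoms:
        if other is atom or other.element == "H":
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    if best is None or best_d > 2.0:
        return None
    return best


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def _atom_key(atom: Atom) -> tuple:
    res = atom.residue
    return (res.chain_id, res.seq_number, res.insertion_code, res.name, atom.name)


def _bonded_neighbors(donor: Atom, acceptor: Atom) -> bool:
    """Exclude pairs that are covalent neighbors along a chain."""
    rd, ra = donor.residue, acceptor.residue
    if rd is ra:
        return True
    if rd.chain_id == ra.chain_id and abs(rd.seq_number - ra.seq_number) <= 1 \
            and rd.insertion_code == ra.insertion_code:
        return True
    return False


@dataclass
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    distance: float
    angle: float

    @property
    def bond_class(self) -> str:
        parts = []
        for atom in (self.donor, self.acceptor):
            parts.append("backbone" if atom.is_backbone else "sidechain")
        return "-".join(parts)

    @property
    def pair_key(self) -> frozenset:
        return frozenset((_atom_key(self.donor), _atom_key(self.acceptor)))

    def __repr__(self) -> str:  # compact, readable in test output
        return (f"HBond({self.donor.residue.label}.{self.donor.name} -> "
                f"{self.acceptor.residue.label}.{self.acceptor.name}, "
                f"{self.distance:.2f} A, {self.angle:.0f} deg)")


def detect_hbonds(sel_a: list[Atom], sel_b: list[Atom],
                  max_da: float = defaults.HB_MAX_DA,
                  min_angle: float = defaults.HB_MIN_ANGLE) -> list[HydrogenBond]:
    """All donor-acceptor pairs across two selections meeting the criteria.

    Both donor->acceptor directions are scanned; the returned list is
    deduplicated on the unordered atom pair and sorted by distance.
    """
    if not sel_a or not sel_b:
        raise ValueError("empty selection")
    bonds: dict[frozenset, HydrogenBond] = {}
    for donors_from, acceptors_from in ((sel_a, sel_b), (sel_b, sel_a)):
        donors = [a for a in donors_from if _is_donor(a)]
        acceptors = [a for a in acceptors_from if _is_acceptor(a)]
        if not donors or not acceptors:
            continue
        tree = cKDTree(np.stack([a.coords for a in acceptors]))
        for donor in donors:
            ante = _antecedent(donor)
            if ante is None:
                warnings.warn(f"donor {_atom_key(donor)} has no antecedent atom; skipped",
                              stacklevel=2)
                continue
            for j in tree.query_ball_point(donor.coords, max_da):
                acceptor = acceptors[j]
                if donor is acceptor or _bonded_neighbors(donor, acceptor):
                    continue
                dist = float(np.linalg.norm(donor.coords - acceptor.coords))
                angle = _angle_deg(ante.coords, donor.coords, acceptor.coords)
                if angle < min_angle:
                    continue
                hb = HydrogenBond(donor=donor, acceptor=acceptor, distance=dist, angle=angle)
                prev = bonds.get(hb.pair_key)
                if prev is None or dist < prev.distance:
                    bonds[hb.pair_key] = hb
    return sorted(bonds.values(), key=lambda h: (h.distance, _atom_key(h.donor)))


@dataclass
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float


@dataclass
class ContactShell:
    contacts: list[Contact]
    residues_a: list[Residue]
    residues_b: list[Residue]

    def __len__(self) -> int:
        return len(self.contacts)


def contact_shell(sel_a: list[Atom], sel_b: list[Atom],
                  cutoff: float = defaults.CONTACT_CUTOFF) -> ContactShell:
    """Every atom pair across disjoint selections within ``cutoff``.

    The residue-level summary lists the unique residues of each side
    participating in at least one contact (file order preserved).
    """
    if not sel_a or not sel_b:
        raise ValueError("empty selection")
    ids_a = {id(a) for a in sel_a}
    if any(id(b) in ids_a for b in sel_b):
        raise ValueError("selections must be disjoint")
    tree_b = cKDTree(np.stack([a.coords for a in sel_b]))
    contacts = []
    for atom_a in sel_a:
        for j in tree_b.query_ball_point(atom_a.coords, cutoff):
            atom_b = sel_b[j]
            contacts.append(Contact(atom_a, atom_b,
                                    float(np.linalg.norm(atom_a.coords - atom_b.coords))))
    contacts.sort(key=lambda c: c.distance)

    def _unique_residues(atoms):
        seen, out = set(), []
        for atom in atoms:
            key = atom.residue.key
            if key not in seen:
                seen.add(key)
                out.append(atom.residue)
        return out

    return ContactShell(
        contacts=contacts,
        residues_a=_unique_residues([c.atom_a for c in contacts]),
        residues_b=_unique_residues([c.atom_b for c in contacts]),
    )


@dataclass
class DoubleHBondMotif:
    """The conserved pair of backbone hydrogen bonds anchoring a peptide
    residue to a beta-strand: peptide N -> strand O and strand N -> peptide O."""
    peptide_residue: Residue
    strand_residues: list[Residue]
    bonds: tuple[HydrogenBond, HydrogenBond]


def find_peptide_chain(structure: Structure,
                       max_res: int = defaults.PEPTIDE_MAX_RES) -> Chain:
    """Shortest protein chain with fewer than ``max_res`` residues."""
    candidates = [c for c in structure.chains
                  if 0 < len(c.protein_residues()) < max_res]
    if not candidates:
        raise ValueError("no peptide chain (shortest protein chain under "
                         f"{max_res} residues) found")
    return min(candidates, key=lambda c: len(c.protein_residues()))


def find_double_hbond_motifs(peptide_chain: Chain, enzyme: Structure,
                             max_da: float = defaults.HB_MAX_DA,
                             min_angle: float = defaults.HB_MIN_ANGLE,
                             max_strand_span: int = 2) -> list[DoubleHBondMotif]:
    """Peptide residues whose backbone N and O both hydrogen-bond to the
    backbone of one enzyme strand segment.

    The two enzyme residues must come from the same chain within
    ``max_strand_span`` sequence positions of each other, as in a
    beta-bridge. At a peptide-in-groove interface this motif appears
    always and only at the substrate lysine.
    """
    peptide_atoms = [a for r in peptide_chain.residues for a in r.atoms]
    if not peptide_atoms:
        raise ValueError("peptide chain has no atoms")
    peptide_keys = {(r.chain_id, r.seq_number, r.insertion_code)
                    for r in peptide_chain.residues}
    enzyme_atoms = [a for r in enzyme.iter_residues()
                    if r.key not in peptide_keys and r.is_protein
                    for a in r.atoms]
    if not enzyme_atoms:
        raise ValueError("no enzyme atoms outside the peptide chain")
    bonds = detect_hbonds(peptide_atoms, enzyme_atoms, max_da=max_da, min_angle=min_angle)
    bb = [b for b in bonds if b.bond_class == "backbone-backbone"]
    motifs = []
    for res in peptide_chain.residues:
        n_bonds = [b for b in bb if b.donor.residue is res and b.donor.name == "N"]
        o_bonds = [b for b in bb if b.acceptor.residue is res and b.acceptor.name == "O"]
        best = None
        for bn in n_bonds:
            for bo in o_bonds:
                ra, rb = bn.acceptor.residue, bo.donor.residue
                if ra.chain_id != rb.chain_id:
                    continue
                if abs(ra.seq_number - rb.seq_number) > max_strand_span:
                    continue
                if best is None or bn.distance + bo.distance < best[0]:
                    best = (bn.distance + bo.distance, bn, bo, ra, rb)
        if best is not None:
            _, bn, bo, ra, rb = best
            strand = [ra] if ra is rb else [ra, rb]
            motifs.append(DoubleHBondMotif(peptide_residue=res,
                                           strand_residues=strand, bonds=(bn, bo)))
    return motifs


@dataclass
class PolarContact:
    """Opposite-charge residue pair with its qualifying atom pairs."""
    residue_pos: Residue
    residue_neg: Residue
    atom_pairs: list[tuple[Atom, Atom, float]]

    @property
    def min_distance(self) -> float:
        return min(d for _, _, d in self.atom_pairs)


def polar_pairs(sel_a: list[Atom], sel_b: list[Atom],
                cutoff: float = defaults.POLAR_CUTOFF) -> list[PolarContact]:
    """Salt-bridge/polar interactions between opposite formal charges.

    Arg/Lys are positive, Asp/Glu negative, His neutral (no pKa model).
    Results are grouped per residue pair and sorted by closest approach.
    """
    if not sel_a or not sel_b:
        warnings.warn("empty selection for polar_pairs", stacklevel=2)
        return []

    def classify(atoms):
        pos, neg = [], []
        for atom in atoms:
            res = atom.residue
            if res is None:
                continue
            if atom.name in POSITIVE_GROUPS.get(res.name, ()):
                pos.append(atom)
            elif atom.name in NEGATIVE_GROUPS.get(res.name, ()):
                neg.append(atom)
        return pos, neg

    pos_a, neg_a = classify(sel_a)
    pos_b, neg_b = classify(sel_b)
    groups: dict[tuple, PolarContact] = {}
    for plus, minus in ((pos_a, neg_b), (pos_b, neg_a)):
        for p in plus:
            for m in minus:
                d = float(np.linalg.norm(p.coords - m.coords))
                if d > cutoff:
                    continue
                key = (p.residue.key, m.residue.key)
                if key not in groups:
                    groups[key] = PolarContact(residue_pos=p.residue,
                                               residue_neg=m.residue, atom_pairs=[])
                groups[key].atom_pairs.append((p, m, d))
    return sorted(groups.values(), key=lambda g: g.min_distance)
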