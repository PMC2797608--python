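"""Coordinate data model and PDB input/output.

The hierarchy is ``Structure -> Chain -> Residue -> Atom`` with author
residue numbering kept authoritative (no renumbering). Reading is backed
by gemmi, which handles the fixed-column PDB dialect and mmCIF behind
the same entry point; writing emits wwPDB v3.3 fixed columns directly.

Alternate locations: by default only the highest-occupancy conformer of
each atom is kept (ties broken toward altloc 'A'); pass
``keep_altlocs=True`` to retain every deposited record, which is the
mode required for "as-deposited" atom counting against the deposition
statistics of an entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine, deposited as HETATM but part of the polymer
}
WATER_CODES = {"HOH", "WAT", "H2O", "DOD"}
COFACTOR_CODES = {"SAH", "SAM", "ZN"}

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

_TWO_LETTER_ELEMENTS = {"ZN", "FE", "MG", "SE", "CL", "BR", "NA", "MN", "CA", "CU", "NI", "CO"}


class PDBFormatError(ValueError):
    """Raised for malformed fixed-column coordinate records."""


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("unit cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("unit cell angles must be in (0, 180)")


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False
    residue: "Residue | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            self.element = infer_element(self.name, self.is_hetero)

    @property
    def is_backbone(self) -> bool:
        return not self.is_hetero and self.name in BACKBONE_NAMES


@dataclass
class Residue:
    name: str
    seq_number: int
    insertion_code: str = ""
    chain_id: str = "A"
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a in self.atoms:
            a.residue = self

    def add(self, atom: Atom) -> None:
        atom.residue = self
        self.atoms.append(atom)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_protein(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def is_water(self) -> bool:
        return self.name in WATER_CODES

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_number}{self.insertion_code}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.residues if r.is_protein)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_protein]


@dataclass
class Structure:
    id: str = ""
    chains: list[Chain] = field(default_factory=list)
    unit_cell: UnitCell | None = None
    model_number: int = 1
    altlocs_collapsed: bool = True

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self) -> Iterator[Atom]:
        for r in self.iter_residues():
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self, atoms: Sequence[Atom] | None = None) -> np.ndarray:
        pool = list(self.iter_atoms()) if atoms is None else list(atoms)
        if not pool:
            return np.empty((0, 3))
        return np.stack([a.coords for a in pool])


@dataclass
class PeptideNumbering:
    """Peptide residue numbering relative to the methyl-accepting lysine.

    The target lysine is position 0; the arginine immediately upstream of
    an H3K9 substrate is R-1 in this convention.
    """

    target: Residue
    offsets: dict[tuple[str, int, str], int]

    def __post_init__(self) -> None:
        if self.offsets.get(self.target.key) != 0:
            raise ValueError("target lysine offset must be 0")

    def offset(self, residue: Residue) -> int:
        return self.offsets[residue.key]


def peptide_numbering(chain: Chain, target_resnum: int) -> PeptideNumbering:
    """Number a peptide chain relative to the residue at ``target_resnum``."""
    target = None
    for r in chain.residues:
        if r.seq_number == target_resnum:
            target = r
            break
    if target is None:
        raise KeyError(f"no residue {target_resnum} in chain {chain.id}")
    offsets = {r.key: r.seq_number - target_resnum for r in chain.residues}
    return PeptideNumbering(target=target, offsets=offsets)


def infer_element(name: str, is_hetero: bool = False) -> str:
    """Infer the element symbol from a PDB atom name."""
    stripped = name.strip()
    if not stripped:
        raise ValueError("cannot infer element from empty atom name")
    head = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if len(head) >= 2 and head[:2] in _TWO_LETTER_ELEMENTS:
        # two-letter symbols only when the name is not a standard protein
        # atom like CA/CB (calcium vs alpha-carbon ambiguity)
        if is_hetero or head[:2] not in {"CA", "CB", "CD", "CE", "CG", "NA"}:
            return head[:2].capitalize()
    return head[0]


# ---------------------------------------------------------------------------
# reading

def _scan_for_malformed(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise PDBFormatError(f"{path}:{lineno}: coordinate record shorter than 54 columns")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise PDBFormatError(f"{path}:{lineno}: malformed coordinate fields") from exc


def read_pdb(path: str | Path, model: int | None = None, keep_altlocs: bool = False) -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    Parameters
    ----------
    path : file path
    model : model number to load; default the first MODEL in the file.
    keep_altlocs : retain every alternate-location record instead of
        collapsing to the highest-occupancy conformer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".pdb", ".ent"} or path.suffix == "":
        _scan_for_malformed(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError(f"{path}: no coordinate records")

    gm = None
    if model is None:
        gm = st[0]
    else:
        for m in st:
            if m.num == model:
                gm = m
                break
        if gm is None:
            raise ValueError(f"{path}: no MODEL {model}")
    structure = Structure(id=st.name or path.stem, model_number=gm.num,
                          altlocs_collapsed=not keep_altlocs)
    if st.cell and st.cell.a > 0 and st.cell.is_crystal():
        structure.unit_cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                                       st.cell.alpha, st.cell.beta, st.cell.gamma,
                                       st.spacegroup_hm or "")
    n_atoms = 0
    for gchain in gm:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            res = Residue(name=gres.name, seq_number=gres.seqid.num,
                          insertion_code=(gres.seqid.icode or "").strip(),
                          chain_id=gchain.name)
            atoms = list(gres)
            if not keep_altlocs:
                atoms = _collapse_altlocs(atoms)
            for ga in atoms:
                res.add(Atom(
                    serial=ga.serial,
                    name=ga.name,
                    element=ga.element.name if ga.element else "",
                    altloc=(ga.altloc or "").strip("\x00"),
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ,
                    bfactor=ga.b_iso,
                    is_hetero=(gres.het_flag == "H"),
                ))
                n_atoms += 1
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            structure.chains.append(chain)
    if n_atoms == 0:
        raise PDBFormatError(f"{path}: no coordinate records")
    return structure


def _collapse_altlocs(gatoms: list) -> list:
    """Keep one conformer per atom name: highest occupancy, ties -> lowest altloc."""
    best: dict[str, object] = {}
    order: list[str] = []
    for ga in gatoms:
        key = ga.name
        if key not in best:
            best[key] = ga
            order.append(key)
        else:
            cur = best[key]
            alt_cur = (cur.altloc or "\x7f")
            alt_new = (ga.altloc or "\x7f")
            if (ga.occ, -ord(alt_new[0])) > (cur.occ, -ord(alt_cur[0])):
                best[key] = ga
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# writing

def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure in wwPDB v3.3 fixed columns (ATOM/HETATM/TER/CRYST1)."""
    lines: list[str] = []
    uc = structure.unit_cell
    if uc is not None:
        lines.append(
            f"CRYST1{uc.a:9.3f}{uc.b:9.3f}{uc.c:9.3f}"
            f"{uc.alpha:7.2f}{uc.beta:7.2f}{uc.gamma:7.2f} {uc.space_group:<11s}{1:4d}"
        )
    serial = 0
    for chain in structure.chains:
        last_res = None
        for res in chain.residues:
            for atom in res.atoms:
                serial = atom.serial if atom.serial > 0 else serial + 1
                record = "HETATM" if atom.is_hetero else "ATOM  "
                x, y, z = atom.coords
                lines.append(
                    f"{record}{serial:5d} {_format_atom_name(atom.name, atom.element)}"
                    f"{atom.altloc or ' ':1s}{res.name:>3s} {chain.id:1s}"
                    f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                    f"          {atom.element.upper():>2s}"
                )
            last_res = res
        if last_res is not None and last_res.is_protein:
            lines.append(
                f"TER   {serial + 1:5d}      {last_res.name:>3s} {chain.id:1s}"
                f"{last_res.seq_number:4d}{last_res.insertion_code or ' ':1s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def atom_table(structure: Structure) -> pd.DataFrame:
    """Flat per-atom table (serial, chain, resname, resnum, icode, atomname, x, y, z, occ, b)."""
    rows = []
    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                rows.append({
                    "serial": a.serial, "chain": chain.id, "resname": res.name,
                    "resnum": res.seq_number, "icode": res.insertion_code,
                    "atomname": a.name, "x": a.coords[0], "y": a.coords[1],
                    "z": a.coords[2], "occ": a.occupancy, "b": a.bfactor,
                })
    return pd.DataFrame(rows)


def write_atom_table(structure: Structure, path: str | Path) -> None:
    atom_table(structure).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counting and selection

CATEGORIES = ("protein", "cofactor", "water", "other")


def _category(res: Residue) -> str:
    if res.name in STANDARD_AA:
        return "protein"
    if res.name in WATER_CODES:
        return "water"
    if res.name in COFACTOR_CODES:
        return "cofactor"
    return "other"


def count_atoms(structure: Structure, category: str, mode: str = "unique",
                cofactor_codes: set[str] | None = None) -> int:
    """Count atoms in a residue category (``protein``/``cofactor``/``water``/``other``).

    ``mode='as-deposited'`` counts every deposited record including
    alternate locations and therefore requires the structure to have been
    read with ``keep_altlocs=True``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}")
    if mode not in {"unique", "as-deposited"}:
        raise ValueError(f"unknown count mode {mode!r}")
    if mode == "as-deposited" and structure.altlocs_collapsed:
        raise ValueError("as-deposited counting requires read_pdb(..., keep_altlocs=True)")
    codes = COFACTOR_CODES if cofactor_codes is None else cofactor_codes
    n = 0
    for res in structure.iter_residues():
        if res.name in STANDARD_AA:
            cat = "protein"
        elif res.name in WATER_CODES:
            cat = "water"
        elif res.name in codes:
            cat = "cofactor"
        else:
            cat = "other"
        if cat == category:
            n += len(res.atoms)
    return n


def select(structure: Structure, query: str) -> list[Atom]:
    """Select atoms with a conjunction of clauses joined by ``and``.

    Clauses: ``chain <id>``, ``resnum <n>`` or ``resnum <n>-<m>``,
    ``resname <code>[,<code>...]``, ``name <atom>[,<atom>...]``,
    ``hetero``, ``protein``, ``water``. Example:
    ``"chain A and resnum 1209"``.
    """
    predicates = []
    for clause in [c.strip() for c in query.split(" and ")]:
        if not clause:
            raise ValueError("empty selection clause")
        parts = clause.split(None, 1)
        key = parts[0].lower()
        if key == "hetero" and len(parts) == 1:
            predicates.append(lambda res, atom: atom.is_hetero)
            continue
        if key == "protein" and len(parts) == 1:
            predicates.append(lambda res, atom: res.is_protein)
            continue
        if key == "water" and len(parts) == 1:
            predicates.append(lambda res, atom: res.is_water)
            continue
        if len(parts) != 2:
            raise ValueError(f"invalid selection clause {clause!r}")
        value = parts[1].strip()
        if key == "chain":
            ids = set(value.split(","))
            predicates.append(lambda res, atom, ids=ids: res.chain_id in ids)
        elif key == "resnum":
            if "-" in value[1:]:  # allow leading minus for negative numbers
                split_at = value.index("-", 1)
                lo, hi = int(value[:split_at]), int(value[split_at + 1:])
            else:
                lo = hi = int(value)
            predicates.append(lambda res, atom, lo=lo, hi=hi: lo <= res.seq_number <= hi)
        elif key == "resname":
            names = {v.strip().upper() for v in value.split(",")}
            predicates.append(lambda res, atom, names=names: res.name in names)
        elif key == "name":
            names = {v.strip().upper() for v in value.split(",")}
            predicates.append(lambda res, atom, names=names: atom.name.upper() in names)
        elif key == "icode":
            predicates.append(lambda res, atom, v=value: res.insertion_code == v)
        else:
            raise ValueError(f"unknown selection keyword {key!r}")
    out = []
    for res in structure.iter_residues():
        for atom in res.atoms:
            if all(p(res, atom) for p in predicates):
                out.append(atom)
    if not out:
        warnings.warn(f"selection {query!r} matched no atoms", stacklevel=2)
    return out
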