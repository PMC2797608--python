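"""Surface electrostatic potential with a screened-Coulomb model.

Formal charges are placed at named side-chain group centers (Arg +1 on
the guanidinium, Lys +1 on NZ, Asp/Glu -1 on the carboxylate midpoint,
chain termini +1/-1, His neutral) and the potential at molecular dot-
surface points is

    phi(p) = sum_i 332.0637 q_i exp(-kappa r_i) / (eps r_i)   kcal/(mol e)

with an effective dielectric (default 80) and optional Debye screening.
This is a deliberate desk-scale approximation of a boundary-element
Poisson treatment: only sign-level statements (e.g. that the peptide-
binding groove is electronegative) are meaningful, never absolute
values. For display, potentials are clamped to +/-5 kcal/(mol e).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from . import defaults
from .structure_io import Atom, Structure

__all__ = [
    "ChargeModel", "PotentialMap", "GrooveScore",
    "assign_charges", "dot_surface", "compute_potential", "groove_score",
    "clamp_potential", "surface_potential",
]


@dataclass
class ChargeModel:
    """Formal-charge model: residue name -> (charge, group atom names).

    The charge is placed at the mean position of the listed atoms that
    are present (Arg falls back from CZ to the NE/NH1/NH2 mean when the
    guanidinium carbon is unresolved)."""
    sidechains: dict = field(default_factory=lambda: {
        "ARG": (+1.0, (("CZ",), ("NE", "NH1", "NH2"))),
        "LYS": (+1.0, (("NZ",),)),
        "ASP": (-1.0, (("OD1", "OD2"),)),
        "GLU": (-1.0, (("OE1", "OE2"),)),
    })
    n_terminus: float = +1.0
    c_terminus: float = -1.0
    include_termini: bool = True


def _group_center(res, atom_groups) -> np.ndarray | None:
    for names in atom_groups:
        coords = [res.atom(n).coords for n in names if res.atom(n) is not None]
        if coords:
            return np.mean(coords, axis=0)
    return None


def assign_charges(structure: Structure,
                   model: ChargeModel | None = None) -> tuple[list[tuple[np.ndarray, float]], dict]:
    """Deterministic formal-charge list plus an assignment report.

    Returns ``(sites, report)`` where sites are (position, charge) pairs
    and the report records the net charge and any sites skipped because
    their group atoms are unresolved.
    """
    model = model or ChargeModel()
    sites: list[tuple[np.ndarray, float]] = []
    skipped: list[str] = []
    for res in structure.iter_residues():
        if not res.is_protein:
            continue
        entry = model.sidechains.get(res.name)
        if entry is None:
            continue
        q, groups = entry
        center = _group_center(res, groups)
        if center is None:
            skipped.append(res.label)
            warnings.warn(f"charge site atoms missing for {res.label}; skipped",
                          stacklevel=2)
            continue
        sites.append((center, q))
    if model.include_termini:
        for chain in structure.chains:
            prot = chain.protein_residues()
            if not prot:
                continue
            n_atom = prot[0].atom("N")
            if n_atom is not None:
                sites.append((n_atom.coords, model.n_terminus))
            else:
                skipped.append(prot[0].label + ":Nterm")
            last = prot[-1]
            oxt = last.atom("OXT")
            carboxy = oxt.coords if oxt is not None else (
                last.atom("O").coords if last.atom("O") is not None else None)
            if carboxy is not None:
                sites.append((carboxy, model.c_terminus))
            else:
                skipped.append(last.label + ":Cterm")
    report = {"n_sites": len(sites), "net_charge": sum(q for _, q in sites),
              "skipped": skipped}
    return sites, report


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    golden = math.pi * (3.0 - math.sqrt(5.0))
    theta = golden * i
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def dot_surface(structure: Structure, probe: float = defaults.PROBE_RADIUS,
                density: float = defaults.DOT_DENSITY,
                atoms: list[Atom] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Solvent-accessible dot surface (Shrake-Rupley style).

    Each atom sphere of radius vdW+probe is sampled quasi-uniformly at
    ``density`` dots per square Angstrom; a dot survives if it lies
    inside no other atom's expanded sphere. Returns ``(points,
    atom_indices)``.
    """
    pool = [a for a in (atoms if atoms is not None else structure.iter_atoms())
            if a.residue is None or not a.residue.is_water]
    if not pool:
        raise ValueError("empty structure: no atoms to build a surface from")
    centers = np.stack([a.coords for a in pool])
    radii = np.array([defaults.VDW_RADII.get(a.element.upper(), defaults.VDW_DEFAULT)
                      for a in pool]) + probe
    tree = cKDTree(centers)
    max_r = radii.max()
    points, owners = [], []
    for i, (center, radius) in enumerate(zip(centers, radii)):
        n_dots = max(1, int(round(density * 4.0 * math.pi * radius * radius)))
        dots = center + radius * _fibonacci_sphere(n_dots)
        neighbors = [j for j in tree.query_ball_point(center, radius + max_r) if j != i]
        keep = np.ones(len(dots), dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(dots - centers[j], axis=1)
            keep &= d >= radii[j] - 1e-9
        if keep.any():
            points.append(dots[keep])
            owners.append(np.full(int(keep.sum()), i))
    if not points:
        raise ValueError("no surface points survive; degenerate structure")
    return np.concatenate(points), np.concatenate(owners)


def clamp_potential(values: np.ndarray, limit: float = defaults.CLAMP) -> np.ndarray:
    """Saturate potentials at +/-limit for display (idempotent)."""
    return np.clip(values, -limit, limit)


@dataclass
class PotentialMap:
    points: np.ndarray
    potential: np.ndarray
    clamped: np.ndarray
    dielectric: float
    kappa: float
    clamp: float


def compute_potential(points: np.ndarray, charges: list[tuple[np.ndarray, float]],
                      dielectric: float = defaults.DIELECTRIC,
                      kappa: float = defaults.KAPPA,
                      clamp: float = defaults.CLAMP,
                      min_dist: float = defaults.MIN_CHARGE_DIST) -> PotentialMap:
    """Screened-Coulomb potential at each point, in kcal/(mol e).

    Point/charge pairs closer than ``min_dist`` are skipped with a
    warning (their bare-Coulomb contribution would be unphysical).
    """
    if not charges:
        raise ValueError("at least one charge required")
    if dielectric <= 0:
        raise ValueError("dielectric must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pos = np.stack([np.asarray(p, dtype=float) for p, _ in charges])
    q = np.array([c for _, c in charges])
    phi = np.empty(len(pts))
    n_skipped = 0
    block = max(1, 5_000_000 // max(1, len(q)))   # bound the distance matrix
    for start in range(0, len(pts), block):
        r = cdist(pts[start:start + block], pos)
        too_close = r < min_dist
        n_skipped += int(too_close.sum())
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = defaults.COULOMB_CONSTANT * q[None, :] * np.exp(-kappa * r) \
                / (dielectric * r)
        contrib[too_close] = 0.0
        phi[start:start + block] = contrib.sum(axis=1)
    if n_skipped:
        warnings.warn(f"{n_skipped} point/charge pairs closer than "
                      f"{min_dist} A skipped", stacklevel=2)
    return PotentialMap(points=pts, potential=phi,
                        clamped=clamp_potential(phi, clamp),
                        dielectric=dielectric, kappa=kappa, clamp=clamp)


@dataclass
class GrooveScore:
    patch_indices: np.ndarray
    mean_potential: float          # over clamped display values
    mean_potential_raw: float
    fraction_negative: float
    n_points: int


def groove_score(pmap: PotentialMap, peptide_sel: list[Atom],
                 patch_cut: float = defaults.PATCH_CUT) -> GrooveScore:
    """Electronegativity statistics of the groove patch near the peptide.

    The patch is every surface point within ``patch_cut`` of any peptide
    atom (for apo enzymes the peptide is transferred from a superposed
    reference complex). ``fraction_negative`` counts strictly negative
    potentials, so an all-zero patch scores 0.
    """
    if not peptide_sel:
        raise ValueError("empty peptide selection")
    pep = np.stack([a.coords for a in peptide_sel])
    tree = cKDTree(pmap.points)
    idx = sorted({j for hits in tree.query_ball_point(pep, patch_cut) for j in hits})
    if not idx:
        raise ValueError("empty groove patch: peptide too far from the surface")
    idx = np.array(idx)
    clamped = pmap.clamped[idx]
    return GrooveScore(patch_indices=idx,
                       mean_potential=float(np.mean(clamped)),
                       mean_potential_raw=float(np.mean(pmap.potential[idx])),
                       fraction_negative=float(np.mean(clamped < 0)),
                       n_points=int(idx.size))


def surface_potential(structure: Structure, probe: float = defaults.PROBE_RADIUS,
                      density: float = defaults.DOT_DENSITY,
                      dielectric: float = defaults.DIELECTRIC,
                      kappa: float = defaults.KAPPA,
                      clamp: float = defaults.CLAMP,
                      model: ChargeModel | None = None,
                      atoms: list[Atom] | None = None) -> PotentialMap:
    """Convenience: assign charges, build the dot surface, map potential."""
    charges, _ = assign_charges(structure, model)
    points, _ = dot_surface(structure, probe=probe, density=density, atoms=atoms)
    return compute_potential(points, charges, dielectric=dielectric,
                             kappa=kappa, clamp=clamp)
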