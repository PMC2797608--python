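"""Deterministic synthetic fixtures for every analysis stage.

Each generator is a pure function of its parameters and an integer seed:
identical inputs give bit-identical structures. The fixtures emulate the
geometric situations the analysis modules must handle — rigid pairs with
a mobile "hinge" domain for core-finding superposition, planted
donor/acceptor geometries and an antiparallel beta-bridge for the
interaction detectors, aromatic-cage channels with a controlled number
of restraining tyrosine hydroxyls, and point-charge clouds paired with
an independent closed-form potential oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import defaults
from .structure_io import Atom, Chain, Residue, Structure, THREE_TO_ONE

__all__ = [
    "make_helix", "make_two_domain_pair", "make_rigid_pair",
    "make_hbond_fixture", "make_beta_bridge", "make_channel_fixture",
    "make_charge_cloud", "FixtureSpec", "make_fixture", "random_rotation",
]

_AA20 = sorted(set(THREE_TO_ONE) - {"MSE"})

# ideal backbone geometry (lengths in Angstrom, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Internal-to-Cartesian (NeRF): position d given bond c-d, angle b-c-d,
    dihedral a-b-c-d."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-math.cos(angle),
                          math.sin(angle) * math.cos(torsion),
                          math.sin(angle) * math.sin(torsion)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_helix(n_res: int, seed: int = 0, sequence: str | None = None,
               phi: float = -57.0, psi: float = -47.0,
               chain_id: str = "A", start_resnum: int = 1) -> Structure:
    """Ideal alpha-helix backbone (N, CA, C, O), poly-Ala by default.

    ``sequence`` (one-letter) overrides the residue names; the seed is
    accepted for interface uniformity (the builder itself is
    deterministic and noise-free).
    """
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    one_to_three = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}
    if sequence is None:
        names = ["ALA"] * n_res
    else:
        if len(sequence) != n_res:
            raise ValueError("sequence length must equal n_res")
        names = [one_to_three.get(ch.upper(), "ALA") for ch in sequence]
    omega = 180.0
    # bootstrap the first residue in a fixed frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place_atom(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, omega)
        c_i = _place_atom(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((n_i, ca_i, c_i))
    chain = Chain(id=chain_id)
    serial = 1
    for i, (n_i, ca_i, c_i) in enumerate(backbone):
        res = Residue(name=names[i], seq_number=start_resnum + i, chain_id=chain_id)
        # carbonyl O in the peptide plane, anti to the next N
        o_i = _place_atom(n_i, ca_i, c_i, _B_C_O, _A_CA_C_O, psi + 180.0)
        for name, pos, elem in (("N", n_i, "N"), ("CA", ca_i, "C"),
                                ("C", c_i, "C"), ("O", o_i, "O")):
            res.add(Atom(serial=serial, name=name, element=elem, altloc="",
                         coords=pos))
            serial += 1
        chain.residues.append(res)
    return Structure(id=f"helix{n_res}", chains=[chain])


def random_rotation(rng: np.random.Generator,
                    min_angle_deg: float = 10.0, max_angle_deg: float = 170.0) -> np.ndarray:
    """Uniform random axis, uniform angle in the given band."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(min_angle_deg, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def _check_rotation(rot: np.ndarray) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3) or np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-8 \
            or np.linalg.det(rot) < 0:
        raise ValueError("degenerate transform: rotation must be proper orthonormal")
    return rot


def make_two_domain_pair(core_len: int = 40, mobile_len: int = 17,
                         rotation: np.ndarray | None = None,
                         translation: np.ndarray | None = None,
                         noise_sigma: float = 0.1, hinge_shift: float = 5.0,
                         seed: int = 0) -> tuple[Structure, Structure, dict]:
    """Pair of structures related by a known rigid transform plus a hinge.

    Structure B is A moved by the planted (rotation, translation) with
    per-atom Gaussian noise; the trailing ``mobile_len`` residues of B
    are additionally displaced by ``hinge_shift`` Angstrom along a random
    direction, emulating a mobile domain that a core-finding
    superposition must down-weight. The returned record carries the
    ground truth for parameter-recovery tests.
    """
    if core_len < defaults.SEED_LEN:
        raise ValueError(f"core_len must be >= {defaults.SEED_LEN}")
    if mobile_len < 0:
        raise ValueError("mobile_len must be >= 0")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n = core_len + mobile_len
    sequence = "".join(rng.choice([THREE_TO_ONE[a] for a in _AA20], size=n))
    a = make_helix(n, sequence=sequence)
    rot = random_rotation(rng) if rotation is None else _check_rotation(rotation)
    trans = (rng.uniform(-10, 10, size=3) if translation is None
             else np.asarray(translation, dtype=float))
    hinge_dir = rng.normal(size=3)
    hinge_dir /= np.linalg.norm(hinge_dir)

    b = make_helix(n, sequence=sequence)
    b.id = a.id + "_moved"
    mobile_resnums = set(range(core_len + 1, n + 1))
    for res in b.iter_residues():
        for atom in res.atoms:
            pos = rot @ atom.coords + trans
            if res.seq_number in mobile_resnums:
                pos = pos + hinge_shift * hinge_dir
            if noise_sigma > 0:
                pos = pos + rng.normal(0.0, noise_sigma, size=3)
            atom.coords = pos
    truth = {
        "rotation": rot, "translation": trans,
        "core_resnums": sorted(set(range(1, core_len + 1))),
        "mobile_resnums": sorted(mobile_resnums),
        "noise_sigma": noise_sigma, "hinge_shift": hinge_shift,
        "hinge_direction": hinge_dir, "seed": seed,
    }
    return a, b, truth


def make_rigid_pair(n_res: int = 40, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    noise_sigma: float = 0.0, seed: int = 0) -> tuple[Structure, Structure, dict]:
    """Rigid pair without a mobile domain (degenerate two-domain case)."""
    return make_two_domain_pair(core_len=n_res, mobile_len=0, rotation=rotation,
                                translation=translation, noise_sigma=noise_sigma,
                                hinge_shift=0.0, seed=seed)


# ---------------------------------------------------------------------------
# interaction fixtures

def _residue_from(name: str, seq: int, chain_id: str, atoms: Sequence[tuple[str, str, np.ndarray]],
                  serial_start: int, hetero: bool = False) -> tuple[Residue, int]:
    res = Residue(name=name, seq_number=seq, chain_id=chain_id)
    serial = serial_start
    for atom_name, element, pos in atoms:
        res.add(Atom(serial=serial, name=atom_name, element=element, altloc="",
                     coords=np.asarray(pos, dtype=float), is_hetero=hetero))
        serial += 1
    return res, serial


def make_hbond_fixture(d_da: float, angle: float, seed: int = 0) -> Structure:
    """One backbone donor (N with CA antecedent) and one carbonyl acceptor.

    The donor--acceptor distance and the antecedent-donor-acceptor angle
    are planted exactly as requested; chains D (donor) and E (acceptor).
    """
    if d_da <= 0:
        raise ValueError("d_da must be positive")
    if not 0 < angle <= 180:
        raise ValueError("angle must be in (0, 180]")
    theta = math.radians(angle)
    n_pos = np.zeros(3)
    o_pos = np.array([d_da, 0.0, 0.0])
    ca_pos = _B_N_CA * np.array([math.cos(theta), math.sin(theta), 0.0])
    # acceptor antecedent carbonyl C, off-axis so it clashes with nothing
    c_pos = o_pos + _B_C_O * np.array([math.cos(math.radians(60)),
                                       math.sin(math.radians(60)), 0.0])
    ca2_pos = c_pos + np.array([1.2, 0.9, 0.0])
    donor, serial = _residue_from("ALA", 1, "D", [("N", "N", n_pos), ("CA", "C", ca_pos)], 1)
    acceptor, _ = _residue_from("ALA", 1, "E", [("CA", "C", ca2_pos), ("C", "C", c_pos),
                                                ("O", "O", o_pos)], serial)
    return Structure(id="hbond_fixture",
                     chains=[Chain(id="D", residues=[donor]), Chain(id="E", residues=[acceptor])])


# bridge templates: per-residue backbone offsets relative to the residue's N.
# "up" pleat points the carbonyl toward +y (the partner strand), "down" away.
_BRIDGE_PEP_UP = [("N", "N", (0.0, 0.0, 0.0)), ("CA", "C", (1.2, -0.85, 0.0)),
                  ("C", "C", (2.6, -0.35, 0.0)), ("O", "O", (2.7, 0.87, 0.0))]
_BRIDGE_PEP_DOWN = [(n, e, (x, -y, z)) for n, e, (x, y, z) in _BRIDGE_PEP_UP]
_BRIDGE_STR_DOWN = [(n, e, (-x, -y, z)) for n, e, (x, y, z) in _BRIDGE_PEP_UP]
_BRIDGE_STR_UP = [(n, e, (-x, y, z)) for n, e, (x, y, z) in _BRIDGE_PEP_UP]


def make_beta_bridge(flip: bool = False, seed: int = 0) -> Structure:
    """Antiparallel beta-bridge between a 3-residue peptide and a strand.

    The central peptide residue (LYS 9, chain P) makes the conserved pair
    of backbone hydrogen bonds with the central strand residue (chain I):
    peptide N donates to the strand carbonyl O and the strand N donates
    to the peptide carbonyl O. With ``flip=True`` the peptide is rotated
    180 degrees about its own axis in the groove, which preserves the
    residue composition but makes the double hydrogen bond geometrically
    impossible.
    """
    serial = 1
    pep_res = []
    for seq, x0, template, name in ((8, -3.8, _BRIDGE_PEP_DOWN, "THR"),
                                    (9, 0.0, _BRIDGE_PEP_UP, "LYS"),
                                    (10, 3.8, _BRIDGE_PEP_DOWN, "SER")):
        atoms = [(n, e, np.array([x0 + dx, dy, dz])) for n, e, (dx, dy, dz) in template]
        res, serial = _residue_from(name, seq, "P", atoms, serial)
        pep_res.append(res)
    strand_res = []
    for seq, x0, template in ((100, 6.55, _BRIDGE_STR_UP),
                              (101, 2.75, _BRIDGE_STR_DOWN),
                              (102, -1.05, _BRIDGE_STR_UP)):
        atoms = [(n, e, np.array([x0 + dx, 3.65 + dy, dz])) for n, e, (dx, dy, dz) in template]
        res, serial = _residue_from("VAL", seq, "I", atoms, serial)
        strand_res.append(res)
    if flip:
        # 180-degree rotation about the peptide backbone axis (x through y=z=0)
        for res in pep_res:
            for atom in res.atoms:
                atom.coords = atom.coords * np.array([1.0, -1.0, -1.0])
    return Structure(id="beta_bridge" + ("_flipped" if flip else ""),
                     chains=[Chain(id="P", residues=pep_res),
                             Chain(id="I", residues=strand_res)])


# ---------------------------------------------------------------------------
# channel fixture

def _aromatic_ring(direction: np.ndarray, oh_distance: float, with_oh: bool,
                   name: str, seq: int, chain_id: str, serial: int,
                   perp: np.ndarray) -> tuple[Residue, int]:
    """Tyr/Phe ring on the axis ``direction`` with the (would-be) hydroxyl
    oxygen at ``oh_distance`` from the origin."""
    u = direction / np.linalg.norm(direction)
    v = perp - np.dot(perp, u) * u
    v /= np.linalg.norm(v)
    oh = oh_distance * u
    cz = oh + defaults.OH_BOND_LENGTH * u          # ring carbon bearing the OH
    center = cz + 1.39 * u
    cg = center + 1.39 * u
    ring = [
        ("CG", cg), ("CZ", cz),
        ("CD1", center + 0.695 * u + 1.204 * v), ("CD2", center + 0.695 * u - 1.204 * v),
        ("CE1", center - 0.695 * u + 1.204 * v), ("CE2", center - 0.695 * u - 1.204 * v),
    ]
    atoms = [(n, "C", pos) for n, pos in ring]
    if with_oh:
        atoms.append(("OH", "O", oh))
    return _residue_from(name, seq, chain_id, atoms, serial)


def make_channel_fixture(n_restraining_tyr: int, seed: int = 0,
                         restrain_dist: float = 3.0,
                         nonrestrain_dist: float = 5.5) -> tuple[Structure, np.ndarray]:
    """Aromatic cage around a target methyl-accepting nitrogen at the origin.

    Exactly ``n_restraining_tyr`` tyrosine hydroxyls sit within
    hydrogen-bond range (3.0 A) of the target; the remaining tyrosines
    have their OH parked at 5.5 A (inside the channel lining radius but
    beyond restraint range). One phenylalanine completes the cage, with
    its para carbon placed so that an in-silico Phe->Tyr switch would put
    the new hydroxyl in restraint range. A LYS residue supplies the NZ
    target atom (chain P).
    """
    if n_restraining_tyr not in (0, 1, 2):
        raise ValueError("n_restraining_tyr must be 0, 1 or 2")
    target = np.zeros(3)
    dirs = [np.array([1.0, 0.0, 0.0]), np.array([-0.5, 0.866, 0.0]),
            np.array([-0.5, -0.866, 0.0])]
    perps = [np.array([0.0, 0.0, 1.0])] * 3
    serial = 1
    residues = []
    for k in range(2):  # two tyrosines, n of them restraining
        dist = restrain_dist if k < n_restraining_tyr else nonrestrain_dist
        res, serial = _aromatic_ring(dirs[k], dist, True, "TYR", 100 + k, "E",
                                     serial, perps[k])
        residues.append(res)
    phe, serial = _aromatic_ring(dirs[2], restrain_dist, False, "PHE", 102, "E",
                                 serial, perps[2])
    residues.append(phe)
    lys_atoms = [("CE", "C", np.array([0.0, 0.0, 1.5])), ("NZ", "N", target.copy())]
    lys, serial = _residue_from("LYS", 9, "P", lys_atoms, serial)
    structure = Structure(id=f"channel_{n_restraining_tyr}tyr",
                          chains=[Chain(id="E", residues=residues),
                                  Chain(id="P", residues=[lys])])
    return structure, target


# ---------------------------------------------------------------------------
# charge clouds

def make_charge_cloud(charges: Sequence[float] | Sequence[tuple], seed: int = 0,
                      box: float = 5.0) -> tuple[list[tuple[np.ndarray, float]], Callable]:
    """Point charges plus an independent closed-form potential oracle.

    ``charges`` is either a list of charge values (positions drawn
    uniformly in a cube of half-width ``box`` from the seed) or a list of
    ``(position, charge)`` pairs. Zero charges are dropped; an empty
    result is an error. The oracle evaluates the screened-Coulomb
    potential phi(p) = sum_i 332.0637 q_i exp(-kappa r_i)/(eps r_i) with
    plain Python arithmetic, independent of the analysis implementation.
    """
    rng = np.random.default_rng(seed)
    sites: list[tuple[np.ndarray, float]] = []
    for entry in charges:
        if isinstance(entry, (tuple, list)) and len(entry) == 2:
            pos, q = entry
            pos = np.asarray(pos, dtype=float)
        else:
            q = float(entry)
            pos = rng.uniform(-box, box, size=3)
        if q != 0.0:
            sites.append((pos, float(q)))
    if not sites:
        raise ValueError("no non-zero charges")

    def oracle(point, eps: float = 1.0, kappa: float = 0.0) -> float:
        px, py, pz = float(point[0]), float(point[1]), float(point[2])
        phi = 0.0
        for pos, q in sites:
            r = math.sqrt((px - pos[0]) ** 2 + (py - pos[1]) ** 2 + (pz - pos[2]) ** 2)
            phi += defaults.COULOMB_CONSTANT * q * math.exp(-kappa * r) / (eps * r)
        return phi

    return sites, oracle


# ---------------------------------------------------------------------------
# dispatcher

@dataclass
class FixtureSpec:
    kind: str
    seed: int = 0
    parameters: dict = field(default_factory=dict)


def make_fixture(spec: FixtureSpec):
    """Build a fixture from a declarative spec (used by the CLI)."""
    p = dict(spec.parameters)
    if spec.kind == "helix":
        return make_helix(p.pop("n_res", 30), seed=spec.seed, **p)
    if spec.kind == "rigid_pair":
        return make_rigid_pair(seed=spec.seed, **p)
    if spec.kind == "two_domain":
        return make_two_domain_pair(seed=spec.seed, **p)
    if spec.kind == "hbond_geometry":
        return make_hbond_fixture(p.pop("d_da", 2.9), p.pop("angle", 180.0), seed=spec.seed)
    if spec.kind == "beta_bridge":
        return make_beta_bridge(p.pop("flip", False), seed=spec.seed)
    if spec.kind == "channel":
        return make_channel_fixture(p.pop("n_restraining_tyr", 0), seed=spec.seed, **p)
    if spec.kind == "charge_cloud":
        return make_charge_cloud(p.pop("charges", [1.0]), seed=spec.seed, **p)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
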