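"""Methylation-state specificity from substrate-lysine channel geometry.

SET-domain methyltransferases accommodate the substrate lysine in a
narrow aromatic channel. Tyrosine hydroxyls close enough to hydrogen-
bond to the methyl-accepting epsilon-nitrogen lock the amine in an
orientation that blocks a further methyl transfer, so the maximal
achievable product state is inversely related to the number of such
"restraining" tyrosines:

    predicted_max_state = 3 - |restraining tyrosines|   (clamped to [0, 3])

With no restraining tyrosine the enzyme can tri-methylate; one allows
di-methylation; two confine it to mono-methylation. In-silico Tyr<->Phe
switches model the classic product-state mutants: removing a hydroxyl
(Tyr->Phe) raises the predicted state, adding one at the idealized
para position of a channel phenylalanine (Phe->Tyr) lowers it. The rule
predicts maximal product state only, never rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .structure_io import Atom, Residue, Structure

__all__ = ["ChannelProfile", "ResidueSwitch", "profile_channel", "apply_switch",
           "catalytic_residue_check"]

_AROMATIC = ("TYR", "PHE", "TRP")


@dataclass
class ResidueSwitch:
    residue: Residue
    from_type: str
    to_type: str

    def __post_init__(self) -> None:
        pair = {self.from_type.upper(), self.to_type.upper()}
        if pair != {"TYR", "PHE"}:
            raise ValueError("only TYR<->PHE switches are supported")
        self.from_type = self.from_type.upper()
        self.to_type = self.to_type.upper()


@dataclass
class ChannelProfile:
    target_nz: np.ndarray | None
    lining_residues: list[Residue]
    restraining_tyrosines: list[Residue]
    aromatic_census: dict[str, int]
    predicted_max_state: int | None
    status: str = "ok"                       # "ok" | "indeterminate"
    radius: float = defaults.CHANNEL_RADIUS
    hb_cut: float = defaults.HB_CUT
    switches: list[ResidueSwitch] = field(default_factory=list)

    @property
    def state_label(self) -> str:
        if self.predicted_max_state is None:
            return "indeterminate"
        return {0: "none", 1: "mono", 2: "di", 3: "tri"}[self.predicted_max_state]


def _resolve_target(target) -> np.ndarray | None:
    """Accept a 3-vector, an Atom, or an atom selection holding an NZ atom."""
    if target is None:
        return None
    if isinstance(target, Atom):
        return target.coords
    if isinstance(target, (list, tuple)) and target and isinstance(target[0], Atom):
        for atom in target:
            if atom.name == "NZ":
                return atom.coords
        if len(target) == 1:
            return target[0].coords
        raise ValueError("peptide selection carries no NZ atom")
    arr = np.asarray(target, dtype=float)
    if arr.shape != (3,):
        raise ValueError("target must be a 3-vector, an Atom, or a selection with NZ")
    return arr


def _effective_type(res: Residue, switches: list[ResidueSwitch]) -> str:
    name = res.name
    for sw in switches:
        if sw.residue.key == res.key:
            name = sw.to_type
    return name


def _ideal_oh(res: Residue) -> np.ndarray:
    """Idealized hydroxyl position for a Phe ring: CZ + 1.38 A along the
    para axis (CG -> CZ direction). No rotamer search is attempted."""
    cg, cz = res.atom("CG"), res.atom("CZ")
    if cg is None or cz is None:
        raise ValueError(f"{res.label}: ring atoms CG/CZ required for Phe->Tyr switch")
    axis = cz.coords - cg.coords
    axis = axis / np.linalg.norm(axis)
    return cz.coords + defaults.OH_BOND_LENGTH * axis


def _oh_position(res: Residue, switches: list[ResidueSwitch]) -> np.ndarray | None:
    """Effective hydroxyl position of a (possibly switched) channel residue."""
    eff = _effective_type(res, switches)
    if eff != "TYR":
        return None
    if res.name == "TYR":
        oh = res.atom("OH")
        return None if oh is None else oh.coords
    return _ideal_oh(res)


def _build_profile(structure: Structure, target: np.ndarray,
                   radius: float, hb_cut: float,
                   switches: list[ResidueSwitch],
                   exclude_keys: set) -> ChannelProfile:
    lining = []
    for res in structure.iter_residues():
        if res.is_water or res.key in exclude_keys:
            continue
        if any(np.linalg.norm(a.coords - target) <= radius for a in res.atoms):
            lining.append(res)
    if not lining:
        raise ValueError(f"no atoms within {radius} A of the target point; "
                         "wrong target or channel cannot be located")
    census = {name: 0 for name in _AROMATIC}
    restraining = []
    for res in lining:
        eff = _effective_type(res, switches)
        if eff in census:
            census[eff] += 1
        oh = _oh_position(res, switches)
        if oh is not None and np.linalg.norm(oh - target) <= hb_cut:
            restraining.append(res)
    state = int(np.clip(3 - len(restraining), 0, 3))
    return ChannelProfile(target_nz=target, lining_residues=lining,
                          restraining_tyrosines=restraining,
                          aromatic_census=census, predicted_max_state=state,
                          radius=radius, hb_cut=hb_cut, switches=list(switches))


def profile_channel(structure: Structure, target_nz,
                    radius: float = defaults.CHANNEL_RADIUS,
                    hb_cut: float = defaults.HB_CUT) -> ChannelProfile:
    """Profile the substrate-lysine channel around the epsilon-nitrogen.

    ``target_nz`` is the position of the methyl-accepting nitrogen: a
    3-vector, the NZ Atom of a bound peptide lysine, or an atom
    selection containing it (for apo enzymes the point is transferred
    from a superposed reference complex). ``target_nz=None`` yields an
    "indeterminate" profile, for enzymes whose channel cannot be located
    (e.g. a disordered Post-SET region).
    """
    target = _resolve_target(target_nz)
    if target is None:
        return ChannelProfile(target_nz=None, lining_residues=[],
                              restraining_tyrosines=[],
                              aromatic_census={name: 0 for name in _AROMATIC},
                              predicted_max_state=None, status="indeterminate",
                              radius=radius, hb_cut=hb_cut)
    exclude = set()
    if isinstance(target_nz, Atom) and target_nz.residue is not None:
        exclude.add(target_nz.residue.key)
    elif isinstance(target_nz, (list, tuple)) and target_nz \
            and isinstance(target_nz[0], Atom):
        exclude = {a.residue.key for a in target_nz if a.residue is not None}
    profile = _build_profile(structure, target, radius, hb_cut, [], exclude)
    profile._structure = structure          # retained for apply_switch
    profile._exclude = exclude
    return profile


def apply_switch(profile: ChannelProfile,
                 switches: list[ResidueSwitch]) -> ChannelProfile:
    """Recompute a channel profile under in-silico Tyr<->Phe switches.

    Switching the same residue back (Tyr->Phe then Phe->Tyr) cancels
    exactly, restoring the original profile. Tyr->Phe removes the
    hydroxyl; Phe->Tyr adds one at the idealized ring para position.
    """
    if profile.status != "ok":
        raise ValueError("cannot switch residues on an indeterminate profile")
    structure = getattr(profile, "_structure", None)
    if structure is None:
        raise ValueError("profile does not retain its source structure")
    lining_keys = {r.key for r in profile.lining_residues}
    active: list[ResidueSwitch] = list(profile.switches)
    for sw in switches:
        if sw.residue.key not in lining_keys:
            raise ValueError(f"switch target {sw.residue.label} is not a lining residue")
        if sw.residue.name not in ("TYR", "PHE"):
            raise ValueError(f"switch target {sw.residue.label} is not aromatic Tyr/Phe")
        # a switch that reverses an active one cancels it (toggle semantics)
        reverted = [a for a in active if a.residue.key == sw.residue.key
                    and a.to_type == sw.from_type and a.from_type == sw.to_type]
        if reverted:
            active.remove(reverted[-1])
        else:
            if _effective_type(sw.residue, active) != sw.from_type:
                raise ValueError(f"{sw.residue.label} is not currently {sw.from_type}")
            active.append(sw)
    new = _build_profile(structure, profile.target_nz, profile.radius,
                         profile.hb_cut, active,
                         getattr(profile, "_exclude", set()))
    new._structure = structure
    new._exclude = getattr(profile, "_exclude", set())
    return new


def catalytic_residue_check(structure: Structure, post_set_tyr: Residue,
                            target_nz,
                            radius: float = defaults.CHANNEL_RADIUS) -> tuple[bool, dict]:
    """Check that a Post-SET tyrosine hydroxyl sits inside the channel.

    Returns (catalytic_competent, geometry report). The residue must be
    a tyrosine with a resolved OH atom.
    """
    if post_set_tyr.name != "TYR":
        raise ValueError(f"{post_set_tyr.label} is not a tyrosine")
    oh = post_set_tyr.atom("OH")
    if oh is None:
        raise ValueError(f"{post_set_tyr.label}: hydroxyl not resolved (disordered?)")
    target = _resolve_target(target_nz)
    if target is None:
        raise ValueError("target epsilon-N position required")
    dist = float(np.linalg.norm(oh.coords - target))
    competent = dist <= radius
    report = {"residue": post_set_tyr.label, "oh_to_target": dist,
              "radius": radius, "catalytic_competent": competent}
    return competent, report
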