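"""Interaction-patch computation between a target and its partner.

The patch (epitope) is the set of atoms of each side lying within a
Euclidean cutoff (default 6 A) of any atom of the other side. All atoms
are used, hydrogens included when present; a heavy-only switch is
available. A k-d tree accelerates the pair search; the result set is
identical to the brute-force all-pairs computation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.spatial import cKDTree

from .model import Atom, coords_array

DEFAULT_CUTOFF = 6.0  # Angstrom


@dataclass
class InterfacePatch:
    target_atoms: list[Atom]
    partner_atoms: list[Atom]
    cutoff: float

    @property
    def target_residues(self) -> set[tuple[str, int, str]]:
        return {a.residue_key() for a in self.target_atoms}

    @property
    def partner_residues(self) -> set[tuple[str, int, str]]:
        return {a.residue_key() for a in self.partner_atoms}

    @property
    def is_empty(self) -> bool:
        return not self.target_atoms and not self.partner_atoms

    def swapped(self) -> "InterfacePatch":
        return InterfacePatch(target_atoms=list(self.partner_atoms),
                              partner_atoms=list(self.target_atoms),
                              cutoff=self.cutoff)

    def to_dict(self) -> dict:
        def _res_list(keys):
            return sorted([{"chain": c, "seqid": n, "icode": i}
                           for (c, n, i) in keys],
                          key=lambda r: (r["chain"], r["seqid"], r["icode"]))
        return {
            "cutoff": self.cutoff,
            "n_target_atoms": len(self.target_atoms),
            "n_partner_atoms": len(self.partner_atoms),
            "target_residues": _res_list(self.target_residues),
            "partner_residues": _res_list(self.partner_residues),
        }


def interaction_patch(target: Sequence[Atom], partner: Sequence[Atom],
                      cutoff: float = DEFAULT_CUTOFF,
                      heavy_only: bool = False) -> InterfacePatch:
    """Atoms of each side within ``cutoff`` (inclusive) of the other side.

    Raises ValueError on an empty selection; two chains everywhere apart
    give an empty patch, not an error.
    """
    if heavy_only:
        target = [a for a in target if a.is_heavy]
        partner = [a for a in partner if a.is_heavy]
    if not target or not partner:
        raise ValueError("empty selection")
    t_xyz = coords_array(target)
    p_xyz = coords_array(partner)
    t_tree = cKDTree(t_xyz)
    p_tree = cKDTree(p_xyz)
    t_hit = p_tree.query_ball_point(t_xyz, r=cutoff)
    p_hit = t_tree.query_ball_point(p_xyz, r=cutoff)
    target_atoms = [a for a, hits in zip(target, t_hit) if hits]
    partner_atoms = [a for a, hits in zip(partner, p_hit) if hits]
    return InterfacePatch(target_atoms=target_atoms,
                          partner_atoms=partner_atoms, cutoff=cutoff)
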