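"""Pocket retention filtering and orthosteric/allosteric classification.

A detected pocket is retained when at least four of its negative-image
probes lie within 1 A of a partner atom (the partner protein chain for
heterodimer pockets, the ligand for liganded pockets) — this removes
cavities that nothing actually binds into.

Liganded (PL) pockets are classified against the associated heterodimer
pocket after mapping the monomer into the heterodimer frame through a
rigid superposition of the shared chain: a ligand sitting on at least
four heterodimer-pocket probes (<= 1 A) is orthosteric, otherwise
allosteric (PLA); an orthosteric ligand that comes within the overlap
cutoff of any epitope atom competes directly with the protein partner
(PLOC), otherwise it binds the orthosteric site without clashing with
the epitope (PLONC).
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cavity import Pocket
from .model import Atom, Ligand, Structure, coords_array

logger = logging.getLogger(__name__)

RETAIN_CONTACT = 1.0        # A, probe-to-partner contact distance
RETAIN_MIN_PROBES = 4
ORTHOSTERIC_MIN_PROBES = 4  # ligand-on-probe count for the orthosteric call
OVERLAP_CUTOFF = 1.0        # A, ligand-to-epitope competitive cutoff


class PocketClass(enum.Enum):
    HD_ORTHOSTERIC = "HD_ORTHOSTERIC"
    PLOC = "PLOC"    # orthosteric competitive
    PLONC = "PLONC"  # orthosteric non-competitive
    PLA = "PLA"      # allosteric
    UNASSIGNED = "UNASSIGNED"


@dataclass
class Superposition:
    """Rigid-body map (rotation then translation) of one frame onto another."""

    rotation: np.ndarray   # 3x3, det +1
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        return xyz @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Superposition":
        return cls(rotation=np.eye(3), translation=np.zeros(3),
                   rmsd=0.0, n_pairs=0)


def retain_pocket(pocket: Pocket, partner_atoms: Sequence[Atom],
                  contact: float = RETAIN_CONTACT,
                  min_contact_probes: int = RETAIN_MIN_PROBES) -> bool:
    """True iff >= min_contact_probes probes lie <= contact of a partner atom."""
    if not pocket.probes or not partner_atoms:
        return False
    tree = cKDTree(coords_array(list(partner_atoms)))
    hits = tree.query_ball_point(pocket.probe_coords(), r=contact,
                                 return_length=True)
    return int(np.count_nonzero(hits > 0)) >= min_contact_probes


def _paired_ca(chain_pl, chain_hd) -> tuple[np.ndarray, np.ndarray]:
    """CA coordinate pairs matched by author residue number + insertion code."""
    def ca_map(chain):
        out = {}
        for res in chain.polymer_residues:
            for atom in res.atoms:
                if atom.name == "CA" and atom.is_heavy:
                    out[(res.seqid, res.icode)] = atom.coords
                    break
        return out
    a, b = ca_map(chain_pl), ca_map(chain_hd)
    keys = sorted(set(a) & set(b))
    if not keys:
        return np.empty((0, 3)), np.empty((0, 3))
    return (np.vstack([a[k] for k in keys]), np.vstack([b[k] for k in keys]))


def superpose_shared_chain(pl: Structure, hd: Structure,
                           shared_accession: str) -> Superposition:
    """Least-squares (Kabsch) rigid superposition of the shared chain,
    mapping monomer (PL) coordinates into the heterodimer (HD) frame.

    Pairing is by author residue number on CA atoms; fewer than three
    pairs is an error ("insufficient anchor").
    """
    def chain_with(s: Structure, accession: str):
        for chain in s.polymer_chains():
            if chain.entity_accession == accession:
                return chain
        raise ValueError(f"structure {s.id!r} has no polymer chain with "
                         f"accession {accession!r}")
    c_pl = chain_with(pl, shared_accession)
    c_hd = chain_with(hd, shared_accession)
    xyz_pl, xyz_hd = _paired_ca(c_pl, c_hd)
    if len(xyz_pl) < 3:
        raise ValueError(f"insufficient anchor: {len(xyz_pl)} paired CA atoms")
    mu_pl = xyz_pl.mean(axis=0)
    mu_hd = xyz_hd.mean(axis=0)
    rot, _ = Rotation.align_vectors(xyz_hd - mu_hd, xyz_pl - mu_pl)
    R = rot.as_matrix()
    t = mu_hd - mu_pl @ R.T
    moved = xyz_pl @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xyz_hd) ** 2, axis=1))))
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_pairs=len(xyz_pl))


def classify_pl_pocket(pl_pocket: Pocket, ligand: Ligand,
                       hd_pocket: Optional[Pocket],
                       epitope_atoms: Sequence[Atom],
                       superposition: Optional[Superposition] = None,
                       orthosteric_min_probes: int = ORTHOSTERIC_MIN_PROBES,
                       probe_contact: float = RETAIN_CONTACT,
                       overlap_cutoff: float = OVERLAP_CUTOFF,
                       ) -> tuple[PocketClass, dict]:
    """Classify a liganded pocket relative to the heterodimer pocket.

    Returns (class, details) where details carries k (ligand-contacted
    heterodimer probes) and the minimal ligand-epitope distance. A
    missing heterodimer pocket yields UNASSIGNED with a warning.
    """
    if hd_pocket is None or not hd_pocket.probes:
        logger.warning("pocket %s: no associated heterodimer pocket; "
                       "classification unassigned", pl_pocket.pocket_id)
        return PocketClass.UNASSIGNED, {"k": None, "min_epitope_dist": None}
    if superposition is None:
        superposition = Superposition.identity()
    lig_xyz = coords_array([a for a in ligand.atoms if a.is_heavy])
    if len(lig_xyz) == 0:
        raise ValueError("ligand has no heavy atoms")
    lig_xyz = superposition.apply(lig_xyz)

    lig_tree = cKDTree(lig_xyz)
    probe_hits = lig_tree.query_ball_point(hd_pocket.probe_coords(),
                                           r=probe_contact,
                                           return_length=True)
    k = int(np.count_nonzero(probe_hits > 0))

    min_epi = None
    if epitope_atoms:
        epi_xyz = coords_array(list(epitope_atoms))
        d = np.min(np.linalg.norm(
            lig_xyz[:, None, :] - epi_xyz[None, :, :], axis=2))
        min_epi = float(d)

    details = {"k": k, "min_epitope_dist": min_epi}
    if k < orthosteric_min_probes:
        return PocketClass.PLA, details
    if min_epi is not None and min_epi <= overlap_cutoff:
        return PocketClass.PLOC, details
    return PocketClass.PLONC, details
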