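"""Core in-memory model: atoms, residues, chains, structures, ligands.

Lightweight dataclasses decoupled from any parser. Coordinates are in
Angstroms throughout; residue numbering follows the source file (author
numbering) while list indices are 0-based.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class Method(enum.Enum):
    """Experimental method of structure determination."""

    XRAY = "XRAY"
    CRYOEM = "CRYOEM"
    NMR = "NMR"
    OTHER = "OTHER"


@dataclass(eq=False)
class Atom:
    """A single atom with a back-reference to its residue identity.

    ``altloc`` is the alternative-location character, empty when absent.
    Atoms compare by identity, never by value.
    """

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    altloc: str = ""
    serial: int = 0
    # back-reference fields (owning residue/chain), filled at build time
    chain_id: str = ""
    res_name: str = ""
    res_seqid: int = 0
    res_icode: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError("atom coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seqid, self.res_icode)


@dataclass
class Residue:
    name: str
    seqid: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)
    is_het: bool = False  # came from a HETATM-like record

    @property
    def is_water(self) -> bool:
        return self.name.upper() in WATER_NAMES

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def key(self) -> tuple[int, str]:
        return (self.seqid, self.icode)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    entity_accession: str = ""
    is_polymer: bool = False

    @property
    def polymer_residues(self) -> list[Residue]:
        """Polymer residues with at least one resolved heavy atom."""
        return [r for r in self.residues
                if not r.is_het and not r.is_water and r.heavy_atoms]

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues:
            yield from res.atoms


@dataclass
class Ligand:
    """A non-polymer, non-water residue treated as a small-molecule ligand."""

    name: str
    atoms: list[Atom]
    chain_id: str = ""
    seqid: int = 0

    @property
    def heavy_atom_count(self) -> int:
        return sum(1 for a in self.atoms if a.is_heavy)

    @property
    def elements(self) -> set[str]:
        return {a.element.upper() for a in self.atoms}


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)
    method: Method = Method.OTHER

    def polymer_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.is_polymer and c.polymer_residues]

    def ligands(self) -> list[Ligand]:
        out = []
        for chain in self.chains:
            for res in chain.residues:
                if res.is_het and not res.is_water:
                    out.append(Ligand(name=res.name, atoms=list(res.atoms),
                                      chain_id=chain.chain_id, seqid=res.seqid))
        return out

    def all_atoms(self, heavy_only: bool = False) -> list[Atom]:
        atoms: list[Atom] = []
        for chain in self.chains:
            for atom in chain.atoms():
                if heavy_only and not atom.is_heavy:
                    continue
                atoms.append(atom)
        return atoms

    def get_chain(self, chain_id: str) -> Chain:
        for chain in self.chains:
            if chain.chain_id == chain_id:
                return chain
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")


@dataclass
class QualityRecord:
    """Per-structure experimental metadata driving the quality filter.

    Absent numeric fields stay ``None`` ("missing"), never 0.
    """

    structure_id: str
    method: Method
    resolution: Optional[float] = None
    r_free: Optional[float] = None
    r_factor: Optional[float] = None
    fsc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise ValueError("resolution must be positive when present")


def coords_array(atoms: Sequence[Atom]) -> np.ndarray:
    """Stack atom coordinates into an (n, 3) array."""
    if not atoms:
        return np.empty((0, 3), dtype=float)
    return np.vstack([a.coords for a in atoms])
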