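"""Functional typing of protein heavy atoms for probe complementarity.

Fixed residue/atom-name lookup. Classes:
  donor         H-bond donor heavy atom (N-H, O-H)
  acceptor      H-bond acceptor (carbonyl/hydroxyl/ether O, some N)
  carboxylate_o negatively charged carboxylate/phosphate oxygen
  basic_n       positively charged nitrogen (Lys NZ, Arg NH/NE, His ring N+)
  aromatic_c    aromatic-ring carbon
  hydrophobic   other carbon / sulfur
Complementary cavity probe types are looked up via COMPLEMENT.
"""
from __future__ import annotations

from typing import Optional

# (resname, atomname) -> class; most specific rule wins
SIDECHAIN_TYPES: dict[tuple[str, str], str] = {}

_def = SIDECHAIN_TYPES  # terse alias for table building

# charged
for _a in ("OD1", "OD2"):
    _def[("ASP", _a)] = "carboxylate_o"
for _a in ("OE1", "OE2"):
    _def[("GLU", _a)] = "carboxylate_o"
_def[("LYS", "NZ")] = "basic_n"
for _a in ("NE", "NH1", "NH2"):
    _def[("ARG", _a)] = "basic_n"
# His treated as donor/acceptor pair rather than charged (neutral tautomer)
_def[("HIS", "ND1")] = "acceptor"
_def[("HIS", "NE2")] = "donor"

# donors
_def[("SER", "OG")] = "donor"
_def[("THR", "OG1")] = "donor"
_def[("TYR", "OH")] = "donor"
_def[("CYS", "SG")] = "donor"
_def[("TRP", "NE1")] = "donor"
_def[("ASN", "ND2")] = "donor"
_def[("GLN", "NE2")] = "donor"

# acceptors
_def[("ASN", "OD1")] = "acceptor"
_def[("GLN", "OE1")] = "acceptor"
_def[("MET", "SD")] = "hydrophobic"

# aromatic ring carbons
for _a in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"):
    _def[("PHE", _a)] = "aromatic_c"
    _def[("TYR", _a)] = "aromatic_c"
for _a in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"):
    _def[("TRP", _a)] = "aromatic_c"
for _a in ("CG", "CD2", "CE1"):
    _def[("HIS", _a)] = "aromatic_c"

BACKBONE_TYPES: dict[str, str] = {
    "N": "donor",      # amide NH
    "O": "acceptor",   # carbonyl
    "OXT": "carboxylate_o",
    "C": "hydrophobic",
    "CA": "hydrophobic",
    "CB": "hydrophobic",
}

COMPLEMENT: dict[str, str] = {
    "donor": "HB_ACCEPTOR",
    "acceptor": "HB_DONOR",
    "carboxylate_o": "DONOR_POS",
    "basic_n": "ACCEPTOR_NEG",
    "aromatic_c": "AROMATIC",
    "hydrophobic": "HYDROPHOBIC",
}


def atom_functional_class(res_name: str, atom_name: str,
                          element: str) -> Optional[str]:
    """Functional class of a protein heavy atom, or None for untyped atoms."""
    res_name = res_name.upper()
    atom_name = atom_name.upper()
    element = element.upper()
    if element in ("H", "D"):
        return None
    cls = SIDECHAIN_TYPES.get((res_name, atom_name))
    if cls is not None:
        return cls
    cls = BACKBONE_TYPES.get(atom_name)
    if cls is not None:
        return cls
    # element fallback for non-canonical residues
    if element in ("C", "S"):
        return "hydrophobic"
    if element == "N":
        return "donor"
    if element == "O":
        return "acceptor"
    return None
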