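"""Structure reading, quality filtering, selection, stripping, MOL2 output.

Coordinates are parsed with gemmi (PDB and mmCIF). Header-level quality
metadata (experimental method, resolution, R-free/R-factor gap, FSC) is
read from REMARK records or the ``refine``/``em_3d_reconstruction`` mmCIF
categories. Entity accessions come from DBREF/struct_ref records or a
caller-supplied mapping; no network lookup is ever performed.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .cavity import Pocket, Probe, ProbeType
from .interface import InterfacePatch
from .model import (Atom, Chain, Ligand, Method, QualityRecord, Residue,
                    Structure)

logger = logging.getLogger(__name__)

DEFAULT_MIN_HEAVY = 8
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I"})

RESOLUTION_XRAY_MAX = 3.5    # A
RESOLUTION_CRYOEM_MAX = 3.0  # A
RGAP_MAX = 0.07
FSC_MAX = 0.143

_METHOD_MAP = [
    ("X-RAY", Method.XRAY),
    ("ELECTRON MICROSCOPY", Method.CRYOEM),
    ("ELECTRON CRYSTALLOGRAPHY", Method.CRYOEM),
    ("CRYO", Method.CRYOEM),
    ("NMR", Method.NMR),
]


class ParseError(ValueError):
    pass


class MetadataError(ValueError):
    pass


def _method_from_text(text: str) -> Method:
    text = text.upper()
    for key, method in _METHOD_MAP:
        if key in text:
            return method
    return Method.OTHER


def _sniff_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="replace")[:2000]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _parse_dbref_accessions(text: str) -> dict[str, str]:
    """chain id -> database accession from PDB DBREF records."""
    acc: dict[str, str] = {}
    for line in text.splitlines():
        if line.startswith("DBREF"):
            chain = line[12:14].strip()
            accession = line[33:41].strip()
            if chain and accession and chain not in acc:
                acc[chain] = accession
    return acc


def _parse_struct_ref_accessions(doc: "gemmi.cif.Document") -> dict[str, str]:
    """chain/entity -> accession from mmCIF struct_ref categories."""
    acc: dict[str, str] = {}
    block = doc.sole_block()
    ent_to_acc: dict[str, str] = {}
    for row in block.find("_struct_ref.", ["entity_id", "pdbx_db_accession"]):
        ent_to_acc[row.str(0)] = row.str(1)
    # map chains (auth asym) to entities via atom_site
    for row in block.find("_atom_site.", ["auth_asym_id", "label_entity_id"]):
        chain, ent = row.str(0), row.str(1)
        if chain not in acc and ent in ent_to_acc:
            acc[chain] = ent_to_acc[ent]
    return acc


def _is_amino(res_name: str) -> bool:
    info = gemmi.find_tabulated_residue(res_name)
    return bool(info and info.is_amino_acid())


def read_structure(path, fmt: str = "auto",
                   accessions: Optional[dict[str, str]] = None) -> Structure:
    """Parse a PDB/mmCIF file into the in-memory model.

    Alternative-location indicators and hydrogens are preserved.
    ``accessions`` overrides per-chain entity accessions (chain id ->
    accession); otherwise DBREF / struct_ref records are used.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = _sniff_format(path, fmt)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(path.read_text())
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ParseError(f"unknown format: {fmt}")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ParseError(f"no atoms parsed from {path}")

    acc_map = dict(accessions or {})
    if not accessions:
        if fmt == "pdb":
            acc_map = _parse_dbref_accessions(path.read_text())
        else:
            try:
                acc_map = _parse_struct_ref_accessions(
                    gemmi.cif.read(str(path)))
            except Exception:
                acc_map = {}

    method = _method_from_text(dict(st.info).get("_exptl.method", ""))
    out = Structure(id=path.stem, method=method)
    serial = 0
    for g_chain in st[0]:
        chain = Chain(chain_id=g_chain.name,
                      entity_accession=acc_map.get(g_chain.name, ""))
        n_amino = 0
        for g_res in g_chain:
            res = Residue(name=g_res.name, seqid=g_res.seqid.num,
                          icode=(g_res.seqid.icode or "").strip(),
                          is_het=(g_res.het_flag == "H"))
            if not res.is_het and _is_amino(res.name):
                n_amino += 1
            for g_atom in g_res:
                serial += 1
                res.atoms.append(Atom(
                    name=g_atom.name,
                    element=g_atom.element.name,
                    coords=np.array([g_atom.pos.x, g_atom.pos.y,
                                     g_atom.pos.z]),
                    altloc=(g_atom.altloc or "").strip("\x00 "),
                    serial=g_atom.serial or serial,
                    chain_id=chain.chain_id,
                    res_name=res.name,
                    res_seqid=res.seqid,
                    res_icode=res.icode,
                ))
            chain.residues.append(res)
        chain.is_polymer = n_amino > 0
        out.chains.append(chain)
    _warn_incomplete_residues(out)
    return out


_EXPECTED_BACKBONE = {"N", "CA", "C", "O"}


def _warn_incomplete_residues(s: Structure) -> None:
    """Inputs are assumed complete; missing backbone atoms only get a warning."""
    for chain in s.chains:
        for res in chain.polymer_residues:
            names = {a.name for a in res.heavy_atoms}
            missing = _EXPECTED_BACKBONE - names
            if missing:
                logger.warning("structure %s chain %s residue %s %d misses "
                               "expected heavy atoms: %s", s.id,
                               chain.chain_id, res.name, res.seqid,
                               ",".join(sorted(missing)))


_RE_RESOLUTION = re.compile(
    r"REMARK\s+2\s+RESOLUTION\.?\s+([\d.]+)\s+ANGSTROM", re.I)
_RE_RWORK = re.compile(
    r"REMARK\s+3\s+R VALUE\s+\(WORKING SET(?:, NO CUTOFF)?\)\s*:\s*([\d.]+)",
    re.I)
_RE_RWORK_ALT = re.compile(
    r"REMARK\s+3\s+R VALUE\s*(?:\(WORKING \+ TEST SET\))?\s*:\s*([\d.]+)", re.I)
_RE_RFREE = re.compile(
    r"REMARK\s+3\s+FREE R VALUE\s*(?:\(NO CUTOFF\))?\s*:\s*([\d.]+)", re.I)
_RE_FSC = re.compile(r"REMARK\s+3\s+.*FSC[^:]*:\s*([\d.]+)", re.I)


def parse_quality(source, fmt: str = "auto",
                  structure_id: str = "") -> QualityRecord:
    """Quality metadata from a file path or a raw PDB header block.

    Absent numeric fields are left missing (None), never defaulted to 0.
    Raises MetadataError when no experimental-method record is present.
    """
    text: Optional[str] = None
    path: Optional[Path] = None
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        path = Path(source)
        fmt = _sniff_format(path, fmt)
        if fmt == "mmcif":
            return _parse_quality_mmcif(path, structure_id or path.stem)
        text = path.read_text()
        structure_id = structure_id or path.stem
    else:
        text = str(source)

    method_line = None
    for line in text.splitlines():
        if line.startswith("EXPDTA"):
            method_line = line[6:].strip()
            break
    if method_line is None:
        raise MetadataError("no EXPDTA method record")
    method = _method_from_text(method_line)

    def _search(rx):
        m = rx.search(text)
        return float(m.group(1)) if m else None

    resolution = _search(_RE_RESOLUTION)
    r_factor = _search(_RE_RWORK)
    if r_factor is None:
        r_factor = _search(_RE_RWORK_ALT)
    r_free = _search(_RE_RFREE)
    fsc = _search(_RE_FSC)
    return QualityRecord(structure_id=structure_id or "header", method=method,
                         resolution=resolution, r_free=r_free,
                         r_factor=r_factor, fsc=fsc)


def _parse_quality_mmcif(path: Path, structure_id: str) -> QualityRecord:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def _num(tag):
        val = block.find_value(tag)
        if val in (None, ".", "?"):
            return None
        try:
            return float(val)
        except ValueError:
            return None

    method_text = block.find_value("_exptl.method")
    if method_text is None:
        raise MetadataError("no _exptl.method record")
    method = _method_from_text(gemmi.cif.as_string(method_text))
    resolution = _num("_refine.ls_d_res_high")
    if resolution is None:
        resolution = _num("_em_3d_reconstruction.resolution")
    r_factor = _num("_refine.ls_R_factor_R_work")
    if r_factor is None:
        r_factor = _num("_refine.ls_R_factor_obs")
    r_free = _num("_refine.ls_R_factor_R_free")
    fsc = _num("_em_3d_reconstruction.fsc_threshold")
    return QualityRecord(structure_id=structure_id, method=method,
                         resolution=resolution, r_free=r_free,
                         r_factor=r_factor, fsc=fsc)


def passes_quality(q: QualityRecord,
                   resolution_xray_max: float = RESOLUTION_XRAY_MAX,
                   resolution_cryoem_max: float = RESOLUTION_CRYOEM_MAX,
                   rgap_max: float = RGAP_MAX,
                   fsc_max: float = FSC_MAX) -> tuple[bool, str]:
    """Method whitelist + per-method metric thresholds (all inclusive).

    NMR structures carry no numeric filter; X-ray requires resolution
    <= 3.5 A and R-free - R-factor <= 0.07; cryo-EM requires resolution
    <= 3.0 A and FSC <= 0.143. A missing required metric fails closed.
    """
    if q.method is Method.NMR:
        return True, "ok"
    if q.method is Method.XRAY:
        if q.resolution is None or q.r_free is None or q.r_factor is None:
            return False, "missing metric"
        if q.resolution > resolution_xray_max:
            return False, f"resolution {q.resolution:.2f} > {resolution_xray_max}"
        gap = q.r_free - q.r_factor
        if gap > rgap_max:
            return False, f"r_free - r_factor {gap:.3f} > {rgap_max}"
        return True, "ok"
    if q.method is Method.CRYOEM:
        if q.resolution is None or q.fsc is None:
            return False, "missing metric"
        if q.resolution > resolution_cryoem_max:
            return False, f"resolution {q.resolution:.2f} > {resolution_cryoem_max}"
        if q.fsc > fsc_max:
            return False, f"fsc {q.fsc:.3f} > {fsc_max}"
        return True, "ok"
    return False, f"method {q.method.value} not allowed"


@dataclass
class Selection:
    accepted: bool
    reason: str
    target_chain: Optional[Chain] = None
    partner_chain: Optional[Chain] = None
    ligand: Optional[Ligand] = None


def select_heterodimer(s: Structure) -> Selection:
    """Accept complexes of exactly two polymer chains with distinct
    accessions, each longer than three residues."""
    chains = s.polymer_chains()
    if len(chains) != 2:
        return Selection(False, f"expected 2 polymer chains, found {len(chains)}")
    a, b = chains
    if not a.entity_accession or not b.entity_accession:
        return Selection(False, "missing accession")
    if a.entity_accession == b.entity_accession:
        return Selection(False, "homodimer")
    for chain in (a, b):
        if len(chain.polymer_residues) <= 3:
            return Selection(False,
                             f"too short: chain {chain.chain_id} has "
                             f"{len(chain.polymer_residues)} residues")
    return Selection(True, "ok", target_chain=a, partner_chain=b)


def select_protein_ligand(s: Structure, min_heavy: int = DEFAULT_MIN_HEAVY,
                          allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS,
                          ) -> Selection:
    """Accept monomer+ligand complexes whose ligand is large enough and
    made exclusively of drug-like elements."""
    allowed = {e.upper() for e in allowed_elements}
    ligands = s.ligands()
    if not ligands:
        return Selection(False, "no ligand")
    # prefer the largest candidate; deterministic tie-break
    ligands.sort(key=lambda l: (-l.heavy_atom_count, l.chain_id, l.seqid))
    reasons = []
    for lig in ligands:
        bad = lig.elements - allowed
        if bad:
            reasons.append(f"{lig.name}: non-drug-like element "
                           f"{','.join(sorted(bad))}")
            continue
        if lig.heavy_atom_count < min_heavy:
            reasons.append(f"{lig.name}: too small "
                           f"({lig.heavy_atom_count} < {min_heavy})")
            continue
        chains = s.polymer_chains()
        target = chains[0] if chains else None
        return Selection(True, "ok", target_chain=target, ligand=lig)
    return Selection(False, "; ".join(reasons))


def check_altloc_at_interface(s: Structure, patch: InterfacePatch) -> bool:
    """True (structure excluded) iff any patch atom has an altloc set."""
    for atom in list(patch.target_atoms) + list(patch.partner_atoms):
        if atom.altloc:
            return True
    return False


def strip_structure(s: Structure, mode: str = "HD",
                    ligand: Optional[Ligand] = None) -> Structure:
    """Remove waters always; remove heteroatom residues in HD mode; in PL
    mode retain only the designated (or largest non-water) ligand."""
    mode = mode.upper()
    if mode not in ("HD", "PL"):
        raise ValueError(f"unknown strip mode {mode!r}")
    keep_key = None
    if mode == "PL":
        if ligand is None:
            ligands = s.ligands()
            if ligands:
                ligands.sort(key=lambda l: (-l.heavy_atom_count,
                                            l.chain_id, l.seqid))
                ligand = ligands[0]
        if ligand is not None:
            keep_key = (ligand.chain_id, ligand.seqid, ligand.name)

    out = Structure(id=s.id, method=s.method)
    for chain in s.chains:
        new_chain = Chain(chain_id=chain.chain_id,
                          entity_accession=chain.entity_accession,
                          is_polymer=chain.is_polymer)
        for res in chain.residues:
            if res.is_water:
                continue
            if res.is_het:
                if mode == "HD":
                    continue
                if keep_key != (chain.chain_id, res.seqid, res.name):
                    continue
            new_chain.residues.append(res)
        if new_chain.residues:
            out.chains.append(new_chain)
    return out


_MOL2_CODE = {
    ProbeType.HYDROPHOBIC: ("HYD", "C.3"),
    ProbeType.AROMATIC: ("ARO", "C.ar"),
    ProbeType.HB_ACCEPTOR: ("ACC", "O.2"),
    ProbeType.HB_DONOR: ("DON", "N.am"),
    ProbeType.ACCEPTOR_NEG: ("ANE", "O.co2"),
    ProbeType.DONOR_POS: ("DPO", "N.4"),
    ProbeType.DUMMY: ("DUM", "Du"),
}
_CODE_TO_TYPE = {code: pt for pt, (code, _) in _MOL2_CODE.items()}


def write_mol2(pocket: Pocket, path) -> None:
    """SYBYL MOL2 negative image: one atom record per probe.

    The probe pharmacophore type is encoded in the atom name and the
    buriedness count is stored in the charge column.
    """
    if not pocket.probes:
        raise ValueError("refusing to write an empty pocket")
    lines = ["@<TRIPOS>MOLECULE", pocket.pocket_id or "pocket",
             f"{len(pocket.probes)} 0 0 0 0", "SMALL", "USER_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i, probe in enumerate(pocket.probes, start=1):
        code, sybyl = _MOL2_CODE[probe.probe_type]
        x, y, z = probe.coords
        lines.append(f"{i:>7d} {code:<4s} {x:>12.4f} {y:>12.4f} {z:>12.4f} "
                     f"{sybyl:<7s} 1 CAV1 {float(probe.buriedness):>8.3f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_mol2(path) -> Pocket:
    """Read back a pocket MOL2 written by :func:`write_mol2`."""
    text = Path(path).read_text()
    lines = text.splitlines()
    name = "pocket"
    probes: list[Probe] = []
    section = None
    mol_header = 0
    for line in lines:
        if line.startswith("@<TRIPOS>"):
            section = line[len("@<TRIPOS>"):].strip()
            mol_header = 0
            continue
        if section == "MOLECULE":
            mol_header += 1
            if mol_header == 1 and line.strip():
                name = line.strip()
        elif section == "ATOM" and line.strip():
            parts = line.split()
            code = parts[1]
            coords = np.array([float(parts[2]), float(parts[3]),
                               float(parts[4])])
            bur = int(round(float(parts[8]))) if len(parts) > 8 else 0
            probes.append(Probe(coords=coords,
                                probe_type=_CODE_TO_TYPE.get(
                                    code, ProbeType.DUMMY),
                                buriedness=bur))
    return Pocket(pocket_id=name, probes=probes)
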