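"""Deterministic synthetic inputs for every pipeline stage.

Nothing here downloads or imitates real proteins: geometry is built
from ideal spacings on a deterministic lattice, accession tags are
synthetic (FIXA/FIXB), and every generator is a pure function of its
parameters and seed, so the same call always yields byte-identical
output.

The groove complex emulates the canonical peptide-in-groove interface
(a p53/MDM2-like arrangement): chain A is a half-pipe wall of residues
forming a concave channel; HD mode seats a 9-residue helix-like peptide
(chain B) in the channel, PL mode a 12-heavy-atom organic ligand. The
flat-chain fixture is a planar sheet with a partner hovering above it:
plenty of contact, but no concavity, so cavity detection at defaults
finds nothing.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROOVE_ACCESSION = "FIXA"
PEPTIDE_ACCESSION = "FIXB"

# half-pipe cross-section: circle of this radius in the (y, z) plane,
# axis along x, opening (no wall) within +-50 deg of +z
_PIPE_RADIUS = 4.0
_PIPE_CENTER_Z = 4.0
_WALL_ANGLES_DEG = tuple(range(50, 311, 20))   # 14 azimuths, opening at top
_RING_X = tuple(np.round(np.arange(0.0, 13.0, 1.6), 3))  # 9 rings


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, xyz, element: str, het: bool = False,
                   altloc: str = " ", occ: float = 1.0) -> str:
    record = "HETATM" if het else "ATOM  "
    x, y, z = xyz
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{record}{serial:>5d} {name_field}{altloc}{resname:>3s} "
            f"{chain}{resseq:>4d}    {x:>8.3f}{y:>8.3f}{z:>8.3f}"
            f"{occ:>6.2f}{0.0:>6.2f}          {element:>2s}")


def _dbref_line(chain: str, first: int, last: int, accession: str) -> str:
    line = list(" " * 68)

    def put(start: int, text: str):  # start is 1-based column
        for i, ch in enumerate(text):
            line[start - 1 + i] = ch
    put(1, "DBREF")
    put(8, "FIXT")
    put(13, chain)
    put(15, f"{first:>4d}")
    put(21, f"{last:>4d}")
    put(27, "UNP")
    put(34, f"{accession:<8s}")
    put(43, f"{accession}_SYN")
    put(56, f"{first:>5d}")
    put(63, f"{last:>5d}")
    return "".join(line).rstrip()


def quality_header(method: str = "X-RAY DIFFRACTION",
                   resolution: Optional[float] = 2.0,
                   r_factor: Optional[float] = 0.18,
                   r_free: Optional[float] = 0.22,
                   fsc: Optional[float] = None) -> list[str]:
    """PDB-style header lines materializing a quality record."""
    lines = [f"EXPDTA    {method}"]
    if resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {resolution:.2f} ANGSTROMS.")
    else:
        lines.append("REMARK   2 RESOLUTION. NOT APPLICABLE.")
    if r_factor is not None:
        lines.append(f"REMARK   3   R VALUE            (WORKING SET) : "
                     f"{r_factor:.3f}")
    if r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : "
                     f"{r_free:.3f}")
    if fsc is not None:
        lines.append(f"REMARK   3   FSC THRESHOLD                    : "
                     f"{fsc:.3f}")
    return lines


def _groove_wall_atoms(jitter: float, rng) -> list[tuple]:
    """(name, resseq, xyz, element) tuples for the chain-A half-pipe."""
    atoms = []
    resseq = 0
    for xc in _RING_X:
        for ang in _WALL_ANGLES_DEG:
            resseq += 1
            rad = math.radians(ang)
            ey, ez = math.sin(rad), math.cos(rad)  # outward unit vector
            yc = _PIPE_RADIUS * ey
            zc = _PIPE_CENTER_Z + _PIPE_RADIUS * ez
            base = np.array([xc, yc, zc])
            if jitter > 0:
                base = base + rng.uniform(-jitter, jitter, size=3)
            out = np.array([0.0, ey, ez])  # radially outward
            atoms.append(("N", resseq, base + [-0.8, 0, 0], "N"))
            atoms.append(("CA", resseq, base, "C"))
            atoms.append(("C", resseq, base + [0.8, 0, 0], "C"))
            atoms.append(("O", resseq, base + 0.7 * out, "O"))
            atoms.append(("CB", resseq, base + 1.4 * out, "C"))
    return atoms


def _peptide_atoms(jitter: float, rng) -> list[tuple]:
    """9-residue helix-like peptide seated on the channel axis."""
    atoms = []
    for k in range(9):
        xc = 2.0 + 1.2 * k
        base = np.array([xc, 0.0, _PIPE_CENTER_Z])
        if jitter > 0:
            base = base + rng.uniform(-jitter, jitter, size=3)
        atoms.append(("N", k + 1, base + [-0.5, 0.3, 0], "N"))
        atoms.append(("CA", k + 1, base, "C"))
        atoms.append(("C", k + 1, base + [0.5, -0.3, 0], "C"))
        atoms.append(("O", k + 1, base + [0.5, 0, 0.6], "O"))
    return atoms


def _ligand_atoms(jitter: float, rng) -> list[tuple]:
    """12-heavy-atom organic-like ligand along the channel axis."""
    elements = ["C", "C", "N", "C", "O", "C", "C", "C", "O", "C", "C", "C"]
    atoms = []
    for k, elem in enumerate(elements):
        xc = 2.6 + 0.8 * k
        dy = 0.4 if k % 2 else -0.4
        dz = 0.3 if k % 3 == 0 else -0.2
        base = np.array([xc, dy, _PIPE_CENTER_Z + dz])
        if jitter > 0:
            base = base + rng.uniform(-jitter, jitter, size=3)
        atoms.append((f"{elem}{k + 1}", 1, base, elem))
    return atoms


def make_groove_complex(seed: int = 0, mode: str = "HD",
                        jitter: float = 0.0,
                        n_waters: int = 0, with_ion: bool = False,
                        altloc_in_interface: bool = False,
                        quality: Optional[dict] = None) -> str:
    """PDB text of the groove complex (chain A wall + partner).

    mode 'HD' adds the chain-B peptide, 'PL' the LIG ligand. Optional
    waters/ion exercise stripping; ``altloc_in_interface`` duplicates
    one peptide/ligand-facing wall atom with altloc A/B.
    """
    mode = mode.upper()
    if mode not in ("HD", "PL"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    lines = ["HEADER    SYNTHETIC GROOVE FIXTURE"]
    lines += quality_header(**(quality or {}))
    wall = _groove_wall_atoms(jitter, rng)
    n_res_a = max(a[1] for a in wall)
    lines.append(_dbref_line("A", 1, n_res_a, GROOVE_ACCESSION))
    if mode == "HD":
        lines.append(_dbref_line("B", 1, 9, PEPTIDE_ACCESSION))

    serial = 0
    for name, resseq, xyz, elem in wall:
        serial += 1
        if altloc_in_interface and serial == 2:  # first CA, faces channel
            lines.append(_pdb_atom_line(serial, name, "ALA", "A", resseq,
                                        xyz, elem, altloc="A", occ=0.5))
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "ALA", "A", resseq,
                                        np.asarray(xyz) + [0.2, 0, 0],
                                        elem, altloc="B", occ=0.5))
            continue
        lines.append(_pdb_atom_line(serial, name, "ALA", "A", resseq,
                                    xyz, elem))
    lines.append("TER")
    if mode == "HD":
        for name, resseq, xyz, elem in _peptide_atoms(jitter, rng):
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "GLY", "B", resseq,
                                        xyz, elem))
        lines.append("TER")
    else:
        for name, resseq, xyz, elem in _ligand_atoms(jitter, rng):
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "LIG", "L", resseq,
                                        xyz, elem, het=True))
    for w in range(n_waters):
        serial += 1
        lines.append(_pdb_atom_line(serial, "O", "HOH", "W", w + 1,
                                    (20.0 + 3.0 * w, 15.0, 15.0), "O",
                                    het=True))
    if with_ion:
        serial += 1
        lines.append(_pdb_atom_line(serial, "NA", "NA", "I", 1,
                                    (25.0, -10.0, 15.0), "NA", het=True))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_flat_chain(seed: int = 0, jitter: float = 0.0,
                    quality: Optional[dict] = None) -> str:
    """PDB text of a planar sheet (chain A) with a peptide hovering above.

    The interface patch is non-empty but the surface has no concavity,
    so cavity detection at default buriedness finds no pocket.
    """
    rng = np.random.default_rng(seed)
    lines = ["HEADER    SYNTHETIC FLAT FIXTURE"]
    lines += quality_header(**(quality or {}))
    lines.append(_dbref_line("A", 1, 25, GROOVE_ACCESSION))
    lines.append(_dbref_line("B", 1, 9, PEPTIDE_ACCESSION))
    serial = 0
    resseq = 0
    for i in range(5):
        for j in range(5):
            resseq += 1
            base = np.array([2.4 * i, 2.4 * j, 0.0])
            if jitter > 0:
                base = base + rng.uniform(-jitter, jitter, size=3)
            for name, off, elem in (("N", [-0.8, 0, 0], "N"),
                                    ("CA", [0, 0, 0], "C"),
                                    ("C", [0.8, 0, 0], "C"),
                                    ("O", [0, 0.6, -0.4], "O")):
                serial += 1
                lines.append(_pdb_atom_line(serial, name, "ALA", "A", resseq,
                                            base + off, elem))
    lines.append("TER")
    for k in range(9):
        base = np.array([1.0 + 1.2 * k, 4.8, 4.2])
        for name, off, elem in (("N", [-0.5, 0.3, 0], "N"),
                                ("CA", [0, 0, 0], "C"),
                                ("C", [0.5, -0.3, 0], "C"),
                                ("O", [0.5, 0, 0.6], "O")):
            serial += 1
            lines.append(_pdb_atom_line(serial, name, "GLY", "B", k + 1,
                                        base + off, elem))
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_descriptor_matrix(n: int, p: int,
                           zero_frac_per_col: Optional[Sequence[float]] = None,
                           duplicates: Optional[Sequence[tuple[int, int]]] = None,
                           seed: int = 0) -> pd.DataFrame:
    """Synthetic descriptor matrix with exact per-column zero counts and
    exact duplicate rows.

    zero_frac_per_col gives, per column, the fraction of rows forced to
    zero (count = round(frac * n), exact by construction). duplicates is
    a list of (i, j) row-index pairs; row j is overwritten with row i.
    """
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 rows and p >= 1 columns")
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.5, 2.0, size=(n, p))
    if zero_frac_per_col is not None:
        if len(zero_frac_per_col) != p:
            raise ValueError("zero_frac_per_col must have one entry per column")
        for j, frac in enumerate(zero_frac_per_col):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"column {j}: infeasible zero fraction {frac}")
            n_zero = int(round(frac * n))
            rows = rng.choice(n, size=n_zero, replace=False)
            values[rows, j] = 0.0
    ids = [f"P{i:03d}" for i in range(n)]
    df = pd.DataFrame(values, index=ids,
                      columns=[f"d{j:03d}" for j in range(p)])
    df.index.name = "pocket_id"
    for (i, j) in duplicates or []:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"duplicate pair ({i}, {j}) out of range")
        df.iloc[j] = df.iloc[i].to_numpy()
    return df


def make_quality_table(rows: Optional[Sequence[dict]] = None
                       ) -> list[tuple[str, str, bool]]:
    """(structure_id, header text, expected pass) triples.

    Default rows exercise the filter boundaries: 3.5 / 3.0 A resolution,
    0.07 R gap, 0.143 FSC, the method whitelist, and missing metrics.
    """
    if rows is None:
        rows = [
            dict(id="xray_ok", method="X-RAY DIFFRACTION", resolution=3.5,
                 r_factor=0.18, r_free=0.25, expect=True),
            dict(id="xray_res_fail", method="X-RAY DIFFRACTION",
                 resolution=3.6, r_factor=0.18, r_free=0.22, expect=False),
            dict(id="xray_rgap_fail", method="X-RAY DIFFRACTION",
                 resolution=2.0, r_factor=0.18, r_free=0.26, expect=False),
            dict(id="xray_missing", method="X-RAY DIFFRACTION",
                 resolution=2.0, r_factor=None, r_free=None, expect=False),
            dict(id="em_ok", method="ELECTRON MICROSCOPY", resolution=3.0,
                 r_factor=None, r_free=None, fsc=0.143, expect=True),
            dict(id="em_fsc_fail", method="ELECTRON MICROSCOPY",
                 resolution=3.0, r_factor=None, r_free=None, fsc=0.144,
                 expect=False),
            dict(id="em_res_fail", method="ELECTRON MICROSCOPY",
                 resolution=3.1, r_factor=None, r_free=None, fsc=0.10,
                 expect=False),
            dict(id="nmr_ok", method="SOLUTION NMR", resolution=None,
                 r_factor=None, r_free=None, expect=True),
            dict(id="other_fail", method="NEUTRON DIFFRACTION",
                 resolution=1.5, r_factor=0.15, r_free=0.18, expect=False),
        ]
    out = []
    for row in rows:
        header = "\n".join(quality_header(
            method=row.get("method", "X-RAY DIFFRACTION"),
            resolution=row.get("resolution"),
            r_factor=row.get("r_factor"),
            r_free=row.get("r_free"),
            fsc=row.get("fsc"))) + "\n"
        out.append((row.get("id", "fixture"), header,
                    bool(row.get("expect", True))))
    return out


def make_ddg_table(seed: int = 0, n: int = 12) -> str:
    """TSV ddG table spanning the hot-spot bands, kcal/mol."""
    rng = np.random.default_rng(seed)
    # fixed boundary rows first, then seeded filler
    rows = [("A", 10, "TRP", 2.40), ("A", 11, "LEU", 1.50),
            ("A", 12, "PHE", 1.49), ("A", 13, "SER", 0.50),
            ("A", 14, "GLY", 0.49), ("A", 15, "ASP", -0.30)]
    names = ["ALA", "VAL", "TYR", "LYS", "GLU", "ASN"]
    for k in range(max(0, n - len(rows))):
        rows.append(("B", 20 + k, names[k % len(names)],
                     float(np.round(rng.uniform(-1.0, 3.0), 2))))
    lines = ["chain\tresnum\tresname\tddg"]
    lines += [f"{c}\t{num}\t{name}\t{ddg:.2f}" for c, num, name, ddg in rows]
    return "\n".join(lines) + "\n"


def write_fixture(text: str, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text)
    return path
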