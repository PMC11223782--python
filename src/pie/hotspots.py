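"""Interface hot-spot labelling from per-residue ddG tables.

Free-energy changes on mutation (typically alanine scanning, kcal/mol)
are consumed from pre-computed tables; a residue whose mutation
destabilizes the complex by at least 1.5 kcal/mol is a critical hot
spot, 0.5 to 1.5 kcal/mol a warm hot spot, anything below (including
stabilizing, negative ddG) is unlabelled. The upper bound belongs to
the critical class, so the warm band is the half-open [0.5, 1.5).
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

CRITICAL_MIN = 1.5  # kcal/mol
WARM_MIN = 0.5      # kcal/mol


class HotspotLabel(enum.Enum):
    CRITICAL = "CRITICAL"
    WARM = "WARM"
    NONE = "NONE"


@dataclass
class HotspotRecord:
    chain_id: str
    res_num: int
    res_name: str
    ddg: float  # kcal/mol
    icode: str = ""
    label: Optional[HotspotLabel] = None


def classify_hotspot(ddg: float, critical_min: float = CRITICAL_MIN,
                     warm_min: float = WARM_MIN) -> HotspotLabel:
    """Label one ddG value; total function, no errors."""
    if warm_min >= critical_min:
        raise ValueError("warm_min must be below critical_min")
    if ddg >= critical_min:
        return HotspotLabel.CRITICAL
    if ddg >= warm_min:
        return HotspotLabel.WARM
    return HotspotLabel.NONE


# FoldX AlaScan lines look like: "LYS 23 to ALA energy change is 1.82"
_FOLDX_LINE = re.compile(
    r"^\s*(?P<resname>[A-Z]{2,4})\s+(?P<chain>[A-Za-z0-9]?)\s*"
    r"(?P<resnum>-?\d+)\s+to\s+ALA\s+energy\s+change\s+is\s+"
    r"(?P<ddg>-?\d+\.?\d*(?:[eE][+-]?\d+)?)\s*$")


def _parse_tsv_line(line: str, lineno: int) -> HotspotRecord:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < 4:
        parts = line.split()
    if len(parts) < 4:
        raise ValueError(f"line {lineno}: expected chain, resnum, resname, "
                         f"ddg columns")
    chain, resnum, resname, ddg = parts[:4]
    try:
        num = int(resnum)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad residue number "
                         f"{resnum!r}") from exc
    try:
        energy = float(ddg)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad ddG value {ddg!r}") from exc
    return HotspotRecord(chain_id=chain, res_num=num, res_name=resname,
                         ddg=energy)


def parse_ddg_table(path, dialect: str = "tsv") -> list[HotspotRecord]:
    """Read a per-residue ddG table (labels left unset).

    dialect 'tsv': columns chain, resnum, resname, ddg (header optional);
    dialect 'foldx_ala_scan': per-residue alanine-scan text lines.
    """
    lines = Path(path).read_text().splitlines()
    records: list[HotspotRecord] = []
    if dialect == "tsv":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            if lineno == 1 and line.lower().lstrip().startswith("chain"):
                continue  # header row
            records.append(_parse_tsv_line(line, lineno))
    elif dialect == "foldx_ala_scan":
        for lineno, line in enumerate(lines, start=1):
            if not line.strip():
                continue
            m = _FOLDX_LINE.match(line)
            if not m:
                raise ValueError(f"line {lineno}: unrecognized alanine-scan "
                                 f"line: {line!r}")
            records.append(HotspotRecord(
                chain_id=m.group("chain") or "",
                res_num=int(m.group("resnum")),
                res_name=m.group("resname"),
                ddg=float(m.group("ddg"))))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return records


def label_records(records: list[HotspotRecord],
                  critical_min: float = CRITICAL_MIN,
                  warm_min: float = WARM_MIN) -> list[HotspotRecord]:
    """Classify every record in place and return the list."""
    for rec in records:
        rec.label = classify_hotspot(rec.ddg, critical_min=critical_min,
                                     warm_min=warm_min)
    return records
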