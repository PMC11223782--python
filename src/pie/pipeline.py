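"""End-to-end orchestration: structures in, pocketome + reports out.

Stages per structure: quality filter -> HD/PL selection -> solvent and
heteroatom stripping -> interaction patch -> altloc check -> cavity
detection -> retention filter -> (PL) classification. Pooled stages:
descriptor table -> prune/standardize -> pairwise distances -> PSI ->
minimum spanning tree. Every filter records in = out + rejected counts
so the run report reconciles exactly; errors on one structure are
recorded and the run continues with the rest.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import pocketome as pocketome_mod
from . import similarity as similarity_mod
from .cavity import CavityParams, Pocket, PocketSource, detect_pockets
from .descriptors import descriptor_table
from .interface import interaction_patch
from .model import Structure
from .pocket_annotation import (PocketClass, classify_pl_pocket,
                                retain_pocket, superpose_shared_chain,
                                Superposition)
from .structure_io import (check_altloc_at_interface, parse_quality,
                           passes_quality, read_structure,
                           select_heterodimer, select_protein_ligand,
                           strip_structure, write_mol2)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline with their defaults."""

    cutoff: float = 6.0                  # interface patch, A
    cavity: CavityParams = field(default_factory=CavityParams)
    retain_contact: float = 1.0          # A
    retain_min_probes: int = 4
    overlap_cutoff: float = 1.0          # PLOC epitope clash, A
    min_heavy: int = 8
    min_nonzero_frac: float = 0.95
    ddof: int = 0
    resolution_xray_max: float = 3.5
    resolution_cryoem_max: float = 3.0
    rgap_max: float = 0.07
    fsc_max: float = 0.143
    out_dir: Optional[Path] = None
    write_pocket_mol2: bool = True

    KNOWN_KEYS = None  # filled after class creation

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        cavity_keys = {f.name for f in dataclasses.fields(CavityParams)}
        cfg_kwargs, cav_kwargs = {}, {}
        for key, value in data.items():
            if key in cavity_keys:
                cav_kwargs[key] = value
            elif key in known:
                cfg_kwargs[key] = value
            else:
                raise ValueError(f"unknown config key {key!r}")
        cfg = cls(**cfg_kwargs)
        if cav_kwargs:
            cfg.cavity = dataclasses.replace(cfg.cavity, **cav_kwargs)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        return d


@dataclass
class ManifestEntry:
    path: str
    mode: str                      # HD or PL
    structure_id: str = ""
    shared_accession: str = ""     # links a PL entry to its HD complex
    hd_id: str = ""                # structure_id of the associated HD entry
    family: str = ""


def read_manifest(path) -> list[ManifestEntry]:
    """TSV manifest: path, mode[, structure_id, shared_accession, hd_id,
    family]; '#' comments and blank lines ignored."""
    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if lineno == 1 and parts[0].lower() == "path":
            continue
        if len(parts) < 2:
            raise ValueError(f"manifest line {lineno}: need at least "
                             f"path and mode")
        parts += [""] * (6 - len(parts))
        entries.append(ManifestEntry(path=parts[0], mode=parts[1].upper(),
                                     structure_id=parts[2],
                                     shared_accession=parts[3],
                                     hd_id=parts[4], family=parts[5]))
    return entries


@dataclass
class RunReport:
    config: dict
    structures_in: int = 0
    rejected: list = field(default_factory=list)   # (id, stage, reason)
    errors: list = field(default_factory=list)
    structures_accepted: int = 0
    pockets_detected: int = 0
    pockets_retained: int = 0
    class_counts: dict = field(default_factory=dict)
    descriptor_columns_dropped: list = field(default_factory=list)
    n_pocketome_nodes: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _process_structure(entry: ManifestEntry, config: PipelineConfig,
                       report: RunReport):
    """One structure through quality -> selection -> patch -> pockets.

    Returns (structure, retained pockets, ligand-or-None, patch) or None
    when the structure is rejected (reason already recorded).
    """
    sid = entry.structure_id or Path(entry.path).stem

    quality = parse_quality(entry.path, structure_id=sid)
    ok, reason = passes_quality(
        quality, resolution_xray_max=config.resolution_xray_max,
        resolution_cryoem_max=config.resolution_cryoem_max,
        rgap_max=config.rgap_max, fsc_max=config.fsc_max)
    if not ok:
        report.rejected.append((sid, "quality", reason))
        return None

    raw = read_structure(entry.path)
    raw.id = sid
    if entry.mode == "HD":
        stripped = strip_structure(raw, "HD")
        sel = select_heterodimer(stripped)
        if not sel.accepted:
            report.rejected.append((sid, "selection", sel.reason))
            return None
        target, partner = sel.target_chain, sel.partner_chain
        patch = interaction_patch(list(target.atoms()),
                                  list(partner.atoms()),
                                  cutoff=config.cutoff)
        partner_atoms = patch.partner_atoms
        source = PocketSource.HD_ORTHOSTERIC
        facing = partner.chain_id
        ligand = None
    elif entry.mode == "PL":
        sel = select_protein_ligand(raw, min_heavy=config.min_heavy)
        if not sel.accepted:
            report.rejected.append((sid, "selection", sel.reason))
            return None
        stripped = strip_structure(raw, "PL", ligand=sel.ligand)
        target, ligand = sel.target_chain, sel.ligand
        target = stripped.get_chain(target.chain_id)
        patch = interaction_patch(list(target.atoms()), ligand.atoms,
                                  cutoff=config.cutoff)
        partner_atoms = patch.partner_atoms
        source = PocketSource.PL
        facing = ligand.name
    else:
        raise ValueError(f"manifest mode must be HD or PL, got {entry.mode!r}")

    if patch.is_empty:
        report.rejected.append((sid, "interface", "no interaction patch"))
        return None
    if check_altloc_at_interface(stripped, patch):
        report.rejected.append((sid, "altloc",
                                "alternative locations at interface"))
        return None

    pockets = detect_pockets(list(target.atoms()), patch.partner_atoms,
                             params=config.cavity, structure_id=sid,
                             source=source, facing=facing)
    report.pockets_detected += len(pockets)
    contact_atoms = ligand.atoms if ligand is not None else partner_atoms
    retained = [p for p in pockets
                if retain_pocket(p, contact_atoms,
                                 contact=config.retain_contact,
                                 min_contact_probes=config.retain_min_probes)]
    report.pockets_retained += len(retained)
    report.structures_accepted += 1
    return stripped, retained, ligand, patch


def run_pipeline(entries: list[ManifestEntry],
                 config: Optional[PipelineConfig] = None) -> dict:
    """Run the full pipeline over a manifest of structures.

    Returns a dict with the run report, the descriptor table, PSI matrix
    and pocketome tree (None where fewer than two pockets survive). When
    ``config.out_dir`` is set, per-stage artifacts are written there.
    """
    config = config or PipelineConfig()
    report = RunReport(config=config.echo(), structures_in=len(entries))
    logger.info("pipeline config: %s", json.dumps(config.echo()))

    per_structure = {}
    for entry in entries:
        sid = entry.structure_id or Path(entry.path).stem
        try:
            result = _process_structure(entry, config, report)
        except Exception as exc:  # keep going; record the failure
            logger.exception("structure %s failed", sid)
            report.errors.append((sid, str(exc)))
            continue
        if result is not None:
            per_structure[sid] = (entry, *result)

    # PL pocket classification against the associated HD complex
    classes: dict[str, str] = {}
    all_pockets: list[Pocket] = []
    for sid, (entry, stripped, retained, ligand, patch) in per_structure.items():
        for pocket in retained:
            all_pockets.append(pocket)
            if entry.mode == "HD":
                classes[pocket.pocket_id] = PocketClass.HD_ORTHOSTERIC.value
                continue
            label = PocketClass.UNASSIGNED
            hd = per_structure.get(entry.hd_id)
            if hd is not None and ligand is not None:
                hd_entry, hd_struct, hd_pockets, _, hd_patch = hd
                if hd_pockets and entry.shared_accession:
                    sup = superpose_shared_chain(stripped, hd_struct,
                                                 entry.shared_accession)
                    label, _ = classify_pl_pocket(
                        pocket, ligand, hd_pockets[0],
                        hd_patch.partner_atoms, sup,
                        overlap_cutoff=config.overlap_cutoff)
            else:
                label, _ = classify_pl_pocket(pocket, ligand, None, [])
            classes[pocket.pocket_id] = label.value
    for label in classes.values():
        report.class_counts[label] = report.class_counts.get(label, 0) + 1

    out = {"report": report, "pockets": all_pockets, "classes": classes,
           "descriptors": None, "psi": None, "distances": None, "tree": None}

    if len(all_pockets) >= 2:
        table = descriptor_table(all_pockets, params=config.cavity,
                                 classes=classes)
        psim, dm, dropped = similarity_mod.psi_pipeline(
            table, min_nonzero_frac=config.min_nonzero_frac, ddof=config.ddof)
        report.descriptor_columns_dropped = dropped
        meta = pd.DataFrame(
            {"family": {e.structure_id or Path(e.path).stem: e.family
                        for e in entries}})
        tree = pocketome_mod.minimum_spanning_tree(dm, psi_matrix=psim.psi)
        pocketome_mod.annotate_nodes(tree, table)
        report.n_pocketome_nodes = len(tree.nodes)
        out.update(descriptors=table, psi=psim, distances=dm, tree=tree)

    if config.out_dir is not None:
        _write_artifacts(out, config)
    return out


def _write_artifacts(result: dict, config: PipelineConfig) -> None:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: RunReport = result["report"]
    (out_dir / "run_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True))
    if config.write_pocket_mol2:
        pocket_dir = out_dir / "pockets"
        pocket_dir.mkdir(exist_ok=True)
        for pocket in result["pockets"]:
            safe = pocket.pocket_id.replace(":", "_").replace("/", "_")
            write_mol2(pocket, pocket_dir / f"{safe}.mol2")
    if result["descriptors"] is not None:
        result["descriptors"].to_csv(out_dir / "descriptors.csv",
                                     float_format="%.10g")
        result["psi"].to_frame().to_csv(out_dir / "psi.csv",
                                        float_format="%.10g")
        pocketome_mod.export_graph(result["tree"], "json",
                                   out_dir / "pocketome.json")
        pocketome_mod.export_graph(result["tree"], "graphml",
                                   out_dir / "pocketome.graphml")
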