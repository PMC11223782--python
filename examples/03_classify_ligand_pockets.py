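"""Classify a liganded pocket against its heterodimer reference.

Builds the HD and PL groove fixtures (which share chain A, accession
FIXA), superposes the monomer onto the heterodimer via the shared
chain, and decides whether the ligand occupies the orthosteric site
competitively (PLOC), non-competitively (PLONC), or binds an allosteric
pocket (PLA).
"""
from pathlib import Path

from pie import fixtures
from pie.cavity import PocketSource, detect_pockets
from pie.interface import interaction_patch
from pie.pocket_annotation import classify_pl_pocket, superpose_shared_chain
from pie.structure_io import (read_structure, select_heterodimer,
                              select_protein_ligand, strip_structure)

work = Path("scratch_example")
work.mkdir(exist_ok=True)
(work / "hd.pdb").write_text(fixtures.make_groove_complex(seed=1, mode="HD"))
(work / "pl.pdb").write_text(fixtures.make_groove_complex(seed=1, mode="PL"))

hd = strip_structure(read_structure(work / "hd.pdb"), "HD")
hd_sel = select_heterodimer(hd)
hd_patch = interaction_patch(list(hd_sel.target_chain.atoms()),
                             list(hd_sel.partner_chain.atoms()))
hd_pockets = detect_pockets(list(hd_sel.target_chain.atoms()),
                            hd_patch.partner_atoms, structure_id="hd",
                            facing="B")

pl_raw = read_structure(work / "pl.pdb")
pl_sel = select_protein_ligand(pl_raw)
pl = strip_structure(pl_raw, "PL", ligand=pl_sel.ligand)
pl_target = pl.get_chain("A")
pl_patch = interaction_patch(list(pl_target.atoms()), pl_sel.ligand.atoms)
pl_pockets = detect_pockets(list(pl_target.atoms()), pl_patch.partner_atoms,
                            structure_id="pl", source=PocketSource.PL,
                            facing="LIG")

sup = superpose_shared_chain(pl, hd, "FIXA")
print(f"shared-chain superposition: {sup.n_pairs} CA pairs, "
      f"rmsd {sup.rmsd:.3f} A")

label, details = classify_pl_pocket(pl_pockets[0], pl_sel.ligand,
                                    hd_pockets[0], hd_patch.partner_atoms,
                                    sup)
print(f"ligand contacts {details['k']} heterodimer-pocket probes (<= 1 A); "
      f"min ligand-epitope distance {details['min_epitope_dist']:.2f} A")
print(f"class: {label.value}")
print("\nPLOC means the ligand sits in the orthosteric pocket AND clashes "
      "with the protein partner's epitope; k >= 4 makes it orthosteric.")
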