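"""Shared fixtures: synthetic structures and detected pockets.

Structure-level fixtures are session-scoped because cavity detection is
the slow step; tests must not mutate them.
"""
from __future__ import annotations

import numpy as np
import pytest

from pie import fixtures as fx
from pie.cavity import PocketSource, detect_pockets
from pie.interface import interaction_patch
from pie.model import Atom, Chain, Residue, Structure
from pie.structure_io import (read_structure, select_heterodimer,
                              select_protein_ligand, strip_structure)


def make_atom(coords, name="CA", element="C", altloc="", serial=1,
              chain_id="A", res_name="ALA", res_seqid=1):
    return Atom(name=name, element=element, coords=np.asarray(coords, float),
                altloc=altloc, serial=serial, chain_id=chain_id,
                res_name=res_name, res_seqid=res_seqid)


def chain_from_ca(coords, chain_id="A", accession="ACC1"):
    """Polymer chain with one CA-only glycine per coordinate."""
    chain = Chain(chain_id=chain_id, entity_accession=accession,
                  is_polymer=True)
    for i, xyz in enumerate(coords, start=1):
        res = Residue(name="GLY", seqid=i)
        res.atoms.append(make_atom(xyz, name="CA", serial=i,
                                   chain_id=chain_id, res_name="GLY",
                                   res_seqid=i))
        chain.residues.append(res)
    return chain


@pytest.fixture(scope="session")
def hd_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fix") / "hd.pdb"
    path.write_text(fx.make_groove_complex(seed=1, mode="HD", n_waters=3,
                                           with_ion=True))
    return path


@pytest.fixture(scope="session")
def pl_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fix") / "pl.pdb"
    path.write_text(fx.make_groove_complex(seed=1, mode="PL", n_waters=2))
    return path


@pytest.fixture(scope="session")
def flat_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("fix") / "flat.pdb"
    path.write_text(fx.make_flat_chain())
    return path


@pytest.fixture(scope="session")
def hd_structure(hd_pdb):
    return read_structure(hd_pdb)


@pytest.fixture(scope="session")
def pl_structure(pl_pdb):
    return read_structure(pl_pdb)


@pytest.fixture(scope="session")
def hd_context(hd_structure):
    """(stripped structure, target chain, partner chain, patch)."""
    stripped = strip_structure(hd_structure, "HD")
    sel = select_heterodimer(stripped)
    assert sel.accepted, sel.reason
    patch = interaction_patch(list(sel.target_chain.atoms()),
                              list(sel.partner_chain.atoms()))
    return stripped, sel.target_chain, sel.partner_chain, patch


@pytest.fixture(scope="session")
def hd_pockets(hd_context):
    stripped, target, partner, patch = hd_context
    return detect_pockets(list(target.atoms()), patch.partner_atoms,
                          structure_id="hd", facing=partner.chain_id)


@pytest.fixture(scope="session")
def groove_pocket(hd_pockets):
    assert hd_pockets, "groove fixture must yield at least one pocket"
    return hd_pockets[0]


@pytest.fixture(scope="session")
def pl_context(pl_structure):
    """(stripped structure, target chain, ligand, patch)."""
    sel = select_protein_ligand(pl_structure)
    assert sel.accepted, sel.reason
    stripped = strip_structure(pl_structure, "PL", ligand=sel.ligand)
    target = stripped.get_chain(sel.target_chain.chain_id)
    patch = interaction_patch(list(target.atoms()), sel.ligand.atoms)
    return stripped, target, sel.ligand, patch


@pytest.fixture(scope="session")
def pl_pockets(pl_context):
    stripped, target, ligand, patch = pl_context
    return detect_pockets(list(target.atoms()), patch.partner_atoms,
                          structure_id="pl", source=PocketSource.PL,
                          facing=ligand.name)
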