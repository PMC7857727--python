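"""PDB input/output for bead models, via gemmi.

Rigid bodies are read with a C-alpha-only reduction (one bead per residue,
weight 1.0); every CA becomes an addressable anchor named
``chain:resnum:CA``.  Realized models are written back as CA-only chains,
one chain per protomer, with anchor names recorded in REMARK records.
"""

from __future__ import annotations

import string

import gemmi
import numpy as np

from .rigid_body import RigidBodySpec
from .scattering_calc import BeadModel

__all__ = ["read_body", "write_model"]


def read_body(path, body_id: str | None = None) -> RigidBodySpec:
    """Read a PDB/mmCIF file as one rigid body (CA beads only)."""
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    coords = []
    anchors = {}
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.name != "CA":
                    continue
                anchors[f"{chain.name}:{residue.seqid.num}:CA"] = len(coords)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"{path}: no CA atoms found")
    return RigidBodySpec(body_id or str(path), np.asarray(coords), anchors=anchors)


def write_model(path, model: BeadModel) -> None:
    """Write a bead model as a CA-only PDB, one chain per protomer."""
    st = gemmi.Structure()
    st.name = "ringfit"
    md = gemmi.Model("1")
    chains = string.ascii_uppercase
    index_to_anchor = {idx: name for name, idx in model.anchors.items()}
    remarks = []
    serial = 0
    for prot in np.unique(model.protomer_id):
        chain = gemmi.Chain(chains[int(prot) % len(chains)])
        sel = np.flatnonzero(model.protomer_id == prot)
        for resnum, i in enumerate(sel, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(resnum, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.occ = float(model.weight[i])
            atom.pos = gemmi.Position(*model.coordinates[i])
            serial += 1
            atom.serial = serial
            res.add_atom(atom)
            chain.add_residue(res)
            if int(i) in index_to_anchor:
                remarks.append(f"REMARK 300 ANCHOR {index_to_anchor[int(i)]} "
                               f"{chain.name}:{resnum}:CA")
        md.add_chain(chain)
    st.add_model(md)
    st.raw_remarks = remarks
    st.write_pdb(str(path))
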