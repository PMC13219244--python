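"""Shared fixtures: synthetic structures generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from c5conform.structure_io import Atom, Structure
from c5conform import synthetic_data as sd


def make_atom(serial, name, element, resnum, position, resname="GLY",
              chain="A", occupancy=1.0, altloc="", icode="", het=False):
    return Atom(serial=serial, name=name, element=element, altloc=altloc,
                residue_number=resnum, insertion_code=icode,
                residue_name=resname, chain_id=chain, occupancy=occupancy,
                position=np.asarray(position, float), het=het)


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue alpha helix with amide hydrogens."""
    return sd.make_ideal_peptide(12, -57.0, -47.0, protonate=True)


@pytest.fixture(scope="session")
def strand12():
    """Ideal 12-residue extended strand with amide hydrogens."""
    return sd.make_ideal_peptide(12, -120.0, 120.0, protonate=True)


@pytest.fixture(scope="session")
def toy_transforms():
    return [
        sd.DomainTransform(),
        sd.DomainTransform(axis=(0, 0, 1), angle_deg=20.0, translation=(3, 1, -2)),
        sd.DomainTransform(axis=(1, 1, 0), angle_deg=-35.0, translation=(0, 5, 0)),
    ]


@pytest.fixture(scope="session")
def toy_pair(toy_transforms):
    """Three-domain toy: (apo, perturbed, truth records, domain map)."""
    spec = sd.ToySpec(n_domains=3, residues_per_domain=15,
                      applied_transforms=toy_transforms, seed=3)
    return sd.make_multidomain_toy(spec)


PDB_FMT = ("{rec:<6}{serial:>5} {name:<4}{alt:1}{res:<3} {chain:1}"
           "{resnum:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
           "{occ:>6.2f}{b:>6.2f}          {el:>2}\n")


def pdb_line(serial, name, resname, chain, resnum, xyz, occ=1.0, alt="",
             el=None, het=False, icode=""):
    el = el or name[0]
    name4 = name if len(name) >= 4 else f" {name:<3}"
    return PDB_FMT.format(rec="HETATM" if het else "ATOM", serial=serial,
                          name=name4.strip().ljust(4) if len(name) >= 4 else name4,
                          alt=alt or " ", res=resname, chain=chain,
                          resnum=resnum, icode=icode or " ",
                          x=xyz[0], y=xyz[1], z=xyz[2], occ=occ, b=0.0, el=el)


@pytest.fixture()
def mini_pdb(tmp_path):
    """Hand-written 3-residue PDB file with a ligand and a second chain."""
    lines = []
    s = 1
    for i, resnum in enumerate((1, 2, 3)):
        for name, el, off in (("N", "N", 0.0), ("CA", "C", 1.4), ("C", "C", 2.4),
                              ("O", "O", 3.0)):
            lines.append(pdb_line(s, name, "ALA", "A", resnum,
                                  (3.8 * i + off, 0.0, 0.0), el=el))
            s += 1
    lines.append(pdb_line(s, "CA", "ALA", "B", 1, (0.0, 10.0, 0.0), el="C"))
    s += 1
    lines.append(pdb_line(s, "C1", "LIG", "C", 1, (0.0, 0.0, 10.0), el="C",
                          het=True))
    path = tmp_path / "mini.pdb"
    path.write_text("".join(lines) + "END\n")
    return path
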