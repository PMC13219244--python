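"""Backbone dihedrals, loop conformation classification and polar contacts.

The scissile loop of the C5a domain (Asp746–Met754) is disordered in free C5
but restructures into an α-helix under several modulators; this module
extracts φ/ψ for a residue window, classifies each residue on the
Ramachandran torus, calls the loop helical when enough consecutive residues
fall in the α region, and detects hydrogen bonds / salt bridges between two
residue groups with distance-only criteria (heavy-atom donors/acceptors, as
appropriate for structures without hydrogens).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from c5conform.structure_io import Atom, Structure

__all__ = [
    "DihedralRecord", "LoopClassification", "ContactRecord",
    "dihedral_angle", "backbone_dihedrals", "classify_rama",
    "loop_is_helical", "polar_contacts", "salt_bridges",
    "SCISSILE_LOOP",
]

#: Residue-number window of the C5a scissile loop (Asp746–Met754).
SCISSILE_LOOP = (746, 754)

# Ramachandran boxes: a rectangle around the canonical alpha-helical well and
# one around the broad beta/extended well (ψ wraps across ±180°).  Chosen to
# admit canonical helix (-57, -47) and strand (-120, 120) while excluding the
# left-handed helical region; the beta box is broad and includes polyproline.
ALPHA_BOX = ((-100.0, -30.0), (-80.0, -5.0))
BETA_PHI = (-180.0, -45.0)
BETA_PSI = ((90.0, 180.0), (-180.0, -150.0))

_DONOR_ACCEPTOR_ELEMENTS = {"N", "O", "S"}

#: Positively chargeable side-chain nitrogens (His included, generously).
BASIC_ATOMS = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
#: Carboxylate oxygens.
ACIDIC_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass
class DihedralRecord:
    residue_number: int
    phi: float | None
    psi: float | None

    def __post_init__(self) -> None:
        for v in (self.phi, self.psi):
            if v is not None and not (-180.0 < v <= 180.0):
                raise ValueError(f"dihedral {v} outside (-180, 180]")


@dataclass
class LoopClassification:
    residues: tuple[int, int]
    helical: bool
    helical_run_length: int
    unresolved: bool
    n_modelled: int = 0


@dataclass
class ContactRecord:
    kind: str  # "hbond" | "salt_bridge"
    atom_a: tuple[str, int, str]  # (chain, residue number, atom name)
    atom_b: tuple[str, int, str]
    distance: float


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                   p3: np.ndarray) -> float:
    """Signed torsion p0-p1-p2-p3 in degrees, IUPAC convention, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def _backbone_index(structure: Structure) -> dict[tuple[str, int], dict[str, np.ndarray]]:
    idx: dict[tuple[str, int], dict[str, np.ndarray]] = {}
    for a in structure.atoms:
        if a.insertion_code:
            continue
        if a.name in ("N", "CA", "C"):
            idx.setdefault((a.chain_id, a.residue_number), {})[a.name] = a.position
    return idx


def backbone_dihedrals(structure: Structure,
                       residue_range: tuple[int, int] = SCISSILE_LOOP,
                       chain_id: str | None = None) -> list[DihedralRecord]:
    """φ/ψ for each modelled residue in an inclusive residue-number window.

    φ needs the preceding residue's C and ψ the following residue's N (by
    consecutive author numbering within the same chain); at chain breaks the
    corresponding angle is ``None``.  Residues absent from the model, or
    missing any of N/CA/C, yield no record.
    """
    idx = _backbone_index(structure)
    lo, hi = residue_range
    records: list[DihedralRecord] = []
    chains = [chain_id] if chain_id else sorted({c for c, _ in idx})
    for ch in chains:
        for num in range(lo, hi + 1):
            res = idx.get((ch, num))
            if not res or not all(k in res for k in ("N", "CA", "C")):
                continue
            prev, nxt = idx.get((ch, num - 1)), idx.get((ch, num + 1))
            phi = psi = None
            if prev and "C" in prev:
                phi = dihedral_angle(prev["C"], res["N"], res["CA"], res["C"])
            if nxt and "N" in nxt:
                psi = dihedral_angle(res["N"], res["CA"], res["C"], nxt["N"])
            records.append(DihedralRecord(num, phi, psi))
    return records


def classify_rama(phi: float | None, psi: float | None) -> str:
    """Classify a (φ, ψ) pair as ``alpha``, ``beta`` or ``other``.

    Undefined angles classify as ``other``.  The two boxes are disjoint, so
    every defined pair receives exactly one region.
    """
    if phi is None or psi is None:
        return "other"
    (pl, ph_), (sl, sh) = ALPHA_BOX
    if pl <= phi <= ph_ and sl <= psi <= sh:
        return "alpha"
    if BETA_PHI[0] <= phi <= BETA_PHI[1] and any(
            lo <= psi <= hi for lo, hi in BETA_PSI):
        return "beta"
    return "other"


def loop_is_helical(records: Sequence[DihedralRecord], min_run: int = 4,
                    residues: tuple[int, int] = SCISSILE_LOOP) -> LoopClassification:
    """Call a loop helical when ≥ ``min_run`` consecutive residues are alpha.

    Consecutive means consecutive residue numbers, so unmodelled residues
    break a run.  Fewer than ``min_run`` modelled residues set
    ``unresolved``.
    """
    by_num = {r.residue_number: classify_rama(r.phi, r.psi) for r in records}
    best = run = 0
    prev_num = None
    for num in sorted(by_num):
        if by_num[num] == "alpha":
            run = run + 1 if prev_num == num - 1 else 1
        else:
            run = 0
        best = max(best, run)
        prev_num = num
    unresolved = len(by_num) < min_run
    return LoopClassification(residues=residues,
                              helical=(best >= min_run and not unresolved),
                              helical_run_length=best,
                              unresolved=unresolved,
                              n_modelled=len(by_num))


def _select(structure: Structure, group: Iterable[int] | Iterable[tuple[str, int]]) -> list[Atom]:
    group = list(group)
    if group and isinstance(group[0], tuple):
        keys = set(group)
        return [a for a in structure.atoms if (a.chain_id, a.residue_number) in keys]
    nums = set(group)
    return [a for a in structure.atoms if a.residue_number in nums]


def _cross_pairs(atoms_a: list[Atom], atoms_b: list[Atom], d_max: float):
    if not atoms_a or not atoms_b:
        return
    tree = cKDTree(np.array([a.position for a in atoms_b]))
    for a in atoms_a:
        for j in tree.query_ball_point(a.position, d_max):
            b = atoms_b[j]
            if a.residue_id == b.residue_id:
                continue
            yield a, b, float(np.linalg.norm(a.position - b.position))


def polar_contacts(structure: Structure, group_a: Iterable, group_b: Iterable,
                   d_max: float = 3.5) -> list[ContactRecord]:
    """Distance-only hydrogen-bond candidates between two residue groups.

    Pairs of N/O/S heavy atoms across the groups within ``d_max`` Å (the
    usual viewer default of 3.5 Å).  No angular criterion is applied since
    deposited structures typically lack hydrogens.  Groups are residue
    numbers or (chain, residue number) pairs and must be disjoint.
    """
    atoms_a = [a for a in _select(structure, group_a)
               if a.element.upper() in _DONOR_ACCEPTOR_ELEMENTS]
    atoms_b = [a for a in _select(structure, group_b)
               if a.element.upper() in _DONOR_ACCEPTOR_ELEMENTS]
    if {a.residue_id for a in atoms_a} & {b.residue_id for b in atoms_b}:
        raise ValueError("residue groups must be disjoint")
    out = []
    for a, b, d in _cross_pairs(atoms_a, atoms_b, d_max):
        out.append(ContactRecord("hbond",
                                 (a.chain_id, a.residue_number, a.name),
                                 (b.chain_id, b.residue_number, b.name), d))
    out.sort(key=lambda r: (r.atom_a, r.atom_b))
    return out


def salt_bridges(structure: Structure, group_a: Iterable, group_b: Iterable,
                 d_max: float = 4.0) -> list[ContactRecord]:
    """Salt bridges between two residue groups (either direction).

    Pairs of side-chain charged-group atoms — Arg NH1/NH2/NE, Lys NZ,
    His ND1/NE2 against Asp OD1/OD2, Glu OE1/OE2 — within ``d_max`` Å.
    His is counted as potentially charged (generous default).
    """
    def split(atoms: list[Atom]) -> tuple[list[Atom], list[Atom]]:
        basic = [a for a in atoms if a.name in BASIC_ATOMS.get(a.residue_name, ())]
        acidic = [a for a in atoms if a.name in ACIDIC_ATOMS.get(a.residue_name, ())]
        return basic, acidic

    sel_a, sel_b = _select(structure, group_a), _select(structure, group_b)
    basic_a, acidic_a = split(sel_a)
    basic_b, acidic_b = split(sel_b)
    out = []
    for pos, neg in ((basic_a, acidic_b), (basic_b, acidic_a)):
        for a, b, d in _cross_pairs(pos, neg, d_max):
            out.append(ContactRecord("salt_bridge",
                                     (a.chain_id, a.residue_number, a.name),
                                     (b.chain_id, b.residue_number, b.name), d))
    out.sort(key=lambda r: (r.atom_a, r.atom_b))
    return out
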