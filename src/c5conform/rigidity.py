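"""Constraint networks and body-bar pebble-game rigid cluster decomposition.

Protein flexibility is modelled combinatorially: every atom is a rigid body
with six degrees of freedom, and interactions become "bars" removing relative
freedoms between body pairs —

- 6 bars for locked dihedrals (peptide bonds and sp2 partial double bonds:
  carboxylate, amide, guanidinium, aromatic rings, carbonyls),
- 5 bars for rotatable covalent bonds and for hydrogen bonds,
- 2 bars for hydrophobic tethers.

Hydrogen bonds carry a Mayo-style energy (V0 = 8 kcal/mol, d0 = 2.8 Å, with
a hybridisation-dependent angular factor); diluting the network by removing
bonds weaker than a series of cut-offs (−0.5 … −2.0 kcal/mol) and
re-decomposing shows which regions depend on weak bonds.  Salt bridges are
treated as strong and survive every cut-off (a flag disables this).

The (6,6) pebble game decides, bar by bar, whether a constraint is
independent (it removes a degree of freedom) or redundant, and partitions the
bodies into rigid clusters — maximal sets with no internal relative motion.
Its correctness is checked elsewhere against the rank of the body-bar
rigidity matrix on random generic frameworks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from c5conform.loop_geometry import ACIDIC_ATOMS, BASIC_ATOMS
from c5conform.structure_io import Atom, DomainMap, Structure

__all__ = [
    "HBond", "Bond", "ConstraintNetwork", "RigidClusterDecomposition",
    "DomainRigidityTable", "place_backbone_hydrogens", "detect_covalent",
    "classify_bond_bars", "mayo_energy", "find_hbonds",
    "find_hydrophobic_tethers", "build_network", "pebble_game",
    "dilution_series", "domain_rigidity", "DILUTION_CUTOFFS",
]

#: Hydrogen-bond energy dilution series (kcal/mol), least to most stringent.
DILUTION_CUTOFFS: tuple[float, ...] = (-0.5, -1.0, -1.5, -2.0)

#: Energy assigned to salt bridges identified without explicit hydrogens.
SALT_BRIDGE_ENERGY = -10.0

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
                   "P": 1.07, "SE": 1.20}
_VDW_RADII = {"C": 1.70, "S": 1.80}

# Side-chain bond templates for the 20 standard residues (backbone bonds
# N-CA, CA-C, C-O[, C-OXT] are implicit).
_SIDECHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "GLY": (),
    "ALA": (("CA", "CB"),),
    "SER": (("CA", "CB"), ("CB", "OG")),
    "CYS": (("CA", "CB"), ("CB", "SG")),
    "VAL": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")),
    "THR": (("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")),
    "ILE": (("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "MET": (("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PRO": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "PHE": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")),
    "TYR": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")),
    "TRP": (("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")),
    "ASP": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "ASN": (("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "GLU": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")),
    "GLN": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")),
    "LYS": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")),
    "ARG": (("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")),
    "HIS": (("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")),
}

# sp2 / partial-double bonds within a residue (locked, 6 bars).
_LOCKED_SIDECHAIN: dict[str, frozenset[frozenset[str]]] = {
    "ASP": frozenset({frozenset(p) for p in (("CG", "OD1"), ("CG", "OD2"))}),
    "GLU": frozenset({frozenset(p) for p in (("CD", "OE1"), ("CD", "OE2"))}),
    "ASN": frozenset({frozenset(p) for p in (("CG", "OD1"), ("CG", "ND2"))}),
    "GLN": frozenset({frozenset(p) for p in (("CD", "OE1"), ("CD", "NE2"))}),
    "ARG": frozenset({frozenset(p) for p in (("NE", "CZ"), ("CZ", "NH1"),
                                             ("CZ", "NH2"))}),
    "HIS": frozenset({frozenset(p) for p in (("CG", "ND1"), ("CG", "CD2"),
                                             ("ND1", "CE1"), ("CD2", "NE2"),
                                             ("CE1", "NE2"))}),
    "PHE": frozenset({frozenset(p) for p in (("CG", "CD1"), ("CG", "CD2"),
                                             ("CD1", "CE1"), ("CD2", "CE2"),
                                             ("CE1", "CZ"), ("CE2", "CZ"))}),
    "TYR": frozenset({frozenset(p) for p in (("CG", "CD1"), ("CG", "CD2"),
                                             ("CD1", "CE1"), ("CD2", "CE2"),
                                             ("CE1", "CZ"), ("CE2", "CZ"))}),
    "TRP": frozenset({frozenset(p) for p in (("CG", "CD1"), ("CG", "CD2"),
                                             ("CD1", "NE1"), ("NE1", "CE2"),
                                             ("CD2", "CE2"), ("CD2", "CE3"),
                                             ("CE2", "CZ2"), ("CE3", "CZ3"),
                                             ("CZ2", "CH2"), ("CZ3", "CH2"))}),
}

#: Side-chain nitrogens whose donor geometry is sp3.
_SP3_DONOR_NAMES = {"NZ"}
#: Oxygens with sp3 (hydroxyl/ether) acceptor geometry.
_SP3_ACCEPTOR_NAMES = {"OG", "OG1", "OH"}


@dataclass
class Bond:
    """Covalent bond between atoms ``i`` and ``j`` (indices into the atom list)."""
    i: int
    j: int
    kind: str  # template | peptide | disulfide | hydrogen | fallback


@dataclass
class HBond:
    """Hydrogen bond (or salt bridge) with Mayo geometry.

    Angles in degrees: ``theta`` is donor–H···acceptor, ``phi`` is
    H···acceptor–base (180° when the acceptor has no base or no explicit H
    exists).  ``energy`` ≤ 0 for retained bonds.
    """

    donor_heavy: int
    hydrogen: int | None
    acceptor: int
    acceptor_base: int | None
    distance_DA: float
    distance_HA: float
    theta: float
    phi: float
    donor_sp2: bool = True
    acceptor_sp2: bool = True
    energy: float = 0.0
    is_salt_bridge: bool = False


@dataclass
class _Edge:
    i: int
    j: int
    bars: int
    kind: str  # covalent_locked | covalent_rotatable | hbond | hydrophobic
    energy: float | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-edge in constraint network")
        if not (1 <= self.bars <= 6):
            raise ValueError(f"bars must be in [1, 6], got {self.bars}")


@dataclass
class ConstraintNetwork:
    """Bodies (atoms, 6 DOF each) joined by integer-bar constraints."""

    n_bodies: int
    edges: list[_Edge] = field(default_factory=list)
    positions: np.ndarray | None = None  # generic embedding, for oracles

    def add_edge(self, i: int, j: int, bars: int, kind: str,
                 energy: float | None = None) -> None:
        if not (0 <= i < self.n_bodies and 0 <= j < self.n_bodies):
            raise ValueError("edge endpoint out of range")
        a, b = (i, j) if i < j else (j, i)
        if any(e.i == a and e.j == b and e.kind == kind for e in self.edges):
            return  # duplicate (i, j, kind)
        self.edges.append(_Edge(a, b, bars, kind, energy))

    def edge_keys(self) -> set[tuple[int, int, str]]:
        return {(e.i, e.j, e.kind) for e in self.edges}


Edge = _Edge


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters, largest first.

    ``clusters`` holds only multi-body clusters; bodies in none of them are
    flexible singletons.  Ranking is by size (descending), ties broken by
    the smallest member index.
    """

    cutoff: float | None
    n_bodies: int
    clusters: list[frozenset[int]]
    n_independent: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for c in self.clusters:
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c

    @property
    def cluster_of(self) -> dict[int, int]:
        """Body index -> 1-based cluster rank (absent = flexible)."""
        out: dict[int, int] = {}
        for rank, c in enumerate(self.clusters, start=1):
            for i in c:
                out[i] = rank
        return out

    @property
    def flexible(self) -> frozenset[int]:
        assigned = {i for c in self.clusters for i in c}
        return frozenset(range(self.n_bodies)) - assigned

    def largest_size(self) -> int:
        return len(self.clusters[0]) if self.clusters else 1


@dataclass
class DomainRigidityTable:
    """Per-(domain, cutoff) rigidity percentages and colour classes."""

    rows: list[tuple[str, float | None, float, str]] = field(default_factory=list)

    def add(self, domain: str, cutoff: float | None, percent: float) -> None:
        if not (0.0 <= percent <= 100.0):
            raise ValueError("percentage outside [0, 100]")
        self.rows.append((domain, cutoff, percent, colour_class(percent)))

    def percent(self, domain: str, cutoff: float | None) -> float:
        for d, c, p, _ in self.rows:
            if d == domain and c == cutoff:
                return p
        raise KeyError((domain, cutoff))


def colour_class(percent: float) -> str:
    """0% -> grey, 1–49% -> light_blue, >=50% -> purple."""
    if percent <= 0.0:
        return "grey"
    return "light_blue" if percent < 50.0 else "purple"


# ---------------------------------------------------------------------------
# Protonation and covalent topology


def place_backbone_hydrogens(structure: Structure) -> Structure:
    """Add idealised amide hydrogens (N–H = 1.01 Å, anti to the preceding
    carbonyl, in the peptide plane).

    Prolines and chain-start residues get no H; pre-existing hydrogens are
    left untouched (idempotent).  Side-chain protons are out of scope — a
    stated fidelity limit for side-chain hydrogen bonds.
    """
    res_atoms: dict[tuple[str, int, str], dict[str, Atom]] = {}
    for a in structure.atoms:
        res_atoms.setdefault(a.residue_id, {})[a.name] = a

    out_atoms: list[Atom] = []
    for a in structure.atoms:
        out_atoms.append(replace(a, position=a.position.copy()))
        if a.name != "N":
            continue
        res = res_atoms[a.residue_id]
        if a.residue_name == "PRO":
            continue
        if any(n in res for n in ("H", "HN", "H1")):
            continue
        prev = res_atoms.get((a.chain_id, a.residue_number - 1, ""))
        if not prev or "C" not in prev:
            continue
        c_prev = prev["C"].position
        if np.linalg.norm(a.position - c_prev) > 1.9:  # chain break
            continue
        if "O" in prev:
            direction = c_prev - prev["O"].position
        elif "CA" in res:  # no carbonyl O: bisector fallback
            direction = ((a.position - c_prev) / np.linalg.norm(a.position - c_prev)
                         + (a.position - res["CA"].position)
                         / np.linalg.norm(a.position - res["CA"].position))
        else:
            continue
        direction = direction / np.linalg.norm(direction)
        out_atoms.append(Atom(
            serial=0, name="H", element="H", altloc="",
            residue_number=a.residue_number, insertion_code=a.insertion_code,
            residue_name=a.residue_name, chain_id=a.chain_id, occupancy=1.0,
            position=a.position + 1.01 * direction))
    for k, a in enumerate(out_atoms, start=1):
        a.serial = k
    return Structure(out_atoms, structure.id)


def detect_covalent(structure: Structure) -> list[Bond]:
    """Covalent bond list from residue templates plus geometric rules.

    Template bonds for the 20 standard residues; peptide bonds C(i)–N(i+1)
    below 1.7 Å; disulfides SG–SG below 2.3 Å; hydrogens attach to the
    nearest heavy atom of their residue within 1.35 Å; atoms not covered by
    a template fall back to a distance rule (sum of covalent radii + 0.6 Å,
    within the residue or to an adjacent residue).
    """
    atoms = structure.atoms
    index_of = {id(a): k for k, a in enumerate(atoms)}
    by_res: dict[tuple[str, int, str], list[Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_id, []).append(a)

    bonds: list[Bond] = []
    seen: set[tuple[int, int]] = set()

    def add(i: int, j: int, kind: str) -> None:
        key = (min(i, j), max(i, j))
        if i != j and key not in seen:
            seen.add(key)
            bonds.append(Bond(key[0], key[1], kind))

    templated: set[int] = set()
    for rid, ratoms in by_res.items():
        names = {a.name: index_of[id(a)] for a in ratoms if a.element != "H"}
        resname = ratoms[0].residue_name
        template = _SIDECHAIN_BONDS.get(resname)
        pairs = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
        if template is not None:
            pairs += [p for p in template if p != ("CD", "N")]  # PRO ring below
            for a in ratoms:
                if a.element != "H":
                    templated.add(index_of[id(a)])
        for n1, n2 in pairs:
            if n1 in names and n2 in names:
                add(names[n1], names[n2], "template")
        if resname == "PRO" and "CD" in names and "N" in names:
            add(names["CD"], names["N"], "template")
        # hydrogens -> nearest heavy atom of the same residue
        for a in ratoms:
            if a.element != "H":
                continue
            heavy = [b for b in ratoms if b.element != "H"]
            if not heavy:
                continue
            nearest = min(heavy, key=lambda b: np.linalg.norm(b.position - a.position))
            if np.linalg.norm(nearest.position - a.position) <= 1.35:
                add(index_of[id(a)], index_of[id(nearest)], "hydrogen")

    # peptide bonds between consecutive residues of a chain
    c_atoms = {(a.chain_id, a.residue_number): index_of[id(a)]
               for a in atoms if a.name == "C" and not a.insertion_code}
    for a in atoms:
        if a.name != "N" or a.insertion_code:
            continue
        prev = c_atoms.get((a.chain_id, a.residue_number - 1))
        if prev is not None and np.linalg.norm(
                atoms[prev].position - a.position) < 1.7:
            add(prev, index_of[id(a)], "peptide")

    # disulfides
    sg = [k for k, a in enumerate(atoms) if a.name == "SG"]
    for x in range(len(sg)):
        for y in range(x + 1, len(sg)):
            i, j = sg[x], sg[y]
            if np.linalg.norm(atoms[i].position - atoms[j].position) < 2.3:
                add(i, j, "disulfide")

    # distance fallback for non-template atoms (e.g. ligands)
    loose = [k for k, a in enumerate(atoms)
             if k not in templated and a.element != "H"]
    if loose:
        pos = np.array([atoms[k].position for k in loose])
        tree = cKDTree(pos)
        for x, k in enumerate(loose):
            rk = _COVALENT_RADII.get(atoms[k].element.upper(), 0.9)
            for y in tree.query_ball_point(pos[x], rk + 1.2 + 0.6):
                if y <= x:
                    continue
                m = loose[y]
                rm = _COVALENT_RADII.get(atoms[m].element.upper(), 0.9)
                if np.linalg.norm(atoms[k].position - atoms[m].position) < rk + rm + 0.6:
                    add(k, m, "fallback")

    bonds.sort(key=lambda b: (b.i, b.j))
    return bonds


def classify_bond_bars(bond: Bond, structure: Structure) -> int:
    """6 bars for non-rotatable (locked) bonds, 5 for rotatable ones.

    Locked: peptide bonds, carbonyl C–O / C–OXT, and the sp2 template bonds
    of Asp/Glu/Asn/Gln/Arg/His and the aromatic rings.
    """
    if bond.kind == "peptide":
        return 6
    a, b = structure.atoms[bond.i], structure.atoms[bond.j]
    if bond.kind == "template" and a.residue_id == b.residue_id:
        pair = frozenset((a.name, b.name))
        if pair in (frozenset(("C", "O")), frozenset(("C", "OXT"))):
            return 6
        if pair in _LOCKED_SIDECHAIN.get(a.residue_name, frozenset()):
            return 6
    return 5


# ---------------------------------------------------------------------------
# Hydrogen bonds, salt bridges, tethers


def mayo_energy(hbond: HBond, v0: float = 8.0, d0: float = 2.8) -> float:
    """Mayo-style hydrogen-bond energy (kcal/mol).

    ``E = v0 * [5 (d0/d)^12 - 6 (d0/d)^10] * F(theta, phi)`` with d the
    donor–acceptor distance and F a hybridisation-dependent angular factor
    in [0, 1] that equals 1 at ideal linear geometry (theta = phi = 180°).
    At d = d0 and F = 1 the energy is exactly ``-v0``.
    """
    if hbond.hydrogen is None and not hbond.is_salt_bridge:
        raise ValueError("hydrogen missing: protonate the structure first")
    d = hbond.distance_DA
    if d <= 0:
        raise ValueError("non-positive donor-acceptor distance")
    x = d0 / d
    radial = 5.0 * x ** 12 - 6.0 * x ** 10
    theta = math.radians(hbond.theta)
    if theta < math.pi / 2:
        return 0.0
    base = math.cos(theta) ** 2 * math.exp(-((math.pi - theta) ** 6))
    phi = math.radians(hbond.phi)
    if not hbond.donor_sp2 and not hbond.acceptor_sp2:
        angular = base * math.cos(phi - math.radians(109.5)) ** 2
    else:
        angular = base * math.cos(phi) ** 2
    angular = min(max(angular, 0.0), 1.0)
    return v0 * radial * angular


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _neighbour_map(n: int, bonds: Sequence[Bond]) -> list[set[int]]:
    nbr: list[set[int]] = [set() for _ in range(n)]
    for b in bonds:
        nbr[b.i].add(b.j)
        nbr[b.j].add(b.i)
    return nbr


def find_hbonds(structure: Structure, cutoff: float = DILUTION_CUTOFFS[0],
                covalent: Sequence[Bond] | None = None, *,
                d_max: float = 3.6, theta_min: float = 100.0,
                keep_salt_bridges: bool = True,
                salt_bridge_d_max: float = 4.0) -> list[HBond]:
    """Geometric hydrogen-bond search with Mayo energies.

    Candidates are donor–H pairs against O/S (and bare N) acceptors with
    donor–acceptor distance ≤ ``d_max`` and D–H···A angle ≥ ``theta_min``;
    each is scored with :func:`mayo_energy` and retained iff the energy is
    at or below ``cutoff``.  Salt bridges (basic side-chain N against
    carboxylate O within ``salt_bridge_d_max``) are additionally identified
    from heavy atoms alone, assigned a strong fixed energy, and — being
    strong interactions — retained at every cut-off unless
    ``keep_salt_bridges`` is disabled.
    """
    atoms = structure.atoms
    bonds = covalent if covalent is not None else detect_covalent(structure)
    nbr = _neighbour_map(len(atoms), bonds)

    donors = []  # (heavy index, hydrogen index)
    for k, a in enumerate(atoms):
        if a.element.upper() != "H":
            continue
        heavies = [j for j in nbr[k] if atoms[j].element.upper() != "H"]
        if heavies and atoms[heavies[0]].element.upper() in ("N", "O", "S"):
            donors.append((heavies[0], k))

    acceptor_idx = []
    for k, a in enumerate(atoms):
        el = a.element.upper()
        if el in ("O", "S"):
            acceptor_idx.append(k)
        elif el == "N" and not any(atoms[j].element.upper() == "H" for j in nbr[k]):
            acceptor_idx.append(k)
    if not acceptor_idx:
        return []
    tree = cKDTree(np.array([atoms[k].position for k in acceptor_idx]))

    out: list[HBond] = []
    seen_pairs: set[tuple[int, int]] = set()
    for d_idx, h_idx in donors:
        dpos, hpos = atoms[d_idx].position, atoms[h_idx].position
        for hit in tree.query_ball_point(dpos, d_max):
            a_idx = acceptor_idx[hit]
            if a_idx in (d_idx, h_idx) or a_idx in nbr[d_idx] or a_idx in nbr[h_idx]:
                continue
            if nbr[a_idx] & nbr[d_idx]:  # 1-3 pair
                continue
            apos = atoms[a_idx].position
            d_da = float(np.linalg.norm(apos - dpos))
            theta = _angle_deg(dpos, hpos, apos)
            if theta < theta_min:
                continue
            base = next((j for j in sorted(nbr[a_idx])
                         if atoms[j].element.upper() != "H"), None)
            phi = (_angle_deg(hpos, apos, atoms[base].position)
                   if base is not None else 180.0)
            hb = HBond(
                donor_heavy=d_idx, hydrogen=h_idx, acceptor=a_idx,
                acceptor_base=base, distance_DA=d_da,
                distance_HA=float(np.linalg.norm(apos - hpos)),
                theta=theta, phi=phi,
                donor_sp2=atoms[d_idx].name not in _SP3_DONOR_NAMES,
                acceptor_sp2=atoms[a_idx].name not in _SP3_ACCEPTOR_NAMES,
                is_salt_bridge=_is_salt_bridge_pair(atoms[d_idx], atoms[a_idx]))
            hb.energy = mayo_energy(hb)
            if hb.energy <= cutoff or (keep_salt_bridges and hb.is_salt_bridge):
                out.append(hb)
                seen_pairs.add((d_idx, a_idx))

    if keep_salt_bridges:
        out.extend(_heavy_salt_bridges(structure, seen_pairs, salt_bridge_d_max))
    out.sort(key=lambda h: (h.donor_heavy, h.acceptor))
    return out


def _is_salt_bridge_pair(donor: Atom, acceptor: Atom) -> bool:
    return (donor.name in BASIC_ATOMS.get(donor.residue_name, ())
            and acceptor.name in ACIDIC_ATOMS.get(acceptor.residue_name, ()))


def _heavy_salt_bridges(structure: Structure, seen: set[tuple[int, int]],
                        d_max: float) -> list[HBond]:
    """Salt bridges from heavy atoms alone (no explicit H required)."""
    atoms = structure.atoms
    basic = [k for k, a in enumerate(atoms)
             if a.name in BASIC_ATOMS.get(a.residue_name, ())]
    acidic = [k for k, a in enumerate(atoms)
              if a.name in ACIDIC_ATOMS.get(a.residue_name, ())]
    out = []
    for i in basic:
        for j in acidic:
            if (i, j) in seen or atoms[i].residue_id == atoms[j].residue_id:
                continue
            d = float(np.linalg.norm(atoms[i].position - atoms[j].position))
            if d <= d_max:
                out.append(HBond(
                    donor_heavy=i, hydrogen=None, acceptor=j,
                    acceptor_base=None, distance_DA=d, distance_HA=d,
                    theta=180.0, phi=180.0, energy=SALT_BRIDGE_ENERGY,
                    is_salt_bridge=True))
    return out


def find_hydrophobic_tethers(structure: Structure,
                             covalent: Sequence[Bond] | None = None,
                             gap: float = 0.25) -> list[tuple[int, int]]:
    """Contacting apolar side-chain atom pairs (C–C, C–S, S–S).

    An atom is apolar when it is a side-chain carbon or sulfur whose
    covalent neighbours are all C, S or H.  Pairs closer than the sum of
    van der Waals radii plus ``gap`` become 2-bar tethers, excluding
    covalently bonded and 1-3 pairs.
    """
    atoms = structure.atoms
    bonds = covalent if covalent is not None else detect_covalent(structure)
    nbr = _neighbour_map(len(atoms), bonds)
    apolar = []
    for k, a in enumerate(atoms):
        el = a.element.upper()
        if el not in ("C", "S") or a.name in _BACKBONE_NAMES:
            continue
        if all(atoms[j].element.upper() in ("C", "S", "H") for j in nbr[k]):
            apolar.append(k)
    if len(apolar) < 2:
        return []
    pos = np.array([atoms[k].position for k in apolar])
    tree = cKDTree(pos)
    rmax = max(_VDW_RADII.values()) * 2 + gap
    out = []
    for x in range(len(apolar)):
        i = apolar[x]
        ri = _VDW_RADII[atoms[i].element.upper()]
        for y in tree.query_ball_point(pos[x], rmax):
            if y <= x:
                continue
            j = apolar[y]
            if j in nbr[i] or (nbr[i] & nbr[j]):
                continue
            rj = _VDW_RADII[atoms[j].element.upper()]
            if np.linalg.norm(atoms[i].position - atoms[j].position) <= ri + rj + gap:
                out.append((min(i, j), max(i, j)))
    return sorted(set(out))


def build_network(structure: Structure, cutoff: float = DILUTION_CUTOFFS[0],
                  *, covalent: Sequence[Bond] | None = None,
                  hbonds: Sequence[HBond] | None = None,
                  tethers: Sequence[tuple[int, int]] | None = None,
                  keep_salt_bridges: bool = True) -> ConstraintNetwork:
    """Assemble the full constraint network at one energy cut-off."""
    bonds = covalent if covalent is not None else detect_covalent(structure)
    if hbonds is None:
        hbonds = find_hbonds(structure, cutoff, covalent=bonds,
                             keep_salt_bridges=keep_salt_bridges)
    else:
        hbonds = [h for h in hbonds if h.energy <= cutoff
                  or (keep_salt_bridges and h.is_salt_bridge)]
    if tethers is None:
        tethers = find_hydrophobic_tethers(structure, covalent=bonds)

    net = ConstraintNetwork(n_bodies=len(structure.atoms),
                            positions=structure.coords())
    for b in bonds:
        bars = classify_bond_bars(b, structure)
        net.add_edge(b.i, b.j, bars,
                     "covalent_locked" if bars == 6 else "covalent_rotatable")
    for h in hbonds:
        i = h.hydrogen if h.hydrogen is not None else h.donor_heavy
        net.add_edge(i, h.acceptor, 5, "hbond", energy=h.energy)
    for i, j in tethers:
        net.add_edge(i, j, 2, "hydrophobic")
    return net


# ---------------------------------------------------------------------------
# (6,6) body-bar pebble game


class _PebbleGame:
    """Directed pebble bookkeeping for the (6,6) body-bar game.

    Every body holds 6 pebbles.  A bar between u and v is independent iff 7
    pebbles can be gathered onto {u, v} (6 cover the trivial rigid motions
    of the pair); accepting it pins one pebble of u on the directed edge
    u -> v.  Pebbles are recovered by reversing directed paths.
    """

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [6] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _find_and_pull(self, s: int, exclude: tuple[int, int]) -> bool:
        """Move one free pebble (outside ``exclude``) to ``s``, if reachable."""
        parent: dict[int, int | None] = {s: None}
        stack = [s]
        target = -1
        while stack:
            u = stack.pop()
            if u != s and u not in exclude and self.pebbles[u] > 0:
                target = u
                break
            for v, cnt in self.out[u].items():
                if cnt > 0 and v not in parent:
                    parent[v] = u
                    stack.append(v)
        if target < 0:
            return False
        # reverse the path s -> ... -> target
        node = target
        while parent[node] is not None:
            prev = parent[node]
            self.out[prev][node] -= 1
            if self.out[prev][node] == 0:
                del self.out[prev][node]
            self.out[node][prev] = self.out[node].get(prev, 0) + 1
            node = prev
        self.pebbles[target] -= 1
        self.pebbles[s] += 1
        return True

    def gather(self, u: int, v: int, target: int = 7) -> bool:
        """Try to collect ``target`` pebbles on {u, v}."""
        while self.pebbles[u] + self.pebbles[v] < target:
            if not (self._find_and_pull(u, (u, v))
                    or self._find_and_pull(v, (u, v))):
                return False
        return True

    def insert_bar(self, u: int, v: int) -> bool:
        """Accept one bar between u and v if independent."""
        if not self.gather(u, v, 7):
            return False
        if self.pebbles[u] == 0:  # total >= 7 and each body holds <= 6
            u, v = v, u
        self.out[u][v] = self.out[u].get(v, 0) + 1
        self.pebbles[u] -= 1
        return True

    def _locked_component(self, u: int, v: int) -> set[int]:
        """Rigid cluster through the locked pair (u, v).

        Called right after ``gather(u, v, 7)`` failed: exactly 6 pebbles sit
        on {u, v} and none is reachable elsewhere.  A body belongs to the
        cluster iff every free pebble it can reach lies on u or v, i.e. it
        is *not* in the reverse-reachable set of the other free pebbles.
        """
        pebbled = [w for w in range(self.n)
                   if self.pebbles[w] > 0 and w not in (u, v)]
        rev: list[list[int]] = [[] for _ in range(self.n)]
        for a in range(self.n):
            for b, cnt in self.out[a].items():
                if cnt > 0:
                    rev[b].append(a)
        reachable = set(pebbled)
        stack = list(pebbled)
        while stack:
            w = stack.pop()
            for p in rev[w]:
                if p not in reachable:
                    reachable.add(p)
                    stack.append(p)
        return set(range(self.n)) - reachable


def pebble_game(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Run the (6,6) body-bar pebble game and extract rigid clusters.

    Edges are processed in a canonical sort, so the decomposition is
    deterministic and independent of input edge order (the independent /
    redundant labelling of individual bars is order-dependent, but the
    cluster partition and the independent count are not).
    """
    n = network.n_bodies
    game = _PebbleGame(n)
    n_independent = 0
    undirected: list[set[int]] = [set() for _ in range(n)]
    for e in sorted(network.edges, key=lambda e: (e.i, e.j, e.kind)):
        undirected[e.i].add(e.j)
        undirected[e.j].add(e.i)
        for _ in range(e.bars):
            if game.insert_bar(e.i, e.j):
                n_independent += 1

    # connected components of the constraint graph bound the cluster search
    comp_id = [-1] * n
    comps: list[list[int]] = []
    for s in range(n):
        if comp_id[s] >= 0:
            continue
        stack, members = [s], []
        comp_id[s] = len(comps)
        while stack:
            u = stack.pop()
            members.append(u)
            for w in undirected[u]:
                if comp_id[w] < 0:
                    comp_id[w] = len(comps)
                    stack.append(w)
        comps.append(sorted(members))

    assigned = [False] * n
    clusters: list[set[int]] = []
    for members in comps:
        member_set = set(members)
        for u in members:
            if assigned[u]:
                continue
            # probe direct neighbours first (cheap, almost always enough),
            # then the rest of the component
            candidates = sorted(undirected[u]) + [
                v for v in members if v not in undirected[u]]
            cluster = {u}
            for v in candidates:
                if v == u or assigned[v]:
                    continue
                if not game.gather(u, v, 7):
                    cluster = game._locked_component(u, v) & member_set
                    break
            for w in cluster:
                assigned[w] = True
            if len(cluster) > 1:
                clusters.append(cluster)

    clusters.sort(key=lambda c: (-len(c), min(c)))
    return RigidClusterDecomposition(
        cutoff=None, n_bodies=n,
        clusters=[frozenset(c) for c in clusters],
        n_independent=n_independent)


def dilution_series(structure: Structure,
                    cutoffs: Sequence[float] = DILUTION_CUTOFFS, *,
                    protonate: bool = True,
                    keep_salt_bridges: bool = True
                    ) -> list[RigidClusterDecomposition]:
    """Rigid cluster decompositions over a hydrogen-bond dilution series.

    Geometry is analysed once; per cut-off, hydrogen bonds weaker than the
    threshold are removed (salt bridges persist) and the pebble game reruns.
    Returns one decomposition per cut-off, tagged with it, alongside the
    (possibly protonated) structure via :func:`prepared_structure`.
    """
    st = place_backbone_hydrogens(structure) if protonate else structure
    covalent = detect_covalent(st)
    all_hbonds = find_hbonds(st, cutoff=0.0, covalent=covalent,
                             keep_salt_bridges=keep_salt_bridges)
    tethers = find_hydrophobic_tethers(st, covalent=covalent)
    out = []
    for c in cutoffs:
        net = build_network(st, c, covalent=covalent, hbonds=all_hbonds,
                            tethers=tethers,
                            keep_salt_bridges=keep_salt_bridges)
        rcd = pebble_game(net)
        rcd.cutoff = c
        out.append(rcd)
    return out


def prepared_structure(structure: Structure, protonate: bool = True) -> Structure:
    """The structure exactly as :func:`dilution_series` analyses it."""
    return place_backbone_hydrogens(structure) if protonate else structure


def domain_rigidity(rcd: RigidClusterDecomposition | Sequence[RigidClusterDecomposition],
                    structure: Structure, domain_map: DomainMap,
                    top_n: int = 20) -> DomainRigidityTable:
    """Percentage of each domain's CA atoms inside the ``top_n`` largest
    rigid clusters of the whole structure, with colour classes.

    ``structure`` must be the one the decomposition indexes (e.g. the
    protonated copy).  Accepts a single decomposition or a dilution series.
    """
    rcds = [rcd] if isinstance(rcd, RigidClusterDecomposition) else list(rcd)
    table = DomainRigidityTable()
    ca_by_domain: dict[str, list[int]] = {name: [] for name in domain_map.names}
    for k, a in enumerate(structure.atoms):
        if a.name == "CA" and not a.insertion_code:
            dom = domain_map.domain_of(a.residue_number)
            if dom in ca_by_domain:
                ca_by_domain[dom].append(k)
    for r in rcds:
        top = set().union(*r.clusters[:top_n]) if r.clusters else set()
        for name, ca_idx in ca_by_domain.items():
            if not ca_idx:
                continue  # flagged by absence from the table
            pct = 100.0 * sum(1 for k in ca_idx if k in top) / len(ca_idx)
            table.add(name, r.cutoff, pct)
    return table
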