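"""PDB structure parsing, cleanup and domain annotation.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Atom` records (author numbering, one conformer per atom after
altloc resolution) plus an identifier.  Parsing and writing go through
`gemmi`; everything downstream consumes only this container.

Domain architecture is described by a :class:`DomainMap` of named, possibly
discontinuous inclusive residue-number ranges.  The module ships
:data:`C5_DOMAIN_MAP`, the 13-domain architecture of complement C5 (CATH
boundaries): MG1–MG8, the linker, C5a, CUB, C5d and C345C, with MG6 and CUB
split into two segments each.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom", "Structure", "DomainMap", "PreparationSpec", "C5_DOMAIN_MAP",
    "UNASSIGNED", "parse_pdb", "write_pdb", "prepare_c5", "assign_domains",
    "extract_ca", "relabel_domains_as_chains", "infer_c5_chains",
]

#: Label used for residues that fall outside every domain range.
UNASSIGNED = "unassigned"

#: Chain-identifier alphabet used when relabelling domains as chains.
_CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be turned into a Structure."""


@dataclass
class Atom:
    """One coordinate record after altloc resolution.

    ``residue_number`` is the author (PDB) numbering; ``insertion_code`` and
    ``altloc`` are empty strings when absent.
    """

    serial: int
    name: str
    element: str
    altloc: str
    residue_number: int
    insertion_code: str
    residue_name: str
    chain_id: str
    occupancy: float
    position: np.ndarray
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.serial}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Structure:
    """Ordered atom list with an identifier (accession or label)."""

    atoms: list[Atom]
    id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure([replace(a, position=a.position.copy()) for a in self.atoms], self.id)

    def coords(self) -> np.ndarray:
        """N×3 array of atom positions in input order."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = p.copy()

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Atoms grouped by (chain, residue number, insertion code), input order."""
        out: dict[tuple[str, int, str], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def select(self, predicate) -> "Structure":
        return Structure([a for a in self.atoms if predicate(a)], self.id)

    def get_atom(self, residue_number: int, name: str, chain_id: str | None = None) -> Atom | None:
        for a in self.atoms:
            if (a.residue_number == residue_number and a.name == name
                    and (chain_id is None or a.chain_id == chain_id)):
                return a
        return None

    def validate(self) -> None:
        """Check the one-conformer invariant: unique (chain, resnum, icode, name)."""
        seen: set[tuple[str, int, str, str]] = set()
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.insertion_code, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom after altloc resolution: {key}")
            seen.add(key)


@dataclass(frozen=True)
class DomainMap:
    """Named, possibly discontinuous inclusive residue-number ranges.

    Ranges within a domain must not overlap and domains must be pairwise
    disjoint; both are checked at construction.
    """

    entries: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    def __post_init__(self) -> None:
        covered: dict[int, str] = {}
        names = [name for name, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("duplicate domain names in map")
        for name, ranges in self.entries:
            for start, end in ranges:
                if start > end:
                    raise ValueError(f"{name}: range {start}-{end} reversed")
                for r in range(start, end + 1):
                    if r in covered:
                        raise ValueError(
                            f"residue {r} claimed by both {covered[r]} and {name}")
                    covered[r] = name

    @classmethod
    def from_ranges(cls, mapping: dict[str, Sequence[tuple[int, int]]]) -> "DomainMap":
        return cls(tuple((k, tuple(tuple(r) for r in v)) for k, v in mapping.items()))

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def ranges(self, domain: str) -> tuple[tuple[int, int], ...]:
        for name, rr in self.entries:
            if name == domain:
                return rr
        raise KeyError(domain)

    def domain_of(self, residue_number: int) -> str:
        for name, rr in self.entries:
            for start, end in rr:
                if start <= residue_number <= end:
                    return name
        return UNASSIGNED

    def without(self, names: Iterable[str]) -> "DomainMap":
        drop = set(names)
        return DomainMap(tuple(e for e in self.entries if e[0] not in drop))

    # Plain-text config: one domain per line, "NAME start-end[,start-end...]".
    @classmethod
    def from_file(cls, path: str | Path) -> "DomainMap":
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            name, spans = line.split(None, 1)
            ranges = []
            for span in spans.replace(" ", "").split(","):
                start, end = span.split("-")
                ranges.append((int(start), int(end)))
            entries.append((name, tuple(ranges)))
        return cls(tuple(entries))

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{name} " + ",".join(f"{s}-{e}" for s, e in rr)
            for name, rr in self.entries
        ]
        Path(path).write_text("\n".join(lines) + "\n")


#: CATH-derived domain boundaries of complement C5 (author numbering).
#: MG6 and CUB are discontinuous: MG6 spans the beta/alpha chain junction and
#: CUB flanks C5d.
C5_DOMAIN_MAP = DomainMap.from_ranges({
    "MG1": [(20, 124)],
    "MG2": [(125, 223)],
    "MG3": [(224, 351)],
    "MG4": [(352, 459)],
    "MG5": [(460, 565)],
    "MG6": [(566, 613), (760, 822)],
    "linker": [(614, 673)],
    "C5a": [(679, 759)],
    "MG7": [(823, 931)],
    "CUB": [(932, 982), (1308, 1371)],
    "C5d": [(983, 1307)],
    "MG8": [(1372, 1521)],
    "C345C": [(1522, 1676)],
})


@dataclass
class PreparationSpec:
    """How to reduce a deposited coordinate file to a single clean copy.

    ``keep_chains`` names the chains forming one copy of the molecule of
    interest (for C5, its beta + alpha chains); everything else is deleted.
    """

    keep_chains: tuple[str, ...]
    drop_het: bool = True
    drop_waters: bool = True
    exclude_domains: tuple[str, ...] = ()
    keep_glycans: bool = False

    def __post_init__(self) -> None:
        if not self.keep_chains:
            raise ValueError("keep_chains must be non-empty")


# ---------------------------------------------------------------------------
# Parsing and writing


def parse_pdb(path: str | Path, id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    Alternate locations are resolved to the highest-occupancy conformer;
    ties break to the lexicographically first altloc identifier.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models")

    atoms: list[Atom] = []
    serial = 0
    model = st[0]
    for chain in model:
        for res in chain:
            # altloc groups within the residue, keyed by atom name
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, a.altloc or ""))
                serial += 1
                atoms.append(Atom(
                    serial=serial,
                    name=name,
                    element=best.element.name.upper(),
                    altloc=(best.altloc or "").strip(),
                    residue_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    residue_name=res.name,
                    chain_id=chain.name,
                    occupancy=min(max(best.occ, 0.0), 1.0),
                    position=np.array([best.pos.x, best.pos.y, best.pos.z]),
                    het=(res.het_flag == "H"),
                ))
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return Structure(atoms, id=id or path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as PDB text (ATOM/HETATM/TER/END), via gemmi."""
    # gemmi's add_* methods copy their argument, so populate children fully
    # before attaching them to the parent.
    by_chain: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.insertion_code), []).append(a)

    st = gemmi.Structure()
    st.name = structure.id or "model"
    model = gemmi.Model("1")
    for chain_id, residues in by_chain.items():
        ch = gemmi.Chain(chain_id)
        for (resnum, icode), res_atoms in residues.items():
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(resnum, icode or " ")
            res.het_flag = "H" if res_atoms[0].het else "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element.capitalize())
                at.occ = a.occupancy
                at.b_iso = 0.0
                at.pos = gemmi.Position(*a.position)
                res.add_atom(at)
            ch.add_residue(res)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Preparation and domain annotation


def prepare_c5(structure: Structure, spec: PreparationSpec,
               domain_map: DomainMap | None = None) -> Structure:
    """Reduce a deposited structure to one clean copy of the molecule.

    Keeps only ``spec.keep_chains``, removes waters and (by default) all
    HETATM records — modulators, ligands, ions, glycans — and optionally
    drops whole domains (e.g. ones unresolved in a paired structure when a
    map is supplied).  Coordinates of retained atoms are never altered.
    """
    keep = set(spec.keep_chains)
    missing = keep - set(structure.chain_ids())
    if missing:
        raise ValueError(f"chains not present in structure: {sorted(missing)}")
    excluded = set(spec.exclude_domains)

    def retained(a: Atom) -> bool:
        if a.chain_id not in keep:
            return False
        if spec.drop_waters and a.residue_name in _WATER_NAMES:
            return False
        if a.het and spec.drop_het and not (spec.keep_glycans and _is_glycan(a)):
            return False
        if excluded and domain_map is not None:
            if domain_map.domain_of(a.residue_number) in excluded:
                return False
        return True

    out = structure.select(retained)
    if not out.atoms:
        raise ValueError("preparation removed every atom; check keep_chains")
    return out


_GLYCAN_NAMES = {"NAG", "NDG", "BMA", "MAN", "FUC", "GAL", "SIA", "GLC", "BGC", "XYS"}


def _is_glycan(a: Atom) -> bool:
    return a.residue_name in _GLYCAN_NAMES


def infer_c5_chains(structure: Structure,
                    beta_span: tuple[int, int] = (20, 565),
                    full_span: tuple[int, int] = (20, 1676)) -> tuple[str, ...]:
    """Chains forming one copy of C5 in a (possibly multi-copy) deposition.

    Picks the alphabetically first chain whose residues span the beta chain
    (20–565), then greedily adds further chains (alphabetical order) that
    extend residue-number coverage of 20–1676 without duplicating numbers
    already covered — i.e. the alpha chain of the same copy.
    """
    per_chain: dict[str, set[int]] = {}
    for a in structure.atoms:
        if not a.het and full_span[0] <= a.residue_number <= full_span[1]:
            per_chain.setdefault(a.chain_id, set()).add(a.residue_number)
    beta_candidates = sorted(
        c for c, nums in per_chain.items()
        if sum(1 for r in nums if beta_span[0] <= r <= beta_span[1]) >= 100)
    if not beta_candidates:
        raise ValueError("no chain spans the beta-chain residue range")
    chosen = [beta_candidates[0]]
    covered = set(per_chain[chosen[0]])
    for c in sorted(per_chain):
        if c in chosen:
            continue
        nums = per_chain[c]
        if len(nums) >= 50 and len(nums & covered) < 0.1 * len(nums):
            chosen.append(c)
            covered |= nums
    return tuple(chosen)


def assign_domains(structure: Structure, domain_map: DomainMap) -> dict[str, list[int]]:
    """Partition residues into named domains by author residue number.

    Returns ``{domain_name: sorted residue numbers present}``; residues
    outside every range land under :data:`UNASSIGNED`.  Discontinuous
    domains unify their segments under one name.
    """
    seen: dict[str, set[int]] = {name: set() for name in domain_map.names}
    seen[UNASSIGNED] = set()
    for (chain, resnum, icode) in structure.residues():
        seen[domain_map.domain_of(resnum)].add(resnum)
    return {name: sorted(v) for name, v in seen.items()}


def extract_ca(structure: Structure, domain: str,
               domain_map: DomainMap) -> list[tuple[int, np.ndarray]]:
    """CA coordinates of a domain, one per residue, ascending residue number.

    Residues without a CA atom are skipped; insertion-coded residues are
    excluded so that author numbering is a unique key across structures.
    """
    ranges = domain_map.ranges(domain)  # raises KeyError for unknown domain
    hits: dict[int, np.ndarray] = {}
    for a in structure.atoms:
        if a.name != "CA" or a.insertion_code:
            continue
        for start, end in ranges:
            if start <= a.residue_number <= end:
                hits.setdefault(a.residue_number, a.position)
                break
    if not hits:
        raise ValueError(f"domain {domain}: no CA atoms found")
    return [(r, hits[r]) for r in sorted(hits)]


def relabel_domains_as_chains(structure: Structure, domain_map: DomainMap,
                              unassigned_chain: str | None = None) -> Structure:
    """Return a copy in which each domain's atoms share a unique chain id.

    Domains take ids from ``A``.. in map order; residues outside every
    domain get a reserved id (the first alphabet letter not used by a
    domain, unless given explicitly).  The result round-trips through
    :func:`write_pdb` / :func:`parse_pdb`.
    """
    names = domain_map.names
    if len(names) >= len(_CHAIN_ALPHABET):
        raise ValueError("more domains than available chain identifiers")
    chain_of = {name: _CHAIN_ALPHABET[i] for i, name in enumerate(names)}
    reserved = unassigned_chain or _CHAIN_ALPHABET[len(names)]
    out = structure.copy()
    for a in out.atoms:
        dom = domain_map.domain_of(a.residue_number)
        a.chain_id = reserved if dom == UNASSIGNED else chain_of[dom]
    # keep atoms grouped by their new chain so the PDB writer emits one
    # chain block per domain
    order = {c: i for i, c in enumerate([*chain_of.values(), reserved])}
    out.atoms.sort(key=lambda a: (order[a.chain_id], a.residue_number,
                                  a.insertion_code, a.serial))
    return out
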