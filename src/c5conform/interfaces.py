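"""Solvent-accessible surface areas and domain-interface buried areas.

SASA is computed with the Shrake–Rupley method on a deterministic
golden-section spiral point lattice, so results are bit-stable across runs
and platforms.  The buried area between two atom sets a and b is

    buried(a, b) = sasa(a) + sasa(b) - sasa(a ∪ b)
                 = ΔASA_a + ΔASA_b,

i.e. the total surface both partners lose on contact, computed with only the
two sets present (the chain-pair convention of interface servers).  Some
tools report the half-sum instead; ``half_sum=True`` switches convention.

Hydrogens are excluded by default — crystal structures rarely resolve them —
and element radii follow the NACCESS/Chothia-style set below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from c5conform.structure_io import Atom, DomainMap, Structure

__all__ = [
    "SasaResult", "InterfaceRecord", "InterfaceDeltaTable", "RADII",
    "sasa", "buried_area", "domain_interface_panel", "interface_delta",
    "DEFAULT_PANELS",
]

#: Element -> van der Waals radius (Å).  NACCESS/Chothia-flavoured values.
RADII: dict[str, dict[str, float]] = {
    "default": {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
        "H": 1.09, "D": 1.09, "SE": 1.90, "F": 1.47, "CL": 1.75,
        "BR": 1.85, "I": 1.98,
    },
}

#: Interface panels probed around the conformational-relay domains of C5:
#: the neighbours of MG3, MG4 and C5a.
DEFAULT_PANELS: dict[str, tuple[str, ...]] = {
    "MG3": ("MG2", "MG4", "MG6", "C5a", "MG7", "MG8"),
    "MG4": ("MG3", "MG5", "linker"),
    "C5a": ("MG3", "MG6", "C5d", "MG8"),
}


@dataclass
class SasaResult:
    per_atom_area: np.ndarray
    total: float
    probe_radius: float
    n_sphere_points: int

    def __post_init__(self) -> None:
        self.per_atom_area = np.asarray(self.per_atom_area, float)
        if np.any(self.per_atom_area < 0):
            raise ValueError("negative per-atom area")
        if abs(self.total - float(self.per_atom_area.sum())) > 1e-6:
            raise ValueError("total inconsistent with per-atom areas")


@dataclass
class InterfaceRecord:
    domain_a: str
    domain_b: str
    buried_area: float
    absent: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not self.absent and self.buried_area < -1e-9:
            raise ValueError("buried area must be non-negative")


@dataclass
class InterfaceDeltaTable:
    """Signed interface-area changes of a complex relative to apo (Å²)."""

    complex_id: str
    apo_id: str
    entries: list[tuple[str, str, float]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def get(self, focal: str, partner: str) -> float:
        for f, p, d in self.entries:
            if (f, p) == (focal, partner):
                return d
        raise KeyError((focal, partner))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic unit-sphere lattice (golden-section spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _radii_for(atoms: Sequence[Atom], radii_set: str | Mapping[str, float]) -> np.ndarray:
    table = RADII[radii_set] if isinstance(radii_set, str) else radii_set
    out = np.empty(len(atoms))
    for k, a in enumerate(atoms):
        el = a.element.upper()
        if el not in table:
            raise KeyError(f"no radius for element {el!r} (atom {a.serial} {a.name})")
        out[k] = table[el]
    return out


def sasa(structure: Structure | Sequence[Atom], probe: float = 1.4,
         n_points: int = 960, radii_set: str | Mapping[str, float] = "default",
         include_hydrogens: bool = False) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is expanded by the probe radius and sampled with ``n_points``
    lattice points; a point is accessible if it lies outside every
    neighbouring expanded sphere.  Deterministic given ``n_points``.
    """
    atoms = structure.atoms if isinstance(structure, Structure) else list(structure)
    if not include_hydrogens:
        atoms = [a for a in atoms if a.element.upper() not in ("H", "D")]
    if not atoms:
        raise ValueError("sasa of empty structure")
    xyz = np.array([a.position for a in atoms])
    radii = _radii_for(atoms, radii_set) + probe
    pts = _sphere_points(n_points)

    tree = cKDTree(xyz)
    rmax = float(radii.max())
    areas = np.zeros(len(atoms))
    for k in range(len(atoms)):
        rk = radii[k]
        neigh = [j for j in tree.query_ball_point(xyz[k], rk + rmax)
                 if j != k and np.linalg.norm(xyz[j] - xyz[k]) < rk + radii[j]]
        surf = xyz[k] + rk * pts
        if neigh:
            d2 = ((surf[:, None, :] - xyz[neigh][None, :, :]) ** 2).sum(axis=2)
            buried_mask = (d2 < (radii[neigh] ** 2)[None, :]).any(axis=1)
            n_acc = int((~buried_mask).sum())
        else:
            n_acc = n_points
        areas[k] = 4.0 * np.pi * rk * rk * n_acc / n_points
    return SasaResult(per_atom_area=areas, total=float(areas.sum()),
                      probe_radius=probe, n_sphere_points=n_points)


def buried_area(a: Sequence[Atom] | Structure, b: Sequence[Atom] | Structure,
                domain_a: str = "a", domain_b: str = "b", *,
                half_sum: bool = False, **sasa_kwargs) -> InterfaceRecord:
    """Surface area buried between two disjoint atom sets (Å²).

    Computed with only the two sets present.  Satisfies, by construction,
    ``sasa(a ∪ b).total == sasa(a).total + sasa(b).total - buried``.
    """
    atoms_a = a.atoms if isinstance(a, Structure) else list(a)
    atoms_b = b.atoms if isinstance(b, Structure) else list(b)
    ids_a = {id(x) for x in atoms_a}
    if any(id(x) in ids_a for x in atoms_b):
        raise ValueError("atom sets must be disjoint")
    s_a = sasa(atoms_a, **sasa_kwargs).total
    s_b = sasa(atoms_b, **sasa_kwargs).total
    s_ab = sasa(atoms_a + atoms_b, **sasa_kwargs).total
    buried = max(0.0, s_a + s_b - s_ab)
    if half_sum:
        buried *= 0.5
    return InterfaceRecord(domain_a=domain_a, domain_b=domain_b, buried_area=buried)


def _domain_atoms(structure: Structure, domain: str, domain_map: DomainMap) -> list[Atom]:
    ranges = domain_map.ranges(domain)
    return [a for a in structure.atoms
            if any(s <= a.residue_number <= e for s, e in ranges)]


def domain_interface_panel(structure: Structure, domain_map: DomainMap,
                           panel: Mapping[str, Iterable[str]] | None = None,
                           *, half_sum: bool = False,
                           **sasa_kwargs) -> list[InterfaceRecord]:
    """Buried areas between each focal domain and its listed partners.

    A partner (or focal domain) with no atoms in the structure yields a
    record flagged ``absent`` rather than a silent zero.
    """
    panel = panel or DEFAULT_PANELS
    records: list[InterfaceRecord] = []
    cache: dict[str, list[Atom]] = {}

    def atoms_of(name: str) -> list[Atom]:
        if name not in cache:
            try:
                cache[name] = _domain_atoms(structure, name, domain_map)
            except KeyError:  # domain not even in the map
                cache[name] = []
        return cache[name]

    for focal, partners in panel.items():
        for partner in partners:
            fa, pa = atoms_of(focal), atoms_of(partner)
            if not fa or not pa:
                records.append(InterfaceRecord(
                    focal, partner, 0.0, absent=True,
                    note=f"{focal if not fa else partner} absent from {structure.id}"))
                continue
            rec = buried_area(fa, pa, focal, partner,
                              half_sum=half_sum, **sasa_kwargs)
            records.append(rec)
    return records


def interface_delta(complex_structure: Structure, apo_structure: Structure,
                    domain_map: DomainMap,
                    panels: Mapping[str, Iterable[str]] | None = None,
                    *, half_sum: bool = False,
                    **sasa_kwargs) -> InterfaceDeltaTable:
    """Interface-area changes of a complex relative to apo (complex − apo).

    Positive values mean the interface grew.  Pairs absent from either
    structure are reported in ``notes`` and omitted from ``entries``.
    """
    panels = panels or DEFAULT_PANELS
    rc = domain_interface_panel(complex_structure, domain_map, panels,
                                half_sum=half_sum, **sasa_kwargs)
    ra = domain_interface_panel(apo_structure, domain_map, panels,
                                half_sum=half_sum, **sasa_kwargs)
    table = InterfaceDeltaTable(complex_id=complex_structure.id,
                                apo_id=apo_structure.id)
    apo_by_pair = {(r.domain_a, r.domain_b): r for r in ra}
    for rec in rc:
        apo_rec = apo_by_pair[(rec.domain_a, rec.domain_b)]
        if rec.absent or apo_rec.absent:
            table.notes.append(
                f"{rec.domain_a}/{rec.domain_b}: {rec.note or apo_rec.note}")
            continue
        table.entries.append(
            (rec.domain_a, rec.domain_b, rec.buried_area - apo_rec.buried_area))
    return table
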