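"""Domain-by-domain rigid superposition and displacement quantification.

For a complex/apo structure pair, each domain of the complex is superimposed
onto the corresponding apo domain with the Kabsch algorithm; the fitted
transform is then applied to *all* CA atoms of the complex, and every other
domain's displacement is read off as

- translation: Euclidean distance (Å) between the centre of mass (COM, the
  arithmetic mean of domain CA coordinates) of the domain in the transformed
  complex and in apo;
- rotation: the angle (°) at the COM of the superimposed reference domain
  between the vectors pointing to the two target-domain COMs.

Iterating over every domain as reference yields a reference × target grid —
one translation matrix and one rotation matrix per complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from c5conform.structure_io import DomainMap, Structure, extract_ca

__all__ = [
    "RigidTransform", "DisplacementRecord", "DisplacementMatrix",
    "kabsch", "com", "match_ca", "displacement_matrix",
]

#: Vector norms below this (Å) make the rotation angle ill-defined.
DEGENERATE_NORM = 1e-6


@dataclass
class RigidTransform:
    """Proper rigid transform ``x -> rotation @ x + translation`` plus fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation is improper (det != +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


@dataclass
class DisplacementRecord:
    reference_domain: str
    target_domain: str
    translation: float
    rotation: float
    n_matched: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.translation < 0:
            raise ValueError("translation must be non-negative")
        if not (0.0 <= self.rotation <= 180.0 + 1e-9):
            raise ValueError("rotation angle must lie in [0, 180] degrees")


@dataclass
class DisplacementMatrix:
    """Reference-domain × target-domain displacement grid (diagonal excluded)."""

    complex_id: str
    apo_id: str
    domains: list[str]
    records: dict[tuple[str, str], DisplacementRecord] = field(default_factory=dict)

    def get(self, reference: str, target: str) -> DisplacementRecord:
        return self.records[(reference, target)]

    def _frame(self, attr: str) -> pd.DataFrame:
        df = pd.DataFrame(index=self.domains, columns=self.domains, dtype=float)
        for (r, t), rec in self.records.items():
            df.loc[r, t] = getattr(rec, attr)
        df.index.name = "reference"
        return df

    def translation_frame(self) -> pd.DataFrame:
        """Translations (Å); rows = reference domain, columns = target."""
        return self._frame("translation")

    def rotation_frame(self) -> pd.DataFrame:
        """Rotations (°); rows = reference domain, columns = target."""
        return self._frame("rotation")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal proper rigid transform superposing ``mobile`` onto ``reference``.

    Closed-form least-squares solution via SVD of the 3×3 covariance matrix;
    a sign flip of the smallest singular vector excludes reflections.  Needs
    at least three non-collinear point pairs.
    """
    M = np.asarray(mobile, float)
    R_ = np.asarray(reference, float)
    if M.shape != R_.shape or M.ndim != 2 or M.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N×3 arrays")
    n = M.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    cm, cr = M.mean(axis=0), R_.mean(axis=0)
    Mc, Rc = M - cm, R_ - cr
    sv = np.linalg.svd(Mc, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate point set (collinear): rotation not unique")
    C = Mc.T @ Rc
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    rot = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    trans = cr - rot @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((Mc @ rot.T - Rc) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def com(coords: np.ndarray) -> np.ndarray:
    """Centre of mass as the unweighted mean of coordinates."""
    X = np.atleast_2d(np.asarray(coords, float))
    if X.size == 0:
        raise ValueError("com of empty coordinate set")
    return X.mean(axis=0)


def match_ca(complex_structure: Structure, apo_structure: Structure,
             domain: str, domain_map: DomainMap) -> tuple[np.ndarray, np.ndarray]:
    """Pair domain CA coordinates by author residue number.

    Returns (complex N×3, apo N×3) over the intersection of residue numbers
    carrying a CA in both structures, ascending.
    """
    ca_c = dict(extract_ca(complex_structure, domain, domain_map))
    ca_a = dict(extract_ca(apo_structure, domain, domain_map))
    common = sorted(set(ca_c) & set(ca_a))
    if len(common) < 3:
        raise ValueError(
            f"domain {domain}: only {len(common)} matched CA residues (need >= 3)")
    return (np.array([ca_c[r] for r in common]),
            np.array([ca_a[r] for r in common]))


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> tuple[float, bool]:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < DEGENERATE_NORM or n2 < DEGENERATE_NORM:
        return 0.0, True
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c))), False


def displacement_matrix(complex_structure: Structure, apo_structure: Structure,
                        domain_map: DomainMap, *,
                        vertex: str = "apo",
                        min_matched: int = 3) -> DisplacementMatrix:
    """All-against-all domain displacement of a complex relative to apo.

    Domains unresolved (fewer than ``min_matched`` matched CA) in either
    structure are dropped pairwise.  ``vertex`` selects the apex of the
    rotation angle: the COM of the superimposed reference domain taken from
    the apo structure (``"apo"``, default — apo is the fixed frame) or from
    the transformed complex (``"complex"``); after superposition the two
    differ by at most the fit RMSD.
    """
    if vertex not in ("apo", "complex"):
        raise ValueError("vertex must be 'apo' or 'complex'")

    matched: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name in domain_map.names:
        try:
            pair = match_ca(complex_structure, apo_structure, name, domain_map)
        except (ValueError, KeyError):
            continue
        if pair[0].shape[0] >= min_matched:
            matched[name] = pair
    domains = list(matched)
    if len(domains) < 2:
        raise ValueError("fewer than two resolved domains in common")

    out = DisplacementMatrix(complex_id=complex_structure.id,
                             apo_id=apo_structure.id, domains=domains)
    for ref in domains:
        X_ref_c, X_ref_a = matched[ref]
        tr = kabsch(X_ref_c, X_ref_a)
        apo_ref_com = com(X_ref_a)
        moved_ref_com = com(tr.apply(X_ref_c))
        # sanity: the superimposed reference domain itself barely moves
        self_shift = float(np.linalg.norm(moved_ref_com - apo_ref_com))
        assert self_shift <= 2.0 * tr.rmsd + 1e-9, (
            f"reference {ref}: self-displacement {self_shift:.3f} exceeds 2*rmsd")
        V = apo_ref_com if vertex == "apo" else moved_ref_com
        for tgt in domains:
            if tgt == ref:
                continue
            X_tgt_c, X_tgt_a = matched[tgt]
            moved = com(tr.apply(X_tgt_c))
            fixed = com(X_tgt_a)
            translation = float(np.linalg.norm(moved - fixed))
            angle, degen = _angle_deg(moved - V, fixed - V)
            out.records[(ref, tgt)] = DisplacementRecord(
                reference_domain=ref, target_domain=tgt,
                translation=translation, rotation=angle,
                n_matched=X_tgt_c.shape[0], degenerate=degen)
    return out
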