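"""Synthetic structures and frameworks with known ground truth.

Everything the analysis stages assume can be generated at desk scale:

- multi-domain CA/backbone structures where each domain has been moved by a
  *known* rigid transform (plus optional Gaussian coordinate noise), with
  displacement ground truth computed in closed form;
- ideal-dihedral peptides (α-helical, extended, or any (φ, ψ)) built from
  standard bond lengths/angles by NeRF internal-coordinate chaining, with
  optional amide hydrogens;
- generic body-bar frameworks with prescribed bar multiplicities, plus an
  independent rigidity-matrix oracle (rank and pairwise-weld tests) for
  validating the pebble game;
- two-body atom clusters at controlled separation for interface-area tests.

All generators are deterministic under a fixed seed, and ground truth is
always produced by closed-form geometry, never by the module being tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from c5conform.rigidity import ConstraintNetwork
from c5conform.structure_io import Atom, DomainMap, Structure

__all__ = [
    "ToySpec", "DomainTransform", "FrameworkSpec",
    "make_multidomain_toy", "make_ideal_peptide", "make_framework",
    "make_contact_pair", "random_framework",
    "body_bar_rank", "body_bar_clusters",
]

# Standard backbone geometry (Engh–Huber-like values).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.5
_OMEGA = 180.0


@dataclass
class DomainTransform:
    """Rigid perturbation of one domain: rotate ``angle_deg`` about ``axis``
    through ``pivot`` (default: the domain's own apo CA centroid), then
    translate."""

    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pivot: tuple[float, float, float] | None = None

    def matrices(self, default_pivot: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (R, t) of the affine map x -> R x + t."""
        axis = np.asarray(self.axis, float)
        n = np.linalg.norm(axis)
        R = (np.eye(3) if n == 0 or self.angle_deg == 0 else
             Rotation.from_rotvec(np.radians(self.angle_deg) * axis / n).as_matrix())
        p = np.asarray(self.pivot if self.pivot is not None else default_pivot, float)
        t = p - R @ p + np.asarray(self.translation, float)
        return R, t


@dataclass
class ToySpec:
    n_domains: int = 3
    residues_per_domain: int = 20
    applied_transforms: list[DomainTransform] = field(default_factory=list)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.applied_transforms and len(self.applied_transforms) != self.n_domains:
            raise ValueError("need one transform per domain (or none)")


@dataclass
class FrameworkSpec:
    bodies: int
    edges: list[tuple[int, int, int]]  # (i, j, bars)
    expected_clusters: list[set[int]] | None = None

    def __post_init__(self) -> None:
        for i, j, bars in self.edges:
            if not (1 <= bars <= 6):
                raise ValueError(f"bars must be in [1, 6], got {bars}")
            if i == j or not (0 <= i < self.bodies and 0 <= j < self.bodies):
                raise ValueError(f"bad edge ({i}, {j})")


# ---------------------------------------------------------------------------
# NeRF peptide builder


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) and torsion(a,b,c,d)."""
    ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_ideal_peptide(n: int, phi: float = -57.0, psi: float = -47.0,
                       protonate: bool = False, residue_name: str = "GLY",
                       chain_id: str = "A", first_residue: int = 1,
                       structure_id: str = "peptide") -> Structure:
    """Ideal-dihedral peptide with exact (φ, ψ) at every residue.

    Standard bond lengths and angles, trans peptide bonds (ω = 180°),
    carbonyl oxygens in the peptide plane, optional amide hydrogens
    (N–H = 1.01 Å, anti to the preceding carbonyl) and a CB when
    ``residue_name`` is not GLY.
    """
    if n < 2:
        raise ValueError("need at least 2 residues")
    N = [np.array([0.0, 0.0, 0.0])]
    t = np.radians(180.0 - _A_N_CA_C)
    CA = [N[0] + np.array([_B_N_CA, 0.0, 0.0])]
    C = [CA[0] + _B_CA_C * np.array([np.cos(t), np.sin(t), 0.0])]
    for i in range(1, n):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(_nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O = [_nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
         for i in range(n)]

    atoms: list[Atom] = []

    def emit(name: str, element: str, resnum: int, pos: np.ndarray) -> None:
        atoms.append(Atom(serial=len(atoms) + 1, name=name, element=element,
                          altloc="", residue_number=resnum, insertion_code="",
                          residue_name=residue_name, chain_id=chain_id,
                          occupancy=1.0, position=pos))

    for i in range(n):
        resnum = first_residue + i
        emit("N", "N", resnum, N[i])
        if protonate and i > 0 and residue_name != "PRO":
            h = N[i] + 1.01 * (C[i - 1] - O[i - 1]) / np.linalg.norm(C[i - 1] - O[i - 1])
            emit("H", "H", resnum, h)
        emit("CA", "C", resnum, CA[i])
        if residue_name != "GLY":
            emit("CB", "C", resnum, _nerf(C[i], N[i], CA[i], 1.521, 110.5, -122.0))
        emit("C", "C", resnum, C[i])
        emit("O", "O", resnum, O[i])
    return Structure(atoms, structure_id)


# ---------------------------------------------------------------------------
# Multi-domain toys with displacement ground truth


def _domain_offset(d: int) -> np.ndarray:
    # non-collinear domain centres so rotation angles are generic
    return np.array([25.0 * np.cos(2.4 * d), 25.0 * np.sin(2.4 * d), 8.0 * d])


def make_multidomain_toy(spec: ToySpec) -> tuple[Structure, Structure,
                                                 list[dict], DomainMap]:
    """Apo/perturbed structure pair plus closed-form displacement truth.

    Domains are compact helical backbone blobs (so per-domain superposition
    is well conditioned) at non-collinear centres; domain ``d`` occupies
    residues ``100*d + 1 ...``.  The perturbed copy applies each domain's
    rigid transform, then Gaussian noise of ``noise_sigma`` Å.

    Ground-truth records mirror the displacement conventions — reference
    domain superposed exactly (its inverse transform applied to all
    domains), translation = CA-centroid shift of the target, rotation =
    angle at the apo reference centroid — computed purely from the applied
    affine maps, never by running the displacement module.
    """
    rng = np.random.default_rng(spec.seed)
    transforms = (spec.applied_transforms
                  or [DomainTransform() for _ in range(spec.n_domains)])

    apo_atoms: list[Atom] = []
    domain_names: list[str] = []
    ranges: dict[str, list[tuple[int, int]]] = {}
    ca_apo: dict[str, np.ndarray] = {}
    for d in range(spec.n_domains):
        name = f"D{d + 1}"
        first = 100 * d + 1
        block = make_ideal_peptide(spec.residues_per_domain, chain_id="A",
                                   first_residue=first)
        offset = _domain_offset(d)
        for a in block.atoms:
            a.position = a.position + offset
            a.serial = len(apo_atoms) + 1
            apo_atoms.append(a)
        domain_names.append(name)
        ranges[name] = [(first, first + spec.residues_per_domain - 1)]
        ca_apo[name] = np.array([a.position for a in block.atoms if a.name == "CA"])
    dmap = DomainMap.from_ranges(ranges)
    apo = Structure(apo_atoms, "toy_apo")

    # affine map per domain
    RT: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, tf in zip(domain_names, transforms):
        RT[name] = tf.matrices(default_pivot=ca_apo[name].mean(axis=0))

    perturbed = apo.copy()
    perturbed.id = "toy_perturbed"
    for a in perturbed.atoms:
        name = dmap.domain_of(a.residue_number)
        R, t = RT[name]
        a.position = R @ a.position + t
    if spec.noise_sigma > 0:
        xyz = perturbed.coords() + rng.normal(0.0, spec.noise_sigma,
                                              (len(perturbed.atoms), 3))
        perturbed.set_coords(xyz)

    truth: list[dict] = []
    for ref in domain_names:
        R_r, t_r = RT[ref]
        # exact superposition of the reference inverts its transform
        Rinv, tinv = R_r.T, -R_r.T @ t_r
        V = ca_apo[ref].mean(axis=0)
        # first-order noise propagation through the reference fit: the
        # least-squares rotation error about principal axis k of the
        # reference CA second-moment matrix S has variance
        # sigma^2 / (s_i + s_j), and is amplified by the lever arm to the
        # target centre; fit translation and target-COM noise add 3/N each.
        Xc = ca_apo[ref] - V
        s = np.linalg.eigvalsh(Xc.T @ Xc)
        omega_var_unit = float(sum(1.0 / (s[i] + s[j])
                                   for i, j in ((0, 1), (0, 2), (1, 2))))
        n_ref = ca_apo[ref].shape[0]
        for tgt in domain_names:
            if tgt == ref:
                continue
            R_d, t_d = RT[tgt]
            com_apo = ca_apo[tgt].mean(axis=0)
            com_moved = Rinv @ (R_d @ ca_apo[tgt].T).T.mean(axis=0) \
                + Rinv @ t_d + tinv
            translation = float(np.linalg.norm(com_moved - com_apo))
            v1, v2 = com_moved - V, com_apo - V
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-6 or n2 < 1e-6:
                rotation = 0.0
            else:
                rotation = float(np.degrees(np.arccos(
                    np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))))
            n_tgt = ca_apo[tgt].shape[0]
            lever = float(np.linalg.norm(com_apo - V))
            sig = spec.noise_sigma
            t_bound = 3.0 * sig * np.sqrt(
                3.0 / n_tgt + 3.0 / n_ref + omega_var_unit * lever ** 2)
            dist = max(np.linalg.norm(v2), 1e-9)
            r_bound = float(np.degrees(np.arcsin(min(1.0, t_bound / dist)))) \
                if sig > 0 else 0.0
            truth.append({"reference_domain": ref, "target_domain": tgt,
                          "translation": translation, "rotation": rotation,
                          "translation_bound": float(t_bound),
                          "rotation_bound": r_bound})
    return apo, perturbed, truth, dmap


# ---------------------------------------------------------------------------
# Body-bar frameworks and the rigidity-matrix oracle


def make_framework(spec: FrameworkSpec, seed: int = 0) -> ConstraintNetwork:
    """Constraint network with the prescribed bars at generic random positions."""
    rng = np.random.default_rng(seed)
    net = ConstraintNetwork(n_bodies=spec.bodies,
                            positions=rng.normal(0.0, 10.0, (spec.bodies, 3)))
    for k, (i, j, bars) in enumerate(spec.edges):
        net.add_edge(i, j, bars, kind=f"bar{k}")
    return net


def random_framework(rng: np.random.Generator, max_bodies: int = 8) -> FrameworkSpec:
    """Random generic body-bar instance for oracle comparisons."""
    n = int(rng.integers(2, max_bodies + 1))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.append((i, j, int(rng.integers(1, 7))))
    if not edges:
        edges.append((0, 1, int(rng.integers(1, 7))))
    return FrameworkSpec(bodies=n, edges=edges)


def _bar_rows(ri: np.ndarray, rj: np.ndarray, rng: np.random.Generator,
              n_bodies: int, i: int, j: int, count: int) -> np.ndarray:
    """Rigidity-matrix rows for ``count`` generic bars between bodies i, j.

    A bar joins generic points p = ri + a (on body i) and q = rj + b (on
    body j); the first-order length constraint on body velocities
    (v, w) is  u·(v_i + w_i×a) − u·(v_j + w_j×b) = 0  with u = (p−q)/|p−q|.
    """
    rows = np.zeros((count, 6 * n_bodies))
    for k in range(count):
        a = rng.normal(0.0, 1.0, 3)
        b = rng.normal(0.0, 1.0, 3)
        p, q = ri + a, rj + b
        u = p - q
        u /= np.linalg.norm(u)
        rows[k, 6 * i:6 * i + 3] = u
        rows[k, 6 * i + 3:6 * i + 6] = np.cross(a, u)
        rows[k, 6 * j:6 * j + 3] = -u
        rows[k, 6 * j + 3:6 * j + 6] = -np.cross(b, u)
    return rows


def _rigidity_matrix(network: ConstraintNetwork,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    n = network.n_bodies
    pos = (network.positions if network.positions is not None
           else rng.normal(0.0, 10.0, (n, 3)))
    blocks = [_bar_rows(pos[e.i], pos[e.j], rng, n, e.i, e.j, e.bars)
              for e in network.edges]
    M = np.vstack(blocks) if blocks else np.zeros((0, 6 * n))
    return M, pos


def body_bar_rank(network: ConstraintNetwork, seed: int = 0) -> int:
    """Independent-constraint count by rigidity-matrix rank (oracle)."""
    rng = np.random.default_rng(seed)
    M, _ = _rigidity_matrix(network, rng)
    return int(np.linalg.matrix_rank(M)) if M.size else 0


def body_bar_clusters(network: ConstraintNetwork, seed: int = 0) -> list[frozenset[int]]:
    """Rigid clusters by pairwise weld tests on the rigidity matrix (oracle).

    A pair (i, j) is mutually rigid iff adding six generic bars between
    them leaves the matrix rank unchanged.  Mutual rigidity is transitive,
    so clusters are the multi-body equivalence classes, ranked largest
    first with ties broken by smallest member.
    """
    rng = np.random.default_rng(seed)
    M, pos = _rigidity_matrix(network, rng)
    n = network.n_bodies
    base_rank = int(np.linalg.matrix_rank(M)) if M.size else 0
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            weld = _bar_rows(pos[i], pos[j], rng, n, i, j, 6)
            rank = int(np.linalg.matrix_rank(np.vstack([M, weld]) if M.size else weld))
            if rank == base_rank:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for k in range(n):
        groups.setdefault(find(k), set()).add(k)
    clusters = [frozenset(g) for g in groups.values() if len(g) > 1]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return clusters


# ---------------------------------------------------------------------------
# Contact pairs for interface tests


def make_contact_pair(separation: float, structure_id: str = "pair"
                      ) -> tuple[Structure, DomainMap]:
    """Two centrosymmetric carbon clusters with COMs ``separation`` Å apart.

    Residue 1 is domain ``A``, residue 2 domain ``B``; the clusters are
    translated copies, so on contact each buries the same area.
    """
    if separation < 0:
        raise ValueError("separation must be non-negative")
    blob = np.array([[0.0, 0.0, 0.0],
                     [1.5, 0.0, 0.0], [-1.5, 0.0, 0.0],
                     [0.0, 1.5, 0.0], [0.0, -1.5, 0.0],
                     [0.0, 0.0, 1.5], [0.0, 0.0, -1.5]])
    atoms: list[Atom] = []
    for resnum, shift in ((1, np.zeros(3)), (2, np.array([separation, 0.0, 0.0]))):
        for k, p in enumerate(blob):
            atoms.append(Atom(serial=len(atoms) + 1, name=f"C{k + 1}",
                              element="C", altloc="", residue_number=resnum,
                              insertion_code="", residue_name="BLB",
                              chain_id="A", occupancy=1.0, position=p + shift))
    dmap = DomainMap.from_ranges({"A": [(1, 1)], "B": [(2, 2)]})
    return Structure(atoms, structure_id), dmap
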