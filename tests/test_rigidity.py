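"""Constraint network construction and pebble-game rigidity."""

import math

import numpy as np
import pytest

from c5conform.rigidity import (Bond, ConstraintNetwork, HBond,
                                build_network, classify_bond_bars,
                                colour_class, detect_covalent, dilution_series,
                                domain_rigidity, find_hbonds,
                                find_hydrophobic_tethers, mayo_energy,
                                pebble_game, place_backbone_hydrogens,
                                prepared_structure)
from c5conform.structure_io import DomainMap, Structure
from c5conform import synthetic_data as sd
from conftest import make_atom


class TestProtonation:
    def test_dipeptide_gets_one_amide_h(self):
        st = sd.make_ideal_peptide(2)
        out = place_backbone_hydrogens(st)
        hs = [a for a in out.atoms if a.element == "H"]
        assert len(hs) == 1
        n = out.get_atom(2, "N")
        assert np.linalg.norm(hs[0].position - n.position) == pytest.approx(
            1.01, abs=1e-6)
        # anti to the preceding carbonyl: N->H parallel to O->C
        c1, o1 = out.get_atom(1, "C"), out.get_atom(1, "O")
        nh = hs[0].position - n.position
        co = c1.position - o1.position
        assert np.dot(nh, co) / (np.linalg.norm(nh) * np.linalg.norm(co)) == \
            pytest.approx(1.0, abs=1e-9)

    def test_proline_skipped(self):
        st = sd.make_ideal_peptide(2, residue_name="PRO")
        out = place_backbone_hydrogens(st)
        assert not [a for a in out.atoms if a.element == "H"]

    def test_idempotent_on_protonated_input(self, helix12):
        before = [a.name for a in helix12.atoms]
        out = place_backbone_hydrogens(helix12)
        assert [a.name for a in out.atoms] == before
        assert np.allclose(out.coords(), helix12.coords())


class TestCovalent:
    def test_dipeptide_bond_inventory(self):
        st = sd.make_ideal_peptide(2)  # GLY-GLY backbone
        bonds = detect_covalent(st)
        kinds = sorted(b.kind for b in bonds)
        assert kinds.count("peptide") == 1
        assert kinds.count("template") == 6  # (N-CA, CA-C, C-O) x 2

    def test_disulfide(self):
        atoms = [
            make_atom(1, "CB", "C", 1, (0, 0, 0), resname="CYS"),
            make_atom(2, "SG", "S", 1, (1.8, 0, 0), resname="CYS"),
            make_atom(3, "SG", "S", 2, (3.85, 0, 0), resname="CYS", chain="B"),
            make_atom(4, "CB", "C", 2, (5.6, 0, 0), resname="CYS", chain="B"),
        ]
        bonds = detect_covalent(Structure(atoms, "ss"))
        assert any(b.kind == "disulfide" for b in bonds)

    def test_chain_break_no_peptide_bond(self):
        st = sd.make_ideal_peptide(2)
        moved = st.copy()
        for a in moved.atoms:
            if a.residue_number == 2:
                a.position = a.position + np.array([10.0, 0, 0])
        assert not any(b.kind == "peptide" for b in detect_covalent(moved))

    def test_hydrogen_attachment(self, helix12):
        bonds = detect_covalent(helix12)
        h_bonds = [b for b in bonds if b.kind == "hydrogen"]
        assert len(h_bonds) == sum(1 for a in helix12.atoms if a.element == "H")


class TestBars:
    def test_peptide_bond_locked(self):
        st = sd.make_ideal_peptide(2)
        bonds = detect_covalent(st)
        pep = next(b for b in bonds if b.kind == "peptide")
        assert classify_bond_bars(pep, st) == 6

    def test_ca_cb_rotatable(self):
        st = sd.make_ideal_peptide(2, residue_name="ALA")
        bonds = detect_covalent(st)
        names = lambda b: {st.atoms[b.i].name, st.atoms[b.j].name}
        cacb = next(b for b in bonds if names(b) == {"CA", "CB"})
        assert classify_bond_bars(cacb, st) == 5

    def test_aromatic_ring_locked(self):
        ring = {"CG": (0.0, 0.0), "CD1": (1.2, 0.7), "CD2": (1.2, -0.7),
                "CE1": (2.6, 0.7), "CE2": (2.6, -0.7), "CZ": (3.3, 0.0)}
        atoms = [make_atom(k + 1, n, "C", 1, (x, y, 0.0), resname="PHE")
                 for k, (n, (x, y)) in enumerate(ring.items())]
        st = Structure(atoms, "phe")
        bonds = detect_covalent(st)
        names = lambda b: {st.atoms[b.i].name, st.atoms[b.j].name}
        cgcd1 = next(b for b in bonds if names(b) == {"CG", "CD1"})
        assert classify_bond_bars(cgcd1, st) == 6

    def test_carbonyl_locked(self):
        st = sd.make_ideal_peptide(2)
        bonds = detect_covalent(st)
        names = lambda b: {st.atoms[b.i].name, st.atoms[b.j].name}
        co = next(b for b in bonds if names(b) == {"C", "O"})
        assert classify_bond_bars(co, st) == 6


class TestMayoEnergy:
    def hb(self, d, theta=180.0, phi=180.0):
        return HBond(0, 1, 2, None, distance_DA=d, distance_HA=d - 1.0,
                     theta=theta, phi=phi)

    def test_equilibrium_ideal_geometry(self):
        assert mayo_energy(self.hb(2.8)) == pytest.approx(-8.0, abs=1e-12)

    def test_long_range_asymptote(self):
        e = mayo_energy(self.hb(50.0))
        assert -1e-6 < e < 0

    def test_formula_at_3p2(self):
        x = 2.8 / 3.2
        expected = 8.0 * (5 * x ** 12 - 6 * x ** 10)  # F = 1
        assert mayo_energy(self.hb(3.2)) == pytest.approx(expected, abs=1e-12)

    def test_bent_geometry_weaker(self):
        assert mayo_energy(self.hb(2.8, theta=120.0)) > mayo_energy(self.hb(2.8))

    def test_missing_hydrogen_raises(self):
        hb = HBond(0, None, 2, None, 2.8, 1.9, 180.0, 180.0)
        with pytest.raises(ValueError, match="protonate"):
            mayo_energy(hb)


class TestHbondSearch:
    @pytest.mark.parametrize("n", [8, 12])
    def test_helix_has_n_minus_4_bonds(self, n):
        st = sd.make_ideal_peptide(n, -57, -47, protonate=True)
        hbonds = find_hbonds(st, -0.5)
        assert len(hbonds) == n - 4
        # all are i -> i+4 backbone bonds
        for hb in hbonds:
            donor_res = st.atoms[hb.donor_heavy].residue_number
            acceptor_res = st.atoms[hb.acceptor].residue_number
            assert donor_res - acceptor_res == 4

    def test_strand_has_none(self, strand12):
        assert find_hbonds(strand12, -0.5) == []

    def test_energy_threshold_filters(self, helix12):
        hbonds = find_hbonds(helix12, 0.0)
        fake = []
        for hb, e in zip(hbonds[:3], (-0.7, -1.2, -2.5)):
            hb.energy = e
            fake.append(hb)
        net = build_network(helix12, -2.0, hbonds=fake, tethers=[])
        assert sum(1 for e in net.edges if e.kind == "hbond") == 1
        net2 = build_network(helix12, -0.5, hbonds=fake, tethers=[])
        assert sum(1 for e in net2.edges if e.kind == "hbond") == 3

    def test_salt_bridge_retained_at_any_cutoff(self):
        atoms = [
            make_atom(1, "NH1", "N", 1, (0, 0, 0), resname="ARG"),
            make_atom(2, "CZ", "C", 1, (-1.3, 0, 0), resname="ARG"),
            make_atom(3, "OD1", "O", 2, (3.8, 0, 0), resname="ASP"),
            make_atom(4, "CG", "C", 2, (4.9, 0.5, 0), resname="ASP"),
        ]
        st = Structure(atoms, "sb")
        hb = find_hbonds(st, -2.0)
        assert len(hb) == 1 and hb[0].is_salt_bridge
        assert not find_hbonds(st, -2.0, keep_salt_bridges=False)


class TestTethers:
    def leu_pair(self, gap_x):
        def leu(first_serial, resnum, x0):
            names = [("CB", (x0, 0, 0)), ("CG", (x0 + 1.3, 0.9, 0)),
                     ("CD1", (x0 + 2.8, 0.7, 0)), ("CD2", (x0 + 1.1, 2.4, 0))]
            return [make_atom(first_serial + k, n, "C", resnum, p, resname="LEU")
                    for k, (n, p) in enumerate(names)]
        atoms = leu(1, 1, 0.0) + leu(5, 2, gap_x)
        return Structure(atoms, "leu2")

    def test_contacting_side_chains_tethered(self):
        st = self.leu_pair(6.3)  # CD1(1)...CB(2) = 3.57 A < 2*1.70 + 0.25
        assert len(find_hydrophobic_tethers(st)) >= 1

    def test_distant_side_chains_untethered(self):
        assert find_hydrophobic_tethers(self.leu_pair(15.0)) == []

    def test_backbone_only_structure_has_none(self, helix12):
        assert find_hydrophobic_tethers(helix12) == []


class TestNetwork:
    def test_composition_counts(self, helix12):
        cov = detect_covalent(helix12)
        hb = find_hbonds(helix12, -0.5, covalent=cov)
        net = build_network(helix12, -0.5, covalent=cov, hbonds=hb, tethers=[])
        assert len(net.edges) == len(cov) + len(hb)

    def test_cutoff_nesting(self, helix12):
        loose = build_network(helix12, -0.5)
        tight = build_network(helix12, -2.0)
        assert tight.edge_keys() <= loose.edge_keys()

    def test_bad_edges_rejected(self):
        net = ConstraintNetwork(n_bodies=3)
        with pytest.raises(ValueError):
            net.add_edge(0, 0, 5, "covalent_rotatable")
        with pytest.raises(ValueError):
            net.add_edge(0, 1, 7, "covalent_rotatable")


def framework(edges, bodies=None):
    n = bodies or (max(max(i, j) for i, j, _ in edges) + 1)
    return sd.make_framework(sd.FrameworkSpec(bodies=n, edges=edges), seed=1)


class TestPebbleGame:
    def test_welded_pair_is_one_cluster(self):
        rcd = pebble_game(framework([(0, 1, 6)]))
        assert rcd.clusters == [frozenset({0, 1})]
        assert rcd.n_independent == 6

    def test_hinged_pair_stays_flexible(self):
        rcd = pebble_game(framework([(0, 1, 5)]))
        assert rcd.clusters == []
        assert rcd.flexible == frozenset({0, 1})
        assert rcd.n_independent == 5

    def test_hinge_chain_all_singletons(self):
        rcd = pebble_game(framework([(i, i + 1, 5) for i in range(4)]))
        assert rcd.clusters == []

    def test_two_welded_triples_with_single_bar(self):
        edges = [(0, 1, 6), (1, 2, 6), (0, 2, 6),
                 (3, 4, 6), (4, 5, 6), (3, 5, 6), (2, 3, 1)]
        rcd = pebble_game(framework(edges))
        assert sorted(rcd.clusters, key=min) == [frozenset({0, 1, 2}),
                                                 frozenset({3, 4, 5})]

    def test_redundant_bars_detected(self):
        # 7th bar between a welded pair is redundant
        net = framework([(0, 1, 6)])
        net.add_edge(0, 1, 1, "extra")
        rcd = pebble_game(net)
        assert rcd.n_independent == 6

    def test_matches_rank_oracle_on_random_instances(self):
        for seed in range(60):
            rng = np.random.default_rng(20_000 + seed)
            spec = sd.random_framework(rng)
            net = sd.make_framework(spec, seed=seed)
            rcd = pebble_game(net)
            assert rcd.n_independent == sd.body_bar_rank(net, seed=seed + 1)
            assert rcd.clusters == sd.body_bar_clusters(net, seed=seed + 1)

    def test_deterministic_under_edge_order(self):
        rng = np.random.default_rng(99)
        spec = sd.random_framework(rng)
        net = sd.make_framework(spec, seed=5)
        shuffled = ConstraintNetwork(n_bodies=net.n_bodies,
                                     positions=net.positions)
        order = rng.permutation(len(net.edges))
        for k in order:
            e = net.edges[k]
            shuffled.add_edge(e.i, e.j, e.bars, e.kind, e.energy)
        assert pebble_game(net).clusters == pebble_game(shuffled).clusters


class TestDilution:
    def test_largest_cluster_non_increasing(self, helix12):
        rcds = dilution_series(helix12)
        sizes = [r.largest_size() for r in rcds]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_identical_when_all_bonds_strong(self, helix12):
        # every bond retained at -0.5 is also stronger than -2.0 kcal/mol,
        # so the whole series sees the same network
        hb = [h.energy for h in find_hbonds(helix12, -0.5)]
        assert hb and all(e < -2.0 for e in hb)
        rcds = dilution_series(helix12)
        assert all(r.clusters == rcds[0].clusters for r in rcds)

    def test_straddling_energies_change_decomposition(self):
        # two welded triples joined by two hydrogen bonds at -1.2 kcal/mol:
        # rigid across the pair at -1.0, split at -1.5
        base = [(0, 1, 6), (1, 2, 6), (0, 2, 6),
                (3, 4, 6), (4, 5, 6), (3, 5, 6)]
        strong = framework(base + [(0, 3, 5), (2, 4, 5), (1, 5, 5)])
        weak = framework(base)
        big = pebble_game(strong)
        split = pebble_game(weak)
        assert big.clusters != split.clusters
        assert big.largest_size() == 6 and split.largest_size() == 3


class TestDomainRigidity:
    def test_fully_rigid_toy_is_purple(self, helix12):
        dmap = DomainMap.from_ranges({"H1": [(1, 6)], "H2": [(7, 12)]})
        rcds = dilution_series(helix12)
        st = prepared_structure(helix12)
        table = domain_rigidity(rcds, st, dmap)
        for cutoff in (-0.5, -2.0):
            for dom in ("H1", "H2"):
                pct = table.percent(dom, cutoff)
                assert pct >= 50.0
        assert colour_class(100.0) == "purple"

    def test_fully_flexible_is_grey(self, strand12):
        dmap = DomainMap.from_ranges({"S": [(1, 12)]})
        net = ConstraintNetwork(n_bodies=len(strand12.atoms))
        rcd = pebble_game(net)  # no constraints at all
        table = domain_rigidity(rcd, strand12, dmap)
        assert table.percent("S", None) == 0.0
        assert table.rows[0][3] == "grey"

    def test_colour_classes(self):
        assert colour_class(0.0) == "grey"
        assert colour_class(1.0) == "light_blue"
        assert colour_class(49.9) == "light_blue"
        assert colour_class(50.0) == "purple"

    def test_monotone_over_dilution_for_each_domain(self, toy_pair):
        apo, _, _, dmap = toy_pair
        st = prepared_structure(apo)
        rcds = dilution_series(apo)
        table = domain_rigidity(rcds, st, dmap)
        for dom in dmap.names:
            pcts = [table.percent(dom, c) for c in (-0.5, -1.0, -1.5, -2.0)]
            assert all(a >= b - 1e-9 for a, b in zip(pcts, pcts[1:]))
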