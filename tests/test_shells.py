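"""Shell partition geometry, per-shell graphs and shortest-path structures."""

import numpy as np
import pytest

from shellscore import (
    ComplexPose, ShellLayout, assign_shell, build_all_shells,
    build_shell_graph, floyd_warshall_paths, make_toy_complex,
)
from shellscore.features import PROTEIN_DIM
from shellscore.shells import load_shell_graphs, save_shell_graphs
from shellscore.structures import LigandAtom, LigandMolecule, ProteinAtom, \
    ProteinStructure
from shellscore.synthetic import ligand_template


def single_atom_complex(protein_positions, lig_coord=(0, 0, 0)):
    lig = LigandMolecule(
        [LigandAtom("C", 0, np.asarray(lig_coord, dtype=float), degree=0,
                    implicit_valence=4, num_h=4, hybridization="SP3")], [])
    atoms = [ProteinAtom("C", "CA", "ALA", i + 1, "A", np.asarray(p, dtype=float))
             for i, p in enumerate(protein_positions)]
    return ComplexPose(ProteinStructure(atoms, resolution=2.0), lig, "p", "c")


class TestAssignShell:
    def test_inside_first_boundary(self):
        layout = ShellLayout(3.0, 1.0, 10)
        assert assign_shell([1.5, 0, 0], np.zeros((1, 3)), layout) == 1

    def test_boundary_belongs_to_inner_shell(self):
        layout = ShellLayout(3.0, 1.0, 10)
        assert assign_shell([3.0, 0, 0], np.zeros((1, 3)), layout) == 1
        assert assign_shell([4.0, 0, 0], np.zeros((1, 3)), layout) == 2

    def test_beyond_outer_boundary_is_none(self):
        layout = ShellLayout(3.0, 1.0, 10)  # outer boundary 12.0
        assert assign_shell([12.5, 0, 0], np.zeros((1, 3)), layout) is None
        assert assign_shell([12.0, 0, 0], np.zeros((1, 3)), layout) == 10

    def test_nearest_ligand_atom_defines_distance(self):
        layout = ShellLayout(3.0, 1.0, 10)
        lig = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        assert assign_shell([11.0, 0, 0], lig, layout) == 1

    def test_partition_is_exhaustive_and_disjoint(self, rng):
        layout = ShellLayout(3.0, 1.0, 5)
        lig_xyz = rng.normal(size=(4, 3))
        for _ in range(200):
            p = rng.uniform(-10, 10, size=3)
            r = np.min(np.linalg.norm(lig_xyz - p, axis=1))
            k = assign_shell(p, lig_xyz, layout)
            if r > layout.outer(layout.n_shells):
                assert k is None
            else:
                assert layout.inner(k) < r <= layout.outer(k)


class TestLayout:
    def test_boundary_formula(self):
        layout = ShellLayout(2.5, 0.75, 6)
        for k in range(1, 7):
            assert layout.outer(k) == pytest.approx(2.5 + (k - 1) * 0.75)

    def test_invalid_layouts_rejected(self):
        for bad in [dict(d0=0), dict(d=-1), dict(n_shells=0)]:
            with pytest.raises(ValueError):
                ShellLayout(**{"d0": 3.0, "d": 1.0, "n_shells": 10, **bad})


class TestBuildShellGraph:
    def test_distance_feature_is_distmax_not_euclidean(self):
        cplx = single_atom_complex([(2.0, 0, 0)])
        g = build_shell_graph(cplx, 1, ShellLayout(3.0, 1.0, 10))
        assert g.n_protein == 1 and len(g.edges) == 1
        assert g.edge_features[0, -1] == pytest.approx(3.0)  # DistMax, not 2.0
        assert g.edge_features[0, 4] == 1  # noncovalent category

    def test_ligand_bond_distance_fixed_to_one(self, toy_complex):
        g = build_shell_graph(toy_complex, 1, ShellLayout(3.0, 1.0, 10))
        lig_edges = [e for e, (i, j) in enumerate(g.edges)
                     if i < g.n_ligand and j < g.n_ligand]
        assert lig_edges and all(
            g.edge_features[e, -1] == 1.0 for e in lig_edges)

    def test_no_protein_protein_edges(self, toy_complex):
        layout = ShellLayout(3.0, 1.0, 4)
        for k in range(1, 5):
            g = build_shell_graph(toy_complex, k, layout)
            for i, j in g.edges:
                assert i < g.n_ligand or j < g.n_ligand

    def test_every_protein_node_touches_a_ligand_node(self, toy_complex):
        layout = ShellLayout(3.0, 1.0, 4)
        for k in range(1, 5):
            g = build_shell_graph(toy_complex, k, layout)
            touched = {int(i) for i, j in g.edges if i >= g.n_ligand}
            touched |= {int(j) for i, j in g.edges if j >= g.n_ligand}
            assert touched == set(range(g.n_ligand, g.n_nodes))

    def test_node_roles_match_padding(self, toy_complex):
        g = build_shell_graph(toy_complex, 2, ShellLayout(3.0, 1.0, 10))
        assert np.all(g.node_features[:g.n_ligand, :PROTEIN_DIM] == 0)
        assert np.all(g.node_features[g.n_ligand:, PROTEIN_DIM:] == 0)

    def test_out_of_range_shell_rejected(self, toy_complex):
        with pytest.raises(ValueError):
            build_shell_graph(toy_complex, 11, ShellLayout(3.0, 1.0, 10))

    def test_rigid_motion_invariance(self, toy_complex, rng):
        layout = ShellLayout(3.0, 1.0, 3)
        before = [build_shell_graph(toy_complex, k, layout) for k in (1, 2, 3)]
        # random rotation (QR) + translation applied to the whole complex
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-20, 20, size=3)
        lig = toy_complex.ligand.translated([0, 0, 0])
        for atom in lig.atoms:
            atom.coord = q @ atom.coord + t
        prot_atoms = [ProteinAtom(a.element, a.name, a.res_name, a.res_id,
                                  a.chain, q @ a.coord + t, a.is_hetatm)
                      for a in toy_complex.protein.atoms]
        moved = ComplexPose(ProteinStructure(prot_atoms, 2.0), lig, "p", "c")
        after = [build_shell_graph(moved, k, layout) for k in (1, 2, 3)]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b.node_features, a.node_features)
            np.testing.assert_array_equal(b.edges, a.edges)
            np.testing.assert_array_equal(b.edge_features, a.edge_features)
            np.testing.assert_array_equal(b.phi, a.phi)


class TestBuildAllShells:
    def test_far_ligand_is_dissociated(self):
        cplx = single_atom_complex([(50.0, 0, 0)])
        graphs, dissociated = build_all_shells(cplx, ShellLayout(3.0, 1.0, 10))
        assert dissociated and len(graphs) == 10
        assert all(g.n_protein == 0 for g in graphs)

    def test_single_occupied_shell_not_dissociated(self):
        cplx = single_atom_complex([(4.5, 0, 0)])  # shell 3 of (3,1,10)
        graphs, dissociated = build_all_shells(cplx, ShellLayout(3.0, 1.0, 10))
        assert not dissociated
        assert [g.n_protein for g in graphs] == [0, 0, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_returns_exactly_n_graphs(self, toy_complex):
        graphs, _ = build_all_shells(toy_complex, ShellLayout(3.0, 1.0, 7))
        assert [g.k for g in graphs] == list(range(1, 8))

    def test_shell_union_covers_all_atoms_within_boundary(self, toy_complex):
        layout = ShellLayout(3.0, 1.0, 10)
        graphs, _ = build_all_shells(toy_complex, layout)
        seen = np.concatenate([g.protein_atom_indices for g in graphs])
        assert len(seen) == len(set(seen))  # disjoint
        lig_xyz = toy_complex.ligand.coords()
        expected = {i for i, a in enumerate(toy_complex.protein.atoms)
                    if np.min(np.linalg.norm(lig_xyz - a.coord, axis=1))
                    <= layout.outer(10)}
        assert set(seen.tolist()) == expected


class TestFloydWarshall:
    def test_path_graph_hops(self):
        phi, _, _ = floyd_warshall_paths(3, [(0, 1), (1, 2)], hop_max=5)
        assert phi[0, 2] == 2 and phi[0, 1] == 1 and phi[0, 0] == 0

    def test_disconnected_pair_is_minus_one(self):
        phi, _, plen = floyd_warshall_paths(2, [], hop_max=5)
        assert phi[0, 1] == -1 and plen[0, 1] == 0

    def test_truncation_at_hop_max(self):
        edges = [(i, i + 1) for i in range(7)]  # path of 8 nodes
        phi, ids, plen = floyd_warshall_paths(8, edges, hop_max=5)
        assert phi[0, 7] == 5
        assert plen[0, 7] == 5 and np.all(ids[0, 7] >= 0)

    def test_edge_path_edges_are_consecutive(self):
        edges = [(0, 1), (1, 2), (2, 3), (0, 3)]
        phi, ids, plen = floyd_warshall_paths(4, edges, hop_max=5)
        assert phi[1, 3] == 2
        assert plen[1, 3] == 2

    def test_matches_bfs_on_random_graphs(self, rng):
        """Floyd-Warshall hop counts equal BFS on 200 random graphs."""
        import networkx as nx

        hop_max = 4
        for trial in range(200):
            n = int(rng.integers(2, 31))
            p = rng.uniform(0.05, 0.3)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            edges = list(g.edges())
            phi, ids, plen = floyd_warshall_paths(n, edges, hop_max)
            lengths = dict(nx.all_pairs_shortest_path_length(g))
            for i in range(n):
                for j in range(n):
                    expect = lengths.get(i, {}).get(j)
                    if expect is None:
                        assert phi[i, j] == -1
                    else:
                        assert phi[i, j] == min(expect, hop_max)
                        assert plen[i, j] == min(expect, hop_max)
            assert np.array_equal(phi, phi.T)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            floyd_warshall_paths(0, [], 5)
        with pytest.raises(ValueError):
            floyd_warshall_paths(3, [], 0)


def test_shell_graph_cache_roundtrip(tmp_path, toy_complex):
    graphs, _ = build_all_shells(toy_complex, ShellLayout(3.0, 1.0, 3))
    path = tmp_path / "cache.npz"
    save_shell_graphs(graphs, path)
    back = load_shell_graphs(path)
    assert len(back) == 3
    for a, b in zip(graphs, back):
        np.testing.assert_array_equal(a.node_features, b.node_features)
        np.testing.assert_array_equal(a.phi, b.phi)
        np.testing.assert_array_equal(a.path_edge_ids, b.path_edge_ids)
        assert a.dist_max == b.dist_max
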