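import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from loopstates import (
    Conformer,
    DCCMatrix,
    Trajectory,
    build_network,
    covariance_pca,
    dcc_matrix,
    path_delta_ranking,
    rmsf,
    shortest_paths,
    simulate_correlated_trajectory,
)
from loopstates.structure_io import TopologyError

from conftest import bead_residue


def chain_model(n=12, spacing=3.8):
    """Helical bead chain (non-collinear, so rigid-body alignment is well posed)."""
    turn, rise = 100.0 * np.pi / 180.0, 1.5
    radius = spacing / (2 * np.sin(turn / 2)) * 0.6
    residues = [
        bead_residue([radius * np.cos(i * turn), radius * np.sin(i * turn), i * rise],
                     number=i + 1)
        for i in range(n)
    ]
    return Conformer(model_id=1, residues=residues)


def static_trajectory(model, n_frames=20):
    frames = [Conformer(model_id=t + 1, residues=model.residues) for t in range(n_frames)]
    return Trajectory(frames=frames)


def displaced_trajectory(base, displacements):
    """Frames where residue i of frame t is shifted by displacements[t, i]."""
    from loopstates.structure_io import Atom, Residue

    frames = []
    for t in range(displacements.shape[0]):
        residues = []
        for i, res in enumerate(base.residues):
            atoms = [Atom(name=a.name, element=a.element,
                          position=a.position + displacements[t, i])
                     for a in res.atoms]
            residues.append(Residue(chain=res.chain, number=res.number,
                                    name=res.name, atoms=atoms))
        frames.append(Conformer(model_id=t + 1, residues=residues))
    return Trajectory(frames=frames)


class TestTrajectory:
    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            Trajectory(frames=[chain_model()])

    def test_topology_must_match(self):
        a = chain_model(5)
        b = chain_model(6)
        with pytest.raises(TopologyError):
            Trajectory(frames=[a, b])


class TestRMSF:
    def test_static_trajectory_is_zero(self):
        values = rmsf(static_trajectory(chain_model()))
        np.testing.assert_allclose(values, 0.0, atol=1e-12)

    def test_isotropic_jitter_matches_analytic_value(self):
        sigma = 0.5
        base = chain_model(20)
        rng = np.random.default_rng(90)
        disp = np.zeros((5000, 20, 3))
        disp[:, 7, :] = rng.normal(0.0, sigma, size=(5000, 3))
        traj = displaced_trajectory(base, disp)
        values = rmsf(traj, align=False)  # alignment is exercised separately
        assert values[7] == pytest.approx(np.sqrt(3.0) * sigma, rel=0.03)

    def test_rigid_rotation_removed_by_alignment(self):
        base = chain_model(10)
        coords = base.coords()
        frames_disp = []
        rng = np.random.default_rng(91)
        for _ in range(30):
            rot = Rotation.random(rng=rng).as_matrix()
            frames_disp.append(coords @ rot.T + rng.normal(size=3) - coords)
        traj = displaced_trajectory(base, np.array(frames_disp))
        values = rmsf(traj, align=True)
        np.testing.assert_allclose(values, 0.0, atol=1e-6)


class TestDCC:
    def test_diagonal_is_one_and_symmetric(self):
        traj = simulate_correlated_trajectory(chain_model(8), [], 100, 0.3, seed=92)
        mat = dcc_matrix(traj)
        np.testing.assert_allclose(np.diag(mat.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)

    def test_identical_and_negated_series(self):
        base = chain_model(3)
        rng = np.random.default_rng(93)
        series = rng.normal(size=(200, 3))
        disp = np.zeros((200, 3, 3))
        disp[:, 0, :] = series
        disp[:, 1, :] = series          # identical motion
        disp[:, 2, :] = -series         # antithetic motion
        mat = dcc_matrix(displaced_trajectory(base, disp), align=False)
        assert mat.values[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert mat.values[0, 2] == pytest.approx(-1.0, abs=1e-9)

    def test_independent_residues_are_uncorrelated(self):
        traj = simulate_correlated_trajectory(chain_model(10), [], 2000, 0.5, seed=94)
        mat = dcc_matrix(traj, align=False)
        off = mat.values[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_zero_variance_residue_zeroed(self):
        base = chain_model(4)
        rng = np.random.default_rng(95)
        disp = rng.normal(size=(100, 4, 3))
        disp[:, 2, :] = 0.0
        mat = dcc_matrix(displaced_trajectory(base, disp), align=False)
        assert mat.values[2, 2] == 1.0
        np.testing.assert_allclose(np.delete(mat.values[2], 2), 0.0)

    def test_rigid_motion_invariance_with_alignment(self):
        base = chain_model(6)
        traj = simulate_correlated_trajectory(base, [([0, 1], 0.8)], 400, 0.2, seed=96)
        mat_plain = dcc_matrix(traj, align=True)
        rng = np.random.default_rng(97)
        rotated_disp = []
        x = traj.coords(None)
        for t in range(x.shape[0]):
            rot = Rotation.random(rng=rng).as_matrix()
            rotated_disp.append(x[t] @ rot.T + rng.normal(size=3) - base.coords())
        mat_moved = dcc_matrix(displaced_trajectory(base, np.array(rotated_disp)),
                               align=True)
        np.testing.assert_allclose(mat_moved.values, mat_plain.values, atol=0.05)

    def test_difference_map_is_elementwise(self):
        t1 = simulate_correlated_trajectory(chain_model(5), [([0, 1], 0.9)], 200, 0.3, seed=98)
        t2 = simulate_correlated_trajectory(chain_model(5), [], 200, 0.3, seed=99)
        m1, m2 = dcc_matrix(t1), dcc_matrix(t2)
        diff = m1 - m2
        np.testing.assert_allclose(diff.values, m1.values - m2.values)


class TestPCA:
    def test_planted_collective_mode_dominates(self):
        base = chain_model(15)
        rng = np.random.default_rng(100)
        direction = np.tile([1.0, 0.0, 0.0], (15, 1))
        amplitude = rng.normal(0.0, 1.0, size=500)
        disp = amplitude[:, None, None] * direction[None, :, :]
        disp += rng.normal(0.0, 0.05, size=disp.shape)  # small independent noise
        traj = displaced_trajectory(base, disp)
        result = covariance_pca(traj, align=False)
        assert result.variance_fraction(0) >= 0.95

    def test_eigenvalue_sum_equals_covariance_trace(self):
        traj = simulate_correlated_trajectory(chain_model(8), [([0, 1, 2], 0.7)],
                                              100, 0.4, seed=101)
        result = covariance_pca(traj, align=False)
        x = traj.coords(None)
        flat = x.reshape(x.shape[0], -1)
        flat = flat - flat.mean(axis=0)
        trace = np.trace(flat.T @ flat / (flat.shape[0] - 1))
        assert result.eigenvalues.sum() == pytest.approx(trace, rel=1e-6)

    def test_static_trajectory_has_zero_spectrum(self):
        result = covariance_pca(static_trajectory(chain_model(6)))
        np.testing.assert_allclose(result.eigenvalues, 0.0, atol=1e-12)

    def test_modes_are_orthonormal(self):
        traj = simulate_correlated_trajectory(chain_model(5), [], 60, 0.3, seed=102)
        result = covariance_pca(traj, align=False)
        gram = result.components.T @ result.components
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-9)


def two_residue_network(c_value, spacing=3.0):
    model = Conformer(model_id=1, residues=[
        bead_residue([0, 0, 0], number=1), bead_residue([spacing, 0, 0], number=2)])
    values = np.array([[1.0, c_value], [c_value, 1.0]])
    dcc = DCCMatrix(values=values, residue_index=[r.key for r in model.residues])
    return build_network(model, dcc, cutoff=4.5)


class TestBuildNetwork:
    def test_perfect_correlation_gives_zero_weight(self):
        net = two_residue_network(1.0)
        assert net[("A", 1, "")][("A", 2, "")]["weight"] == pytest.approx(0.0)

    def test_no_edge_beyond_cutoff(self):
        net = two_residue_network(1.0, spacing=10.0)
        assert net.number_of_edges() == 0

    def test_inverse_e_correlation_gives_unit_weight(self):
        net = two_residue_network(np.exp(-1.0))
        assert net[("A", 1, "")][("A", 2, "")]["weight"] == pytest.approx(1.0)

    def test_weight_strictly_decreasing_in_correlation(self):
        weights = []
        for c in (0.2, 0.4, 0.6, 0.8, 0.99):
            net = two_residue_network(c)
            weights.append(net[("A", 1, "")][("A", 2, "")]["weight"])
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_anticorrelation_uses_magnitude(self):
        assert (two_residue_network(-0.5)[("A", 1, "")][("A", 2, "")]["weight"]
                == pytest.approx(-np.log(0.5)))

    def test_invalid_cutoff_rejected(self):
        model = chain_model(2)
        dcc = DCCMatrix(values=np.eye(2), residue_index=[r.key for r in model.residues])
        with pytest.raises(ValueError):
            build_network(model, dcc, cutoff=0.0)


def brute_force_k_shortest(g, source, target, k):
    """Enumerate every simple path and keep the k shortest lengths."""
    lengths = []
    for path in nx.all_simple_paths(g, source, target):
        lengths.append(sum(g[u][v]["weight"] for u, v in zip(path, path[1:])))
    return sorted(lengths)[:k]


def random_weighted_graph(seed, n=8, p=0.45):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(("A", i, "") for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(("A", i, ""), ("A", j, ""),
                           weight=float(rng.uniform(0.1, 3.0)))
    return g


class TestShortestPaths:
    def test_direct_edge_beats_detour(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("a", "c", weight=1.5)
        g.add_edge("c", "b", weight=1.5)
        ps = shortest_paths(g, "a", "b", k=2)
        assert ps.paths[0] == ["a", "b"]
        assert ps.lengths[0] == pytest.approx(1.0)

    def test_k_one_is_dijkstra(self):
        g = random_weighted_graph(1)
        ps = shortest_paths(g, ("A", 0, ""), ("A", 7, ""), k=1)
        expected = nx.dijkstra_path_length(g, ("A", 0, ""), ("A", 7, ""))
        assert len(ps.paths) == 1
        assert ps.lengths[0] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        g = random_weighted_graph(seed)
        source, target = ("A", 0, ""), ("A", 7, "")
        if not nx.has_path(g, source, target):
            ps = shortest_paths(g, source, target, k=5)
            assert not ps.reachable
            return
        ps = shortest_paths(g, source, target, k=5)
        oracle = brute_force_k_shortest(g, source, target, 5)
        np.testing.assert_allclose(ps.lengths, oracle[: len(ps.lengths)], rtol=1e-12)
        assert np.all(np.diff(ps.lengths) >= -1e-12)

    def test_disconnected_pair_flagged(self):
        g = nx.Graph()
        g.add_node("a"); g.add_node("b")
        ps = shortest_paths(g, "a", "b")
        assert not ps.reachable and ps.paths == []

    def test_unknown_node_raises(self):
        g = random_weighted_graph(2)
        with pytest.raises(KeyError):
            shortest_paths(g, ("A", 0, ""), ("Z", 99, ""))

    @pytest.mark.parametrize("seed", range(5))
    def test_triangle_property_of_optimal_lengths(self, seed):
        g = random_weighted_graph(seed, n=7, p=0.6)
        nodes = [n for n in g if nx.has_path(g, ("A", 0, ""), n)]
        for a, b, c in itertools.islice(itertools.combinations(nodes, 3), 10):
            if not (nx.has_path(g, a, b) and nx.has_path(g, b, c) and nx.has_path(g, a, c)):
                continue
            lab = nx.dijkstra_path_length(g, a, b)
            lbc = nx.dijkstra_path_length(g, b, c)
            lac = nx.dijkstra_path_length(g, a, c)
            assert lac <= lab + lbc + 1e-12


class TestPathDeltaRanking:
    def test_identical_networks_give_zero_delta(self):
        g = random_weighted_graph(3)
        pairs = [(("A", 0, ""), ("A", 7, "")), (("A", 1, ""), ("A", 6, ""))]
        pairs = [p for p in pairs if nx.has_path(g, *p)]
        table, _ = path_delta_ranking(g, g, pairs)
        np.testing.assert_allclose(table["delta"].dropna(), 0.0, atol=1e-12)

    def test_strengthened_edge_shortens_paths_through_it(self):
        g = nx.Graph()
        for u, v, w in [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 3.0)]:
            g.add_edge(u, v, weight=w)
        h = g.copy()
        h["a"]["b"]["weight"] = 0.5
        table, _ = path_delta_ranking(g, h, [("a", "c")])
        assert table["delta"].iloc[0] < 0

    def test_planted_pathway_dominates_top_shortened_pairs(self):
        """Strengthening one residue chain's correlations in the variant makes
        pairs along that chain the most-shortened communication routes."""
        base = chain_model(12)
        blocks_wt = [(list(range(12)), 0.3)]
        blocks_var = [(list(range(6)), 0.9), (list(range(6, 12)), 0.3)]
        t_wt = simulate_correlated_trajectory(base, blocks_wt, 600, 0.2, seed=110)
        t_var = simulate_correlated_trajectory(base, blocks_var, 600, 0.2, seed=111)
        nets = []
        for traj in (t_wt, t_var):
            mat = dcc_matrix(traj, align=False)
            nets.append(build_network(base, mat, cutoff=4.5))
        pairs = [(("A", i, ""), ("A", j, ""))
                 for i in range(1, 13) for j in range(i + 2, 13)]
        table, participation = path_delta_ranking(nets[0], nets[1], pairs)
        top = table.head(5)
        in_chain = [row.source[1] <= 6 and row.target[1] <= 6
                    for row in top.itertuples(index=False)]
        assert np.mean(in_chain) >= 0.8
        assert participation.index[0][1] <= 6  # most-used residue lies on the chain
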