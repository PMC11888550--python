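"""Equivariant encoder: message passing, ternary attention, coordinate and
feature updates, SE(3)-equivariance and weight sharing."""

import numpy as np
import pytest

from ternadock import nn
from ternadock.encoder import (
    EncoderConfig,
    distance_constraint_projection,
    encode,
    init_encoder_params,
    intra_messages,
    ternary_attention,
    update_coords,
    update_features,
)
from ternadock.graphs import (AtomNode, apply_random_se3, build_ligand_graph,
                              build_protein_graph)


def small_config(**kw):
    kw.setdefault("n_layers", 2)
    kw.setdefault("hidden_dim", 16)
    return EncoderConfig(**kw)


def activate_coord_updates(params, seed=0):
    """Randomize the zero-initialized phi_x output layers so coordinate
    updates are non-trivial."""
    rng = np.random.default_rng(seed + 99)
    for k in list(params):
        if "/phi_x/W1" in k:
            params[k] = rng.normal(0, 0.2, size=params[k].shape)
    return params


@pytest.fixture(scope="module")
def setup(toy):
    cfg = EncoderConfig(n_layers=2, hidden_dim=16)
    params = activate_coord_updates(init_encoder_params(cfg, seed=0))
    return cfg, params


class TestIntraMessages:
    def test_graph_without_edges_gives_zero_messages(self, setup):
        cfg, params = setup
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        atoms = [AtomNode(atomic_number=6, position=c) for c in coords]
        g = build_ligand_graph(atoms, coords)  # 10 A apart: no edges
        H = np.ones((2, cfg.hidden_dim))
        _, m = intra_messages(params, cfg, 0, "lig", H, coords, g)
        assert np.allclose(np.asarray(m), 0.0)

    def test_messages_invariant_to_rotation(self, setup, toy):
        cfg, params = setup
        g = toy.lig_graph
        H = np.random.default_rng(0).normal(size=(g.n_nodes, cfg.hidden_dim))
        X = g.positions()
        _, m0 = intra_messages(params, cfg, 0, "lig", H, X, g)
        moved, tf = apply_random_se3(g, seed=4)
        _, m1 = intra_messages(params, cfg, 0, "lig", H, moved.positions(), g)
        assert np.abs(np.asarray(m0) - np.asarray(m1)).max() < 1e-5

    def test_frozen_edge_mlp_passes_squared_distance(self):
        # phi_e frozen to read out exactly its squared-distance input slot
        cfg = small_config(n_layers=1)
        params = init_encoder_params(cfg, seed=0)
        d = cfg.hidden_dim
        name = "enc/0/lig/phi_e"
        nn.zero_mlp(params, name)
        # single linear layer equivalent: make first layer identity on the
        # d2 column, second layer sum it out
        W0 = params[name + "/W0"]
        W0[:] = 0.0
        W0[2 * d, :] = 1.0  # the d2 slot follows the two latent blocks
        params[name + "/W1"][:] = np.ones((d, d)) / d  # average the hidden copies
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        atoms = [AtomNode(atomic_number=6, position=c) for c in coords]
        g = build_ligand_graph(atoms, coords)
        H = np.zeros((2, d))
        m_edges, m_nodes = intra_messages(params, cfg, 0, "lig", H, coords, g)
        # silu(4.0) = 4*sigmoid(4); mean over the single neighbour
        expected = 4.0 * 0.5 * (1 + np.tanh(2.0))
        assert np.allclose(np.asarray(m_nodes), expected, atol=1e-10)


class TestTernaryAttention:
    def test_rows_sum_to_one(self, setup, toy):
        cfg, params = setup
        rng = np.random.default_rng(1)
        H = {r: rng.normal(size=(g.n_nodes, cfg.hidden_dim))
             for r, g in (("lig", toy.lig_graph), ("p1", toy.p1_graph),
                          ("p2", toy.p2_graph))}
        for role in ("lig", "p1", "p2"):
            a, mu = ternary_attention(params, cfg, 0, role, H)
            assert np.allclose(np.asarray(a).sum(axis=1), 1.0, atol=1e-6)

    def test_keys_span_other_two_graphs(self, setup, toy):
        cfg, params = setup
        rng = np.random.default_rng(1)
        H = {r: rng.normal(size=(g.n_nodes, cfg.hidden_dim))
             for r, g in (("lig", toy.lig_graph), ("p1", toy.p1_graph),
                          ("p2", toy.p2_graph))}
        a, _ = ternary_attention(params, cfg, 0, "lig", H)
        assert np.asarray(a).shape == (toy.lig_graph.n_nodes,
                                       toy.p1_graph.n_nodes + toy.p2_graph.n_nodes)

    def test_identical_keys_give_uniform_weights(self, setup):
        cfg, params = setup
        d = cfg.hidden_dim
        H = {"lig": np.random.default_rng(0).normal(size=(2, d)),
             "p1": np.ones((3, d)), "p2": np.ones((4, d))}
        a, _ = ternary_attention(params, cfg, 0, "lig", H)
        assert np.allclose(np.asarray(a), 1.0 / 7.0, atol=1e-9)

    def test_closed_form_softmax_two_keys(self):
        # inner products (0, ln 2) -> weights (1/3, 2/3)
        w = nn.softmax(np.array([[0.0, np.log(2.0)]]))
        assert np.allclose(w, [[1 / 3, 2 / 3]])


class TestUpdateCoords:
    def _two_node_graph(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        atoms = [AtomNode(atomic_number=6, position=c) for c in coords]
        return build_ligand_graph(atoms, coords), coords

    def test_frozen_phi_x_zero_is_identity(self):
        cfg = small_config(n_layers=1)
        params = init_encoder_params(cfg, seed=0)
        nn.zero_mlp(params, "enc/0/lig/phi_x")
        g, coords = self._two_node_graph()
        m_edges = np.ones((g.n_edges, cfg.hidden_dim))
        out = update_coords(params, cfg, 0, "lig", coords, g, m_edges)
        assert np.array_equal(np.asarray(out), coords)

    def test_hand_evaluated_unit_scale_update(self):
        # phi_x frozen to 1: node 0 moves one unit away from node 1
        cfg = small_config(n_layers=1)
        params = init_encoder_params(cfg, seed=0)
        nn.constant_mlp(params, "enc/0/lig/phi_x", 1.0)
        g, coords = self._two_node_graph()
        m_edges = np.zeros((g.n_edges, cfg.hidden_dim))
        out = np.asarray(update_coords(params, cfg, 0, "lig", coords, g, m_edges))
        assert np.allclose(out[0], [-1.0, 0, 0], atol=1e-12)
        assert np.allclose(out[1], [3.0, 0, 0], atol=1e-12)

    def test_equivariance_under_rigid_motion(self, setup, toy):
        cfg, params = setup
        g = toy.lig_graph
        X = g.positions()
        m_edges = np.random.default_rng(0).normal(size=(g.n_edges, cfg.hidden_dim))
        out0 = np.asarray(update_coords(params, cfg, 0, "lig", X, g, m_edges))
        moved, tf = apply_random_se3(g, seed=13)
        out1 = np.asarray(update_coords(params, cfg, 0, "lig",
                                        moved.positions(), g, m_edges))
        assert np.abs(out1 - tf.apply(out0)).max() < 1e-4

    def test_coincident_nodes_skip_contribution(self):
        cfg = small_config(n_layers=1)
        params = init_encoder_params(cfg, seed=0)
        nn.constant_mlp(params, "enc/0/lig/phi_x", 1.0)
        coords = np.zeros((2, 3))
        atoms = [AtomNode(atomic_number=6, position=c) for c in coords]
        g = build_ligand_graph(atoms, coords)
        m_edges = np.zeros((g.n_edges, cfg.hidden_dim))
        out = np.asarray(update_coords(params, cfg, 0, "lig", coords, g, m_edges))
        assert np.all(np.isfinite(out)) and np.allclose(out, 0.0)


class TestUpdateFeatures:
    @pytest.mark.parametrize("beta,expect", [(0.0, "unchanged"), (1.0, "phi")])
    def test_beta_limits(self, beta, expect):
        cfg = small_config(n_layers=1, beta=beta)
        params = init_encoder_params(cfg, seed=0)
        nn.constant_mlp(params, "enc/0/lig/phi_h", 7.0)
        H = np.random.default_rng(0).normal(size=(3, cfg.hidden_dim))
        zeros = np.zeros_like(H)
        out = np.asarray(update_features(params, cfg, 0, "lig", H, zeros, zeros, zeros))
        if expect == "unchanged":
            assert np.allclose(out, H)
        else:
            assert np.allclose(out, 7.0)

    def test_half_beta_is_midpoint_of_constant(self):
        cfg = small_config(n_layers=1, beta=0.5)
        params = init_encoder_params(cfg, seed=0)
        nn.constant_mlp(params, "enc/0/lig/phi_h", 4.0)
        H = np.full((2, cfg.hidden_dim), 2.0)
        zeros = np.zeros_like(H)
        out = np.asarray(update_features(params, cfg, 0, "lig", H, zeros, zeros, zeros))
        assert np.allclose(out, 3.0)


class TestEncode:
    def test_independent_rigid_motions_equivariance(self, toy):
        """Core symmetry: each graph's output coordinates follow that graph's
        input motion; all latents are invariant (10 random trials)."""
        cfg = small_config()
        params = activate_coord_updates(init_encoder_params(cfg, seed=3))
        base = encode(params, toy.lig_graph, toy.p1_graph, toy.p2_graph, cfg)
        graphs = {"lig": toy.lig_graph, "p1": toy.p1_graph, "p2": toy.p2_graph}
        for trial in range(10):
            moved, tfs = {}, {}
            for i, (r, g) in enumerate(graphs.items()):
                moved[r], tfs[r] = apply_random_se3(g, seed=100 * trial + i)
            out = encode(params, moved["lig"], moved["p1"], moved["p2"], cfg)
            for r in graphs:
                dev = np.abs(np.asarray(out.X[r])
                             - tfs[r].apply(np.asarray(base.X[r]))).max()
                assert dev < 1e-4, f"{r} coordinates broke equivariance: {dev}"
                hdev = np.abs(np.asarray(out.H[r]) - np.asarray(base.H[r])).max()
                assert hdev < 1e-4, f"{r} latents broke invariance: {hdev}"

    def test_shared_protein_weights_single_store(self):
        cfg = small_config(shared_protein_weights=True)
        params = init_encoder_params(cfg, seed=0)
        assert "enc/0/prot/phi_e/W0" in params
        assert "enc/0/p1/phi_e/W0" not in params
        cfg2 = small_config(shared_protein_weights=False)
        params2 = init_encoder_params(cfg2, seed=0)
        assert "enc/0/p1/phi_e/W0" in params2 and "enc/0/p2/phi_e/W0" in params2

    def test_deterministic_given_seeded_init(self, toy):
        cfg = small_config()
        p1 = init_encoder_params(cfg, seed=7)
        p2 = init_encoder_params(cfg, seed=7)
        s1 = encode(p1, toy.lig_graph, toy.p1_graph, toy.p2_graph, cfg)
        s2 = encode(p2, toy.lig_graph, toy.p1_graph, toy.p2_graph, cfg)
        for r in ("lig", "p1", "p2"):
            assert np.array_equal(np.asarray(s1.X[r]), np.asarray(s2.X[r]))
            assert np.array_equal(np.asarray(s1.H[r]), np.asarray(s2.H[r]))

    def test_all_phi_zero_is_identity_on_coordinates(self, toy):
        cfg = small_config()
        params = init_encoder_params(cfg, seed=0)
        for k in list(params):
            if "/phi_x/" in k and (k.endswith("W0") or k.endswith("W1")
                                   or k.endswith("b0") or k.endswith("b1")):
                params[k] = np.zeros_like(params[k])
        out = encode(params, toy.lig_graph, toy.p1_graph, toy.p2_graph, cfg)
        assert np.allclose(np.asarray(out.X["lig"]), toy.lig_graph.positions())
        assert np.allclose(np.asarray(out.X["p1"]), toy.p1_graph.positions())

    def test_cross_message_in_row_space_of_WH(self, toy):
        cfg = small_config(n_layers=1)
        params = init_encoder_params(cfg, seed=0)
        rng = np.random.default_rng(0)
        H = {r: rng.normal(size=(g.n_nodes, cfg.hidden_dim))
             for r, g in (("lig", toy.lig_graph), ("p1", toy.p1_graph),
                          ("p2", toy.p2_graph))}
        a, mu = ternary_attention(params, cfg, 0, "lig", H)
        W = params["enc/0/lig/W"]
        H_kv = nn.layer_norm(np.concatenate([H["p1"], H["p2"]], axis=0))
        VH = H_kv @ W.T
        # mu rows are convex combinations of VH rows: rank check
        stacked = np.vstack([VH, np.asarray(mu)])
        assert np.linalg.matrix_rank(stacked, tol=1e-8) == \
            np.linalg.matrix_rank(VH, tol=1e-8)


def test_distance_constraint_projection_restores_local_geometry():
    rng = np.random.default_rng(0)
    steps = rng.normal(size=(5, 3))
    steps = 1.5 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
    ref = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    distorted = ref + rng.normal(scale=0.3, size=ref.shape)
    fixed = np.asarray(distance_constraint_projection(distorted, ref))
    dref = np.linalg.norm(np.diff(ref, axis=0), axis=1)
    dfix = np.linalg.norm(np.diff(fixed, axis=0), axis=1)
    ddis = np.linalg.norm(np.diff(distorted, axis=0), axis=1)
    assert np.abs(dfix - dref).max() < np.abs(ddis - dref).max()
    assert np.abs(dfix - dref).max() < 0.05
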