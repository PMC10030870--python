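"""Neural reparametrizations: forward passes, chain-rule gradients, training."""

import numpy as np
import pytest

import neulay as nl
from neulay.energy import EnergyParams
from neulay.fdl import StopRule
from neulay.models import (
    NeuLay2Params,
    NodeMLPParams,
    init_params,
    loss_param_gradient,
    neulay2_forward,
    nodemlp_forward,
)
from neulay.spectral import operator_view


class TestNodeMLPForward:
    def test_zero_weights_zero_output(self):
        p = NodeMLPParams(np.ones((4, 3)), np.zeros((3, 2)), np.zeros(2), sigma="tanh")
        assert np.all(nodemlp_forward(p) == 0)

    def test_affine_identity(self):
        z = np.array([[1.0, 2.0, 0.0], [3.0, 4.0, 0.0]])
        w = np.eye(3)[:, :2]
        c = np.array([0.5, -0.5])
        p = NodeMLPParams(z, w, c, sigma="identity")
        assert np.allclose(nodemlp_forward(p), z[:, :2] + c)

    def test_matches_independent_oracle(self, rng):
        z = rng.normal(size=(10, 6))
        w = rng.normal(size=(6, 3))
        b = rng.normal(size=3)
        out = nodemlp_forward(NodeMLPParams(z, w, b, sigma="tanh"))
        oracle = np.tanh(np.array([[zr @ w[:, k] + b[k] for k in range(3)] for zr in z]))
        assert np.abs(out - oracle).max() < 1e-9

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            NodeMLPParams(np.zeros((4, 2)), np.zeros((3, 2)), np.zeros(2))


class TestNeuLay2Forward:
    def test_pass_through_z_block(self, small_er):
        n = small_er.n_nodes
        h, h1, h2, d = 5, 4, 3, 3
        op = operator_view(small_er, "full")
        z = np.random.default_rng(0).normal(size=(n, h))
        w = np.zeros((h + h1 + h2, d))
        w[:d, :d] = np.eye(d)  # project Z's first d columns through
        p = NeuLay2Params(
            z, np.zeros((h, h1)), np.zeros((h1, h2)), w, np.zeros(d),
            sigma_hidden="tanh", sigma_out="identity",
        )
        assert np.allclose(neulay2_forward(op, p), z[:, :d])

    def test_single_isolated_node(self):
        import networkx as nx

        nxg = nx.Graph()
        nxg.add_node(0)
        g = nl.Graph.from_networkx(nxg)
        op = operator_view(g, "full")  # f(A) = [[1]]
        assert np.allclose(op.dense(), [[1.0]])
        p = init_params(1, (2, 2, 2, 3), seed=0)
        x = neulay2_forward(op, p)
        # hand computation: G1 = tanh(Z W1), G2 = tanh(G1 W2), X = [Z|G1|G2] W + b
        g1 = np.tanh(p.Z @ p.W1)
        g2 = np.tanh(g1 @ p.W2)
        by_hand = np.concatenate([p.Z, g1, g2], axis=1) @ p.W + p.b
        assert np.allclose(x, by_hand)

    def test_permutation_equivariance(self):
        g = nl.er_graph(20, 0.25, seed=8)
        op = operator_view(g, "full")
        p = init_params(20, (6, 5, 4, 3), seed=1)
        x = neulay2_forward(op, p)
        perm = np.random.default_rng(2).permutation(20)
        a_perm = g.adjacency.toarray()[np.ix_(perm, perm)]
        import scipy.sparse as sp

        g_perm = nl.Graph(tuple(range(20)), sp.csr_matrix(a_perm))
        op_perm = operator_view(g_perm, "full")
        p_perm = NeuLay2Params(
            p.Z[perm], p.W1, p.W2, p.W, p.b,
            sigma_hidden=p.sigma_hidden, sigma_out=p.sigma_out,
        )
        assert np.allclose(neulay2_forward(op_perm, p_perm), x[perm], atol=1e-10)


class TestInitParams:
    def test_deterministic(self):
        a = init_params(10, (4, 4, 4, 3), seed=9)
        b = init_params(10, (4, 4, 4, 3), seed=9)
        for ta, tb in zip(a.tensors(), b.tensors()):
            assert np.array_equal(ta, tb)

    def test_finite_initial_loss_many_seeds(self):
        g = nl.er_graph(100, 0.05, seed=0)
        op = operator_view(g, "full")
        p = EnergyParams().resolve(100)
        for seed in range(20):
            theta = init_params(100, (50, 50, 50, 3), seed=seed)
            x = neulay2_forward(op, theta)
            assert np.isfinite(nl.total_loss(g, nl.Layout(x), p))

    def test_zero_scale_degenerate(self):
        theta = init_params(5, (4, 4, 4, 3), seed=0, scale=0.0)
        assert np.all(theta.Z == 0)

    def test_model_variants(self):
        assert isinstance(init_params(5, (4, 4, 4, 3), model="nodemlp", seed=0), NodeMLPParams)
        one_layer = init_params(5, (4, 4, 4, 3), model="neulay", seed=0)
        assert one_layer.widths == (4, 4, 0)


class TestChainRuleGradients:
    @pytest.mark.parametrize("model", ["nodemlp", "neulay", "neulay2"])
    def test_matches_finite_differences(self, model):
        g = nl.er_graph(10, 0.4, seed=5)
        op = None if model == "nodemlp" else operator_view(g, "full")
        eparams = EnergyParams(a_n=0.6, r0=0.3).resolve(10)
        theta = init_params(10, (5, 4, 3, 3), seed=11, model=model)

        def loss():
            x = nodemlp_forward(theta) if model == "nodemlp" else neulay2_forward(op, theta)
            return nl.total_loss(g, nl.Layout(x), eparams, "brute")

        grads = loss_param_gradient(g, theta, eparams, op, method="brute")
        scale = max(np.abs(gt).max() for gt in grads if gt.size)
        h = 1e-5
        for tensor, grad in zip(theta.tensors(), grads):
            for idx in np.ndindex(tensor.shape):
                tensor[idx] += h
                fp = loss()
                tensor[idx] -= 2 * h
                fm = loss()
                tensor[idx] += h
                fd = (fp - fm) / (2 * h)
                # relative to the overall gradient scale: near-zero entries
                # (e.g. the bias of a translation-invariant loss) are noise
                assert abs(grad[idx] - fd) < 1e-4 * max(scale, 1.0)

    def test_saturating_output_gradients(self):
        g = nl.er_graph(8, 0.5, seed=6)
        op = operator_view(g, "full")
        eparams = EnergyParams(a_n=0.6, r0=0.3).resolve(8)
        theta = init_params(8, (4, 3, 3, 2), seed=12, sigma_out="tanh")
        grads = loss_param_gradient(g, theta, eparams, op, method="brute")
        h = 1e-5
        t = theta.W1
        gt = grads[1]
        scale = max(np.abs(x).max() for x in grads)
        for idx in np.ndindex(t.shape):
            t[idx] += h
            fp = nl.total_loss(g, nl.Layout(neulay2_forward(op, theta)), eparams, "brute")
            t[idx] -= 2 * h
            fm = nl.total_loss(g, nl.Layout(neulay2_forward(op, theta)), eparams, "brute")
            t[idx] += h
            assert abs(gt[idx] - (fp - fm) / (2 * h)) < 1e-4 * max(scale, 1.0)


class TestReductionConsistency:
    def test_zero_width_second_layer_is_one_gcn_layer(self):
        g = nl.er_graph(12, 0.3, seed=3)
        op = operator_view(g, "full")
        rng = np.random.default_rng(4)
        z = rng.normal(size=(12, 5))
        w1 = rng.normal(size=(5, 4))
        w = rng.normal(size=(9, 3))
        b = rng.normal(size=3)
        one = NeuLay2Params(z, w1, np.zeros((4, 0)), w, b)
        g1 = np.tanh(op.dense() @ z @ w1)
        expected = np.concatenate([z, g1], axis=1) @ w + b
        assert np.allclose(neulay2_forward(op, one), expected)

    def test_zero_gcn_widths_behave_like_embedding_only(self):
        g = nl.er_graph(12, 0.3, seed=3)
        op = operator_view(g, "full")
        rng = np.random.default_rng(5)
        z = rng.normal(size=(12, 5))
        w = rng.normal(size=(5, 3))
        b = rng.normal(size=3)
        gcn_free = NeuLay2Params(
            z, np.zeros((5, 0)), np.zeros((0, 0)), w, b, sigma_out="identity"
        )
        mlp = NodeMLPParams(z, w, b, sigma="identity")
        assert np.allclose(neulay2_forward(op, gcn_free), nodemlp_forward(mlp))


class TestTraining:
    def test_single_node_loss_zero(self):
        import networkx as nx

        nxg = nx.Graph()
        nxg.add_node(0)
        g = nl.Graph.from_networkx(nxg)
        _, traj, _ = nl.train_model(
            g, "neulay2", EnergyParams(), StopRule(max_steps=50), seed=0,
            hidden=(2, 2, 2),
        )
        assert all(e == 0.0 for e in traj.energies)

    def test_loss_nonincreasing_small_gd_rate(self):
        g = nl.er_graph(20, 0.3, seed=2)
        _, traj, _ = nl.train_model(
            g, "neulay2", EnergyParams(epsilon=5e-5), StopRule(max_steps=400),
            seed=2, hidden=(10, 10, 10), optimizer="gd",
        )
        e = np.array(traj.energies)
        violations = np.sum(np.diff(e) > 1e-12 * np.abs(e[:-1]))
        assert violations <= max(1, int(0.001 * len(e)))

    def test_training_reduces_loss(self):
        g = nl.cubic_lattice(3)
        _, traj, theta = nl.train_model(
            g, "neulay2", EnergyParams(), StopRule(max_steps=500), seed=1,
            optimizer="adam",
        )
        assert traj.energies[-1] < 0.5 * traj.energies[0]
        assert isinstance(theta, NeuLay2Params)

    def test_trajectory_comparable_to_fdl(self):
        # the recorded loss is the loss of the induced layout, so FDL and
        # reparametrized runs share one objective
        g = nl.cubic_lattice(3)
        lay = nl.init_layout(27, 3, 1.0, seed=0)
        e_direct = nl.total_loss(g, lay, EnergyParams().resolve(27))
        _, traj, _ = nl.train_model(
            g, "neulay2", EnergyParams(), StopRule(max_steps=30), seed=0,
            optimizer="adam",
        )
        assert traj.energies[0] == pytest.approx(
            nl.total_loss(
                g,
                nl.Layout(
                    neulay2_forward(
                        operator_view(g, "full"), init_params(27, (27, 27, 27, 3), seed=0)
                    )
                ),
                EnergyParams().resolve(27),
            )
        )
        assert np.isfinite(e_direct)


class TestCheckpoint:
    def test_round_trip_neulay2(self, tmp_path):
        theta = init_params(8, (4, 3, 2, 3), seed=7)
        path = tmp_path / "ckpt.json"
        from neulay.models import load_params, save_params

        save_params(theta, path)
        back = load_params(path)
        for a, b in zip(theta.tensors(), back.tensors()):
            assert np.array_equal(a, b)
        g = nl.er_graph(8, 0.4, seed=1)
        op = operator_view(g, "full")
        assert np.allclose(neulay2_forward(op, theta), neulay2_forward(op, back))

    def test_round_trip_nodemlp(self, tmp_path):
        from neulay.models import load_params, save_params

        theta = init_params(6, (4, 0, 0, 2), seed=3, model="nodemlp")
        path = tmp_path / "ckpt.json"
        save_params(theta, path)
        back = load_params(path)
        assert np.allclose(nodemlp_forward(theta), nodemlp_forward(back))

    def test_version_check(self, tmp_path):
        import json

        from neulay.models import load_params

        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"checkpoint_version": 99, "model": "nodemlp", "tensors": {}}))
        with pytest.raises(ValueError, match="version"):
            load_params(path)
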