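"""Layer semantics, architecture wiring, parameter arithmetic, checkpoints."""

import numpy as np
import pytest

from bindnode.gnn import (
    ARCHITECTURES,
    BindingGNN,
    GATv2Layer,
    GCNLayer,
    GraphContext,
    ModelConfig,
    SAGELayer,
    count_model_parameters,
    count_parameters,
    count_reference_cnn_parameters,
    load_checkpoint,
    parameter_reduction_percent,
    save_checkpoint,
)
from bindnode.graph import ResidueGraph
from bindnode._autograd import Tensor


def star_graph(weights):
    """Node 0 connected to nodes 1..k with the given edge weights."""
    k = len(weights)
    edges = np.array([[0, j + 1] for j in range(k)])
    return ResidueGraph(k + 1, edges, np.asarray(weights, dtype=float), 5.0)


class TestSAGELayer:
    def _scalar_layer(self):
        layer = SAGELayer("s", 1, 1, np.random.default_rng(0))
        layer.W_self.value[:] = 0.0
        layer.W_nbr.value[:] = 1.0
        layer.b.value[:] = 0.0
        return layer

    def test_unweighted_mean(self):
        layer = self._scalar_layer()
        g = star_graph([1.0, 1.0])
        h = Tensor(np.array([[0.0], [1.0], [3.0]]))
        out = layer(h, GraphContext(g)).value
        assert out[0, 0] == pytest.approx(2.0)

    def test_weighted_mean_matches_explicit_loop(self):
        layer = self._scalar_layer()
        g = star_graph([3.0, 1.0])
        h = np.array([[0.0], [1.0], [3.0]])
        out = layer(Tensor(h), GraphContext(g)).value
        # explicit loop oracle
        num = sum(w * h[j + 1, 0] for j, w in enumerate([3.0, 1.0]))
        assert out[0, 0] == pytest.approx(num / 4.0) == pytest.approx(1.5)

    def test_isolated_node_reduces_to_identity(self):
        layer = SAGELayer("s", 2, 2, np.random.default_rng(0))
        layer.W_self.value = np.eye(2)
        layer.W_nbr.value[:] = 7.0  # must not contribute
        layer.b.value[:] = 0.0
        g = ResidueGraph(1, np.empty((0, 2), dtype=int), np.empty(0), 5.0)
        h = np.array([[2.0, -1.0]])
        assert np.allclose(layer(Tensor(h), GraphContext(g)).value, h)


class TestGCNLayer:
    def test_single_node_is_linear_map(self, rng):
        layer = GCNLayer("g", 3, 2, rng)
        g = ResidueGraph(1, np.empty((0, 2), dtype=int), np.empty(0), 5.0)
        h = rng.standard_normal((1, 3))
        expected = h @ layer.W.value + layer.b.value
        assert np.allclose(layer(Tensor(h), GraphContext(g)).value, expected)

    def test_two_node_normalization_by_hand(self, rng):
        layer = GCNLayer("g", 2, 2, rng)
        layer.W.value = np.eye(2)
        layer.b.value[:] = 0.0
        g = ResidueGraph(2, np.array([[0, 1]]), np.array([1.0]), 5.0)
        h = rng.standard_normal((2, 2))
        out = layer(Tensor(h), GraphContext(g)).value
        assert np.allclose(out, (h + h[::-1]) / 2.0)

    def test_no_edges_degenerates_to_per_node_linear(self, rng):
        layer = GCNLayer("g", 3, 3, rng)
        g = ResidueGraph(4, np.empty((0, 2), dtype=int), np.empty(0), 5.0)
        h = rng.standard_normal((4, 3))
        assert np.allclose(
            layer(Tensor(h), GraphContext(g)).value, h @ layer.W.value + layer.b.value
        )


class TestGATv2Layer:
    def test_uniform_logits_give_mean_aggregation(self, rng):
        layer = GATv2Layer("a", 3, 2, rng)
        layer.a.value[:] = 0.0  # all attention logits equal
        layer.b.value[:] = 0.0
        g = star_graph([0.5, 0.9, 0.2])
        h = rng.standard_normal((4, 3))
        out = layer(Tensor(h), GraphContext(g)).value
        gr = h @ layer.W_r.value
        assert np.allclose(out[0], gr[[0, 1, 2, 3]].mean(axis=0))

    def test_single_node_attends_to_itself(self, rng):
        layer = GATv2Layer("a", 3, 2, rng)
        layer.b.value[:] = 0.0
        g = ResidueGraph(1, np.empty((0, 2), dtype=int), np.empty(0), 5.0)
        h = rng.standard_normal((1, 3))
        assert np.allclose(
            layer(Tensor(h), GraphContext(g)).value, h @ layer.W_r.value
        )

    def test_attention_rows_sum_to_one(self, rng):
        """Recomputes α from the layer's own weights with an explicit
        per-node softmax and checks the aggregated output matches."""
        layer = GATv2Layer("a", 4, 3, rng)
        g = star_graph([1.0, 0.3])
        h = rng.standard_normal((3, 4))
        out = layer(Tensor(h), GraphContext(g)).value
        gl, gr = h @ layer.W_l.value, h @ layer.W_r.value
        slope = layer.slope
        for i, nbrs in enumerate([[1, 2, 0], [0, 1], [0, 2]]):
            z = np.array([gl[i] + gr[j] for j in nbrs])
            z = np.where(z > 0, z, slope * z)
            logits = z @ layer.a.value[:, 0]
            alpha = np.exp(logits - logits.max())
            alpha /= alpha.sum()
            assert alpha.sum() == pytest.approx(1.0)
            expected = sum(a * gr[j] for a, j in zip(alpha, nbrs)) + layer.b.value
            assert np.allclose(out[i], expected, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_inputs():
    rng = np.random.default_rng(9)
    L, d = 15, 32
    coords = rng.uniform(0, 15, (L, 3))
    from bindnode.graph import build_graph, compute_distance_map

    graph = build_graph(compute_distance_map(coords), 9.0)
    return rng.standard_normal((L, d)), graph, rng.uniform(0, 1, (L, 20))


@pytest.mark.parametrize("arch", ARCHITECTURES)
@pytest.mark.parametrize("use_dssp", [False, True])
def test_forward_shape_and_sigmoid_range(tiny_inputs, arch, use_dssp):
    x, graph, dssp = tiny_inputs
    cfg = ModelConfig(arch=arch, input_dim=x.shape[1], use_dssp=use_dssp)
    model = BindingGNN(cfg, seed=4)
    probs = model.predict_proba(x, graph, dssp if use_dssp else None)
    assert probs.shape == (x.shape[0], 3)
    assert np.all((probs > 0) & (probs < 1))


def test_use_dssp_without_matrix_is_error(tiny_inputs):
    x, graph, _ = tiny_inputs
    model = BindingGNN(ModelConfig(input_dim=x.shape[1], use_dssp=True), seed=0)
    with pytest.raises(ValueError, match="DSSP"):
        model.forward(x, graph, None)


def test_inference_is_deterministic(tiny_inputs):
    x, graph, _ = tiny_inputs
    model = BindingGNN(ModelConfig(arch="SAGEConvGATMLP", input_dim=x.shape[1]), seed=2)
    p1 = model.predict_proba(x, graph)
    p2 = model.predict_proba(x, graph)
    assert np.allclose(p1, p2, atol=1e-6)


def test_permutation_equivariance(tiny_inputs):
    x, graph, _ = tiny_inputs
    rng = np.random.default_rng(5)
    perm = rng.permutation(graph.n_nodes)
    inv = np.argsort(perm)
    pos = {int(p): k for k, p in enumerate(perm)}
    edges = np.array(
        [sorted((pos[int(i)], pos[int(j)])) for i, j in graph.edges]
    )
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    pgraph = type(graph)(
        graph.n_nodes, edges[order], graph.weights[order], graph.threshold
    )
    for arch in ARCHITECTURES:
        model = BindingGNN(ModelConfig(arch=arch, input_dim=x.shape[1]), seed=8)
        base = model.predict_proba(x, graph)
        permuted = model.predict_proba(x[perm], pgraph)
        assert np.allclose(permuted[inv], base, atol=1e-8), arch


class TestParameterArithmetic:
    def test_sageconv_closed_form(self):
        counts = count_parameters(ModelConfig(arch="SAGEConv", input_dim=1024))
        assert counts.per_layer["sage1"] == 2 * 1024 * 128 + 128 == 262272
        assert counts.per_layer["sage2"] == 2 * 128 * 3 + 3 == 771
        assert counts.total == 263043

    def test_reference_cnn_closed_form(self):
        ref = count_reference_cnn_parameters(1024)
        assert ref.per_layer["conv1"] == 1024 * 128 * 5 + 128
        assert ref.per_layer["conv2"] == 128 * 3 * 5 + 3
        assert ref.total == 657411

    def test_reduction_is_almost_sixty_percent(self):
        red = parameter_reduction_percent(263043, 657411)
        assert red == pytest.approx(59.99, abs=0.01)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    @pytest.mark.parametrize("use_dssp", [False, True])
    def test_closed_form_equals_enumerated_arrays(self, arch, use_dssp):
        cfg = ModelConfig(arch=arch, input_dim=96, use_dssp=use_dssp)
        assert count_parameters(cfg).total == count_model_parameters(
            BindingGNN(cfg, seed=0)
        )

    def test_printed_architecture_dimensions(self):
        cfg = ModelConfig(arch="SAGEConv", input_dim=1024, use_dssp=True)
        assert cfg.entry_dim == 1044
        assert cfg.dssp_dim == 20
        gat = BindingGNN(ModelConfig(arch="SAGEConvGATMLP", input_dim=1024), seed=0)
        assert gat.fc1.W.value.shape[0] == 160
        mlp = BindingGNN(
            ModelConfig(arch="SAGEConvMLP", input_dim=1024, use_dssp=True), seed=0
        )
        assert mlp.fc1.W.value.shape == (148, 32)
        assert mlp.fc2.W.value.shape[0] == 32


def test_checkpoint_round_trip_bit_exact(tiny_inputs, tmp_path):
    x, graph, dssp = tiny_inputs
    cfg = ModelConfig(arch="SAGEConvMLP", input_dim=x.shape[1], use_dssp=True)
    model = BindingGNN(cfg, seed=3)
    save_checkpoint(model, tmp_path / "ckpt")
    loaded = load_checkpoint(tmp_path / "ckpt")
    for name, t in model.parameters().items():
        assert np.array_equal(loaded.parameters()[name].value, t.value)
    assert np.array_equal(
        loaded.predict_proba(x, graph, dssp), model.predict_proba(x, graph, dssp)
    )
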