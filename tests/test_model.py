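"""Architecture and fusion-math tests: the printed shape chain, the
cross-stream residual update, the weighted FC fusion, parameter counting,
and checkpoint round-tripping."""

import numpy as np
import pytest

from duostream import nn
from duostream.model import (
    CANONICAL_CHANNELS,
    BasicBlock,
    CrossStreamBlock,
    ModelSpec,
    build_two_stream,
    classify,
    conv_layer_count,
    count_parameters,
    cross_stream_block_forward,
    fast_spec,
    fc_fusion_forward,
    forward_shapes,
    get_state,
    load_checkpoint,
    save_checkpoint,
    shallow_conv_layer_count,
)
from duostream.preprocess import ViewPair


# ---------------------------------------------------------------------------
# shape chain
# ---------------------------------------------------------------------------

EXPECTED_CHAIN_224 = {
    "conv1": (112, 112, 64),
    "maxpool": (56, 56, 64),
    "conv2": (56, 56, 64),
    "conv3": (28, 28, 128),
    "conv4": (14, 14, 256),
    "conv5": (7, 7, 512),
    "avgpool": (1, 1, 512),
    "fc_1": (128,),
    "fc_2": (32,),
    "concat": (64,),
    "logits": (18,),
}


def test_forward_shapes_224_full_chain():
    spec = ModelSpec(num_classes=18)
    chain = dict(forward_shapes(spec, 224))
    assert chain == EXPECTED_CHAIN_224


def test_conv_layer_counts():
    spec = ModelSpec(num_classes=18)
    assert conv_layer_count(spec) == 17
    assert shallow_conv_layer_count(spec) == 13
    model = build_two_stream(fast_spec(6), rng=0)
    assert len(model.conv_layers("front")) == 17
    assert len(model.conv_layers("back")) == 17
    assert len(model.conv_units("front")) == 17


def test_actual_forward_matches_analytic_chain():
    """Run a real (reduced-channel) forward and check every stage shape."""
    spec = fast_spec(6)
    model = build_two_stream(spec, rng=0)
    cache = {}
    x = np.zeros((1, 3, 32, 32))
    logits = model.forward(x, x, cache=cache)
    chain = dict(forward_shapes(spec, 32))
    h, w, c = chain["conv5"]
    assert cache["stage4_front"].shape == (1, c, h, w)
    assert cache["embedding"].shape == (1, chain["concat"][0])
    assert logits.shape == (1, 6)


def test_canonical_224_forward_stage_shapes():
    """One full-width forward pass at 224 reproduces the printed dimensions."""
    spec = ModelSpec(num_classes=18)
    model = build_two_stream(spec, rng=0).eval()
    cache = {}
    x = np.zeros((1, 3, 224, 224))
    logits = model.forward(x, x, cache=cache)
    assert cache["stage4_front"].shape == (1, 512, 7, 7)
    assert cache["embedding"].shape == (1, 64)
    assert logits.shape == (1, 18)


# ---------------------------------------------------------------------------
# cross-stream residual block
# ---------------------------------------------------------------------------

def _zero_residual(block: BasicBlock):
    block.conv1.weight.data[:] = 0
    block.conv2.weight.data[:] = 0


def test_cross_block_with_zero_residual_is_stream_sum(rng):
    block = CrossStreamBlock(8, 8, 1, rng)
    _zero_residual(block.front)
    _zero_residual(block.back)
    xf = rng.normal(size=(2, 8, 4, 4))
    xb = rng.normal(size=(2, 8, 4, 4))
    of, ob = cross_stream_block_forward(xf, xb, block)
    np.testing.assert_array_equal(of.data, xf + xb)
    np.testing.assert_array_equal(ob.data, xf + xb)


def test_cross_block_equal_inputs_is_single_stream_plus_identity(rng):
    block = CrossStreamBlock(8, 8, 1, rng).eval()
    x = rng.normal(size=(2, 8, 4, 4))
    single = block.front.forward(nn.Tensor(x)).data  # x + F(x)
    of, _ = cross_stream_block_forward(x, x, block)
    np.testing.assert_allclose(of.data, single + x, atol=1e-12)


def test_cross_block_matches_hand_composition(rng):
    """out_p == h(x_p + x_q) + F(x_p) composed manually from the block parts."""
    block = CrossStreamBlock(8, 16, 2, rng).eval()  # downsampling block
    xf = rng.normal(size=(2, 8, 4, 4))
    xb = rng.normal(size=(2, 8, 4, 4))
    of, ob = cross_stream_block_forward(xf, xb, block)
    summed = nn.Tensor(xf + xb)
    ref_f = block.front.shortcut(summed).data + block.front.residual_branch(nn.Tensor(xf)).data
    ref_b = block.back.shortcut(summed).data + block.back.residual_branch(nn.Tensor(xb)).data
    np.testing.assert_allclose(of.data, ref_f, atol=1e-12)
    np.testing.assert_allclose(ob.data, ref_b, atol=1e-12)


def test_cross_block_shape_mismatch_rejected(rng):
    block = CrossStreamBlock(8, 8, 1, rng)
    with pytest.raises(ValueError):
        cross_stream_block_forward(
            rng.normal(size=(1, 8, 4, 4)), rng.normal(size=(1, 8, 5, 5)), block
        )


# ---------------------------------------------------------------------------
# FC fusion
# ---------------------------------------------------------------------------

def test_fc_fusion_identity_g_alpha_third(rng):
    ident = lambda t: t
    yf = rng.normal(size=(3, 32))
    yb = rng.normal(size=(3, 32))
    of, ob = fc_fusion_forward(yf, yb, ident, ident, alpha=1.0 / 3.0)
    np.testing.assert_allclose(of.data, yf + yb / 3.0, atol=1e-15)
    np.testing.assert_allclose(ob.data, yb + yf / 3.0, atol=1e-15)


def test_fc_fusion_alpha_zero_is_independent(rng):
    g1 = nn.Linear(16, 8, rng)
    g2 = nn.Linear(16, 8, rng)
    yf = rng.normal(size=(4, 16))
    yb = rng.normal(size=(4, 16))
    of, ob = fc_fusion_forward(yf, yb, g1.forward, g2.forward, alpha=0.0)
    np.testing.assert_array_equal(of.data, g1.forward(nn.Tensor(yf)).data)
    np.testing.assert_array_equal(ob.data, g2.forward(nn.Tensor(yb)).data)


def test_fc_fusion_symmetry_equal_streams(rng):
    ident = lambda t: t
    y = rng.normal(size=(2, 8))
    alpha = 0.25
    of, ob = fc_fusion_forward(y, y, ident, ident, alpha=alpha)
    np.testing.assert_allclose(of.data, (1 + alpha) * y, atol=1e-15)
    np.testing.assert_array_equal(of.data, ob.data)


def test_fc_fusion_dim_mismatch_rejected(rng):
    with pytest.raises(ValueError):
        fc_fusion_forward(
            rng.normal(size=(2, 8)), rng.normal(size=(2, 9)), lambda t: t, lambda t: t, 0.5
        )


# ---------------------------------------------------------------------------
# network-level properties
# ---------------------------------------------------------------------------

def test_concat_only_streams_are_independent(rng):
    """Without cross terms, the front embedding half ignores the back input."""
    model = build_two_stream(fast_spec(6, mode="concat_only"), rng=0).eval()
    f = rng.normal(size=(1, 3, 32, 32))
    b1 = rng.normal(size=(1, 3, 32, 32))
    b2 = rng.normal(size=(1, 3, 32, 32))
    c1, c2 = {}, {}
    model.forward(f, b1, cache=c1)
    model.forward(f, b2, cache=c2)
    np.testing.assert_array_equal(c1["embedding"].data[:, :16], c2["embedding"].data[:, :16])
    assert not np.array_equal(c1["embedding"].data[:, 16:], c2["embedding"].data[:, 16:])


def test_full_model_couples_streams(rng):
    """With cross-stream terms active, the front half does react to the back view."""
    model = build_two_stream(fast_spec(6, mode="two_stream_full"), rng=0).eval()
    f = rng.normal(size=(1, 3, 32, 32))
    b1 = rng.normal(size=(1, 3, 32, 32))
    b2 = rng.normal(size=(1, 3, 32, 32))
    c1, c2 = {}, {}
    model.forward(f, b1, cache=c1)
    model.forward(f, b2, cache=c2)
    assert not np.array_equal(c1["embedding"].data[:, :16], c2["embedding"].data[:, :16])


def _tie_streams(model):
    """Give both streams (and the head halves) identical weights."""
    for pf, pb in zip(model.stream_front.parameters(), model.stream_back.parameters()):
        pb.data = pf.data.copy()
    model.fc2.weight.data = model.fc1.weight.data.copy()
    model.fc2.bias.data = model.fc1.bias.data.copy()
    model.fc4.weight.data = model.fc3.weight.data.copy()
    model.fc4.bias.data = model.fc3.bias.data.copy()
    d = model.head.weight.data.shape[0] // 2
    model.head.weight.data[d:] = model.head.weight.data[:d].copy()


def test_view_swap_symmetry_with_tied_weights(rng):
    model = build_two_stream(fast_spec(6), rng=0).eval()
    _tie_streams(model)
    f = rng.normal(size=(2, 3, 32, 32))
    b = rng.normal(size=(2, 3, 32, 32))
    out_ab = model.forward(f, b).data
    out_ba = model.forward(b, f).data
    np.testing.assert_allclose(out_ab, out_ba, atol=1e-10)


def test_classify_shapes_and_determinism(rng):
    model = build_two_stream(fast_spec(18), rng=3)
    img = rng.normal(size=(32, 32, 3))
    vp = ViewPair(front=img, back=img.copy())
    logits1, pred1 = classify(model, vp)
    logits2, pred2 = classify(model, vp)
    assert logits1.shape == (18,)
    np.testing.assert_array_equal(logits1, logits2)
    assert pred1 == pred2 == int(np.argmax(logits1))


def test_classify_rejects_unpreprocessed_shapes():
    model = build_two_stream(fast_spec(6), rng=0)
    bad = ViewPair(front=np.zeros((32, 32, 3)), back=np.zeros((32, 32, 3)))
    bad.front = np.zeros((32, 16, 3))  # bypass the pair invariant on purpose
    with pytest.raises(ValueError):
        classify(model, bad)


# ---------------------------------------------------------------------------
# parameter counting and checkpointing
# ---------------------------------------------------------------------------

def test_count_parameters_arithmetic(rng):
    assert nn.Linear(64, 18, rng).weight.data.size + 18 == 64 * 18 + 18 == 1170
    assert nn.Conv2d(3, 64, 7, 2, 3, rng).weight.data.size == 9408


def test_two_stream_has_more_parameters_than_single():
    full = build_two_stream(fast_spec(6), rng=0)
    single = build_two_stream(fast_spec(6, mode="front_only"), rng=0)
    assert count_parameters(full) >= count_parameters(single)


def test_canonical_parameter_count_exceeds_single_resnet():
    """Two unshared 17-conv streams + FC head land near 22 M trainable scalars."""
    n = count_parameters(build_two_stream(ModelSpec(num_classes=18), rng=0))
    assert 20_000_000 < n < 25_000_000


def test_checkpoint_roundtrip_bit_exact(tmp_path, rng):
    model = build_two_stream(fast_spec(6), rng=7)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path, classes=[f"c{i}" for i in range(6)],
                    preprocess_config={"target_size": 32})
    clone, meta = load_checkpoint(path)
    for k, v in get_state(model).items():
        np.testing.assert_array_equal(v, get_state(clone)[k])
    assert meta["classes"] == [f"c{i}" for i in range(6)]
    x = rng.normal(size=(1, 3, 32, 32))
    np.testing.assert_array_equal(
        model.eval().forward(x, x).data, clone.eval().forward(x, x).data
    )


def test_invalid_mode_rejected():
    with pytest.raises(ValueError):
        ModelSpec(num_classes=6, mode="sideways")
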