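"""MMIL network invariants: attention simplex, permutation/duplication
invariance, Kronecker fusion contract, loss oracle and gradient sanity."""

import numpy as np
import pytest

from mmil._autodiff import Tensor, softmax
from mmil.model import (
    LossBatch,
    MMILNet,
    ModelConfig,
    cross_entropy_loss,
    load_checkpoint,
    save_checkpoint,
)


def _net(**kw):
    kw.setdefault("in_dim", 6)
    kw.setdefault("image_repr_dim", 5)
    kw.setdefault("biomarker_repr_dim", 3)
    kw.setdefault("seed", 0)
    return MMILNet(ModelConfig(**kw))


def test_attention_weights_on_simplex_and_single_instance(rng):
    net = _net()
    bag, w = net.attention_pool(rng.normal(size=(7, 6)))
    assert w.data.shape == (7, 1)
    assert np.all(w.data > 0)
    assert np.isclose(w.data.sum(), 1.0, atol=1e-6)

    one_bag, one_w = net.attention_pool(rng.normal(size=(1, 6)))
    assert np.allclose(one_w.data, [[1.0]])
    # single instance: bag representation is that instance's embedding
    X = rng.normal(size=(1, 6))
    bag1, _ = net.attention_pool(X)
    P = net.params
    emb = np.maximum(X @ P["W_embed"].data + P["b_embed"].data, 0)
    assert np.allclose(bag1.data, emb)


def test_attention_permutation_equivariance(rng):
    net = _net()
    X = rng.normal(size=(9, 6))
    perm = rng.permutation(9)
    bag_a, w_a = net.attention_pool(X)
    bag_b, w_b = net.attention_pool(X[perm])
    assert np.allclose(bag_a.data, bag_b.data, atol=1e-10)
    assert np.allclose(w_a.data.ravel()[perm], w_b.data.ravel(), atol=1e-12)


def test_empty_bag_raises(rng):
    with pytest.raises(ValueError, match="empty"):
        _net().attention_pool(np.zeros((0, 6)))


def test_biomarker_encoder_contract(rng):
    net = _net()
    v = rng.random(4)
    a = net.encode_biomarkers(v)
    b = net.encode_biomarkers(v)
    assert np.array_equal(a.data, b.data)
    assert a.data.shape == (1, 3)
    assert np.isfinite(net.encode_biomarkers(np.zeros(4)).data).all()
    with pytest.raises(ValueError, match="biomarkers"):
        net.encode_biomarkers(np.zeros(5))


def test_fusion_length_and_hand_kronecker(rng):
    net = _net(image_repr_dim=1, biomarker_repr_dim=1, gate_enabled=False, in_dim=2)
    fused = net.gated_tensor_fuse(np.array([[2.0]]), np.array([[3.0]]))
    assert np.allclose(fused.data.ravel(), [6.0, 2.0, 3.0, 1.0])

    for d1, d2 in [(32, 8), (4, 4), (1, 7)]:
        net2 = _net(in_dim=4, image_repr_dim=d1, biomarker_repr_dim=d2)
        out = net2.gated_tensor_fuse(rng.normal(size=(1, d1)), rng.normal(size=(1, d2)))
        assert out.data.shape == (1, (d1 + 1) * (d2 + 1))


def test_fusion_preserves_unimodal_subblock_with_unit_gates(rng):
    net = _net(image_repr_dim=4, biomarker_repr_dim=3, gate_enabled=False)
    img = rng.normal(size=(1, 4))
    fused = net.gated_tensor_fuse(img, np.zeros((1, 3))).data.ravel()
    # image entry i pairs with the appended biomarker 1 at column index d2
    sub = fused.reshape(5, 4)[:4, 3]
    assert np.allclose(sub, img.ravel())


def test_fusion_dim_cap_enforced():
    with pytest.raises(ValueError, match="cap"):
        ModelConfig(in_dim=4, image_repr_dim=300, biomarker_repr_dim=300,
                    fusion_dim_cap=1000)


def test_forward_probabilities_sum_to_one_fuzzed(rng):
    net = _net()
    for _ in range(100):
        n = int(rng.integers(1, 12))
        pred = net.forward(rng.normal(size=(n, 6)), rng.random(4))
        p = pred.class_probabilities
        assert np.isclose(p.sum(), 1.0, atol=1e-6) and (p > 0).all()
        assert np.isclose(pred.attention_weights.sum(), 1.0, atol=1e-6)


def test_forward_permutation_and_duplication_invariance(rng):
    net = _net()
    X = rng.normal(size=(8, 6))
    bio = rng.random(4)
    base = net.forward(X, bio).class_probabilities
    perm = net.forward(X[rng.permutation(8)], bio).class_probabilities
    assert np.allclose(base, perm, atol=1e-9)
    # duplicating every instance halves each weight, bag output unchanged
    dup = net.forward(np.vstack([X, X]), bio).class_probabilities
    assert np.allclose(base, dup, atol=1e-9)


def test_image_only_mode_ignores_biomarkers(rng):
    net = _net(mode="image")
    X = rng.normal(size=(5, 6))
    a = net.forward(X, np.zeros(4)).class_probabilities
    b = net.forward(X, np.ones(4) * 0.9).class_probabilities
    assert np.array_equal(a, b)


def test_biomarker_only_mode_ignores_tiles(rng):
    net = _net(mode="biomarker")
    bio = rng.random(4)
    a = net.forward(rng.normal(size=(3, 6)), bio).class_probabilities
    b = net.forward(rng.normal(size=(9, 6)), bio).class_probabilities
    assert np.allclose(a, b)


def test_nan_input_fails_fast(rng):
    net = _net()
    X = rng.normal(size=(4, 6))
    X[2, 3] = np.nan
    with pytest.raises(FloatingPointError):
        net.forward(X, rng.random(4))


@pytest.mark.parametrize(
    "probs, labels, expected",
    [
        ([[0.0, 1.0]], [1], 0.0),
        ([[0.5, 0.5]], [1], np.log(2)),
        ([[0.2, 0.8], [0.6, 0.4]], [1, 0], -(np.log(0.8) + np.log(0.6)) / 2),
    ],
)
def test_cross_entropy_hand_values(probs, labels, expected):
    loss = cross_entropy_loss(np.array(probs), np.array(labels))
    assert float(loss.data) == pytest.approx(expected, abs=1e-9)


def test_cross_entropy_clamps_zero_probability():
    with pytest.warns(RuntimeWarning, match="clamped"):
        loss = cross_entropy_loss(np.array([[1.0, 0.0]]), np.array([1]))
    assert np.isfinite(loss.data)
    assert float(loss.data) == pytest.approx(-np.log(1e-12))


def test_cross_entropy_rejects_out_of_range_labels():
    with pytest.raises(ValueError):
        cross_entropy_loss(np.array([[0.5, 0.5]]), np.array([2]))


def test_loss_gradient_wrt_logits_matches_finite_differences(rng):
    logits = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
    labels = np.array([0, 1, 1, 0])

    def fn():
        return cross_entropy_loss(softmax(logits, axis=1), labels)

    fn().backward()
    eps = 1e-6
    for idx in np.ndindex(4, 2):
        logits.data[idx] += eps
        up = fn().data.item()
        logits.data[idx] -= 2 * eps
        down = fn().data.item()
        logits.data[idx] += eps
        assert abs(logits.grad[idx] - (up - down) / (2 * eps)) < 1e-4


def test_loss_batch_record():
    lb = LossBatch(probs=np.array([[0.5, 0.5], [0.9, 0.1]]), labels=np.array([1, 0]))
    assert lb.n == 2 and lb.n_classes == 2
    assert lb.loss == pytest.approx((np.log(2) - np.log(0.9)) / 2)


def test_checkpoint_round_trip(tmp_path, rng):
    net = _net()
    X = rng.normal(size=(5, 6))
    bio = rng.random(4)
    before = net.forward(X, bio).class_probabilities
    path = save_checkpoint(net, tmp_path / "ck.npz", extra={"kept_dims": [1, 2]})
    loaded, extra = load_checkpoint(path)
    assert extra == {"kept_dims": [1, 2]}
    after = loaded.forward(X, bio).class_probabilities
    assert np.array_equal(before, after)


def test_model_seed_reproducibility(rng):
    a, b = _net(seed=5), _net(seed=5)
    X = rng.normal(size=(3, 6))
    bio = rng.random(4)
    assert np.array_equal(
        a.forward(X, bio).class_probabilities, b.forward(X, bio).class_probabilities
    )
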