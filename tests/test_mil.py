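"""MIL model: encoding, pooling, classification, training, explanation."""

from __future__ import annotations

import numpy as np
import pytest

from hypomil.autograd import Tensor
from hypomil.mil import (HypoxiaMILClassifier, ModelConfig, _MILNet,
                         aggregate_max, classify_bag, evaluate_split,
                         sample_training_bag, summarize_splits)


def _random_tiles(rng, n=5, size=64):
    return rng.integers(0, 256, (n, size, size, 3), dtype=np.uint8)


@pytest.fixture(scope="module")
def toy_model():
    """A tiny model fitted on brightness-separated bags (fast, separable)."""
    rng = np.random.default_rng(0)
    X, y = [], []
    for i in range(12):
        level = 60 if i % 2 == 0 else 190
        X.append(rng.normal(level, 20, (6, 64, 64, 3)).clip(0, 255)
                 .astype(np.uint8))
        y.append(i % 2)
    model = HypoxiaMILClassifier(lr=0.01, epochs=8, bag_size=4, random_state=1)
    model.fit(X, y)
    return model, X, y


# ----------------------------------------------------------------- encoding

def test_identical_tiles_get_identical_features(toy_model):
    model, X, _ = toy_model
    tile = X[0][0]
    feats = model.encode_tiles(np.stack([tile, tile, tile]))
    assert feats.shape == (3, 512)
    assert np.array_equal(feats[0], feats[1]) and np.array_equal(feats[1], feats[2])


def test_permuted_bag_gives_permuted_features(toy_model):
    model, X, _ = toy_model
    tiles = X[0]
    perm = np.array([3, 1, 5, 0, 4, 2])
    assert np.allclose(model.encode_tiles(tiles)[perm],
                       model.encode_tiles(tiles[perm]), atol=1e-6)


def test_zero_tile_through_bias_free_backbone_gives_zero_gap():
    """conv biases start at zero, so a zero tile GAPs to the zero vector."""
    net = _MILNet("small_cnn", "max", np.random.default_rng(0))
    fmap = net.backbone.feature_map(Tensor(np.zeros((1, 64, 64, 3))))
    assert np.all(fmap.data == 0)


def test_incompatible_tile_size_names_required_divisibility():
    net = _MILNet("small_cnn", "max", np.random.default_rng(0))
    with pytest.raises(ValueError, match="divisible by 16"):
        net.forward(np.zeros((1, 100, 100, 3), dtype=np.uint8))


def test_vgg19_backbone_forward_shape():
    net = _MILNet("vgg19_like", "max", np.random.default_rng(0))
    out = net.forward(np.random.default_rng(1)
                      .integers(0, 256, (2, 32, 32, 3), dtype=np.uint8))
    assert out["probs"].shape == (2,)
    assert out["probs"].sum() == pytest.approx(1.0, abs=1e-6)


# ------------------------------------------------------------------ pooling

def test_max_aggregation_elementwise():
    assert np.array_equal(aggregate_max(np.array([[1.0, 0.0], [0.0, 1.0]])),
                          np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="empty"):
        aggregate_max(np.empty((0, 4)))


@pytest.mark.parametrize("pooling", ["max", "attention"])
def test_single_tile_bag_feature_equals_tile_feature(pooling):
    net = _MILNet("small_cnn", pooling, np.random.default_rng(2))
    f, _ = net.tile_features(Tensor(np.random.default_rng(0)
                                    .uniform(0, 1, (1, 64, 64, 3))))
    bag, _ = net.aggregate(f)
    assert np.allclose(bag.data, f.data, atol=1e-6)


def test_attention_weights_form_a_simplex():
    """Gated-attention weights are nonnegative and sum to 1 for 1000 bags."""
    net = _MILNet("small_cnn", "attention", np.random.default_rng(3))
    rng = np.random.default_rng(4)
    for _ in range(1000):
        f = Tensor(rng.normal(0, 1, (int(rng.integers(1, 8)), 512)))
        a = net.attention(f).data
        assert (a >= 0).all()
        assert a.sum() == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("pooling", ["max", "attention"])
def test_bag_prediction_invariant_to_tile_order(pooling):
    net = _MILNet("small_cnn", pooling, np.random.default_rng(5))
    rng = np.random.default_rng(6)
    tiles = _random_tiles(rng, n=7)
    base = net.forward(tiles)["probs"]
    for _ in range(5):
        perm = rng.permutation(len(tiles))
        assert np.allclose(net.forward(tiles[perm])["probs"], base, atol=1e-6)


def test_max_pool_invariant_to_tile_duplication():
    net = _MILNet("small_cnn", "max", np.random.default_rng(7))
    tiles = _random_tiles(np.random.default_rng(8), n=4)
    dup = np.concatenate([tiles, tiles[[1, 1, 3]]])
    assert np.allclose(net.forward(dup)["probs"],
                       net.forward(tiles)["probs"], atol=1e-6)


def test_attention_invariant_to_duplicating_whole_bag():
    net = _MILNet("small_cnn", "attention", np.random.default_rng(9))
    tiles = _random_tiles(np.random.default_rng(10), n=4)
    doubled = np.concatenate([tiles, tiles])
    assert np.allclose(net.forward(doubled)["probs"],
                       net.forward(tiles)["probs"], atol=1e-6)


# ----------------------------------------------------------- classification

def test_classify_bag_probabilities_normalized():
    rng = np.random.default_rng(0)
    for _ in range(20):
        p = classify_bag(rng.normal(0, 1, 8), rng.normal(0, 1, (8, 2)),
                         rng.normal(0, 1, 2))
        assert p.shape == (2,)
        assert ((p >= 0) & (p <= 1)).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-6)


def test_classify_bag_zero_weights_is_coin_flip():
    p = classify_bag(np.ones(4), np.zeros((4, 2)), np.zeros(2))
    assert np.allclose(p, [0.5, 0.5])


def test_classify_bag_matches_hand_computed_toy():
    """2-tile, 4-feature bag against manual matrix arithmetic.

    max-pool of [(1,0,2,-1),(0,1,3,0)] is (1,1,3,0); relu leaves it; with
    W1 = [[1,0],[-1,1],[.5,-.5],[2,1]], b1 = (.1,-.2) the logits are
    (1.6, -0.7), so p0 = 1/(1+e^(-2.3)).
    """
    feats = np.array([[1.0, 0.0, 2.0, -1.0], [0.0, 1.0, 3.0, 0.0]])
    W1 = np.array([[1.0, 0.0], [-1.0, 1.0], [0.5, -0.5], [2.0, 1.0]])
    b1 = np.array([0.1, -0.2])
    p = classify_bag(aggregate_max(feats), W1, b1)
    assert p[0] == pytest.approx(0.908877038985, abs=1e-9)
    assert p[1] == pytest.approx(1 - 0.908877038985, abs=1e-9)


def test_forward_pass_decomposes_into_public_pieces(toy_model):
    """score_tile == encode → max-aggregate → classify_bag with the fitted
    head weights (internal and functional paths agree)."""
    model, X, _ = toy_model
    tile = X[1][0]
    direct = model.score_tile(tile)
    feats = model.encode_tiles(tile[None])
    composed = classify_bag(aggregate_max(feats),
                            model._net.head.w.data, model._net.head.b.data)
    assert np.allclose(direct, composed, atol=1e-5)


# ----------------------------------------------------------------- training

def test_training_halves_loss_on_separable_toy(toy_model):
    model, _, _ = toy_model
    h = model.loss_history_
    assert h[-1] < 0.5 * h[0]


def test_training_is_reproducible():
    rng = np.random.default_rng(0)
    X = [rng.normal(100 + 50 * (i % 2), 30, (4, 64, 64, 3)).clip(0, 255)
         .astype(np.uint8) for i in range(8)]
    y = [i % 2 for i in range(8)]
    runs = []
    for _ in range(2):
        m = HypoxiaMILClassifier(lr=0.01, epochs=2, bag_size=3, random_state=5)
        m.fit(X, y)
        runs.append((m.loss_history_, m._net.head.w.data.copy()))
    assert runs[0][0] == runs[1][0]
    assert np.array_equal(runs[0][1], runs[1][1])


def test_attention_pooling_trains():
    rng = np.random.default_rng(1)
    X = [rng.normal(60 + 130 * (i % 2), 20, (4, 64, 64, 3)).clip(0, 255)
         .astype(np.uint8) for i in range(8)]
    m = HypoxiaMILClassifier(pooling="attention", lr=0.01, epochs=4,
                             bag_size=3, random_state=2)
    m.fit(X, [i % 2 for i in range(8)])
    assert m.loss_history_[-1] < m.loss_history_[0]
    w = m.attention_weights(X[0])
    assert w.sum() == pytest.approx(1.0, abs=1e-6)


def test_fit_validates_classes_and_sizes():
    rng = np.random.default_rng(0)
    X = [_random_tiles(rng, 2) for _ in range(4)]
    with pytest.raises(ValueError, match="2 classes"):
        HypoxiaMILClassifier(epochs=1).fit(X, [0, 0, 0, 0])
    with pytest.raises(ValueError, match="2 samples per class"):
        HypoxiaMILClassifier(epochs=1).fit(X, [0, 0, 0, 1])
    with pytest.raises(ValueError, match="bag_size"):
        HypoxiaMILClassifier(bag_size=0, epochs=1).fit(X, [0, 0, 1, 1])


def test_small_sample_bags_resample_with_replacement():
    rng = np.random.default_rng(0)
    tiles = _random_tiles(rng, n=3)
    bag = sample_training_bag(tiles, 10, rng)
    assert bag.shape == (10, 64, 64, 3)
    big = sample_training_bag(tiles, 2, rng)
    assert big.shape == (2, 64, 64, 3)


def test_predict_sample_rejects_empty_bag(toy_model):
    model, _, _ = toy_model
    with pytest.raises(ValueError, match="zero tiles"):
        model.predict_sample(np.empty((0, 64, 64, 3), dtype=np.uint8))


def test_score_tile_equals_single_tile_prediction(toy_model):
    model, X, _ = toy_model
    tile = X[2][1]
    assert model.score_tile(tile)[1] == pytest.approx(
        model.predict_sample(tile[None]), abs=1e-6)


def test_checkpoint_round_trip(toy_model, tmp_path):
    """Saved single-file checkpoints restore identical predictions."""
    model, X, _ = toy_model
    path = tmp_path / "model.npz"
    model.save(path)
    restored = HypoxiaMILClassifier.load(path)
    assert np.array_equal(restored.classes_, model.classes_)
    assert restored.loss_history_ == model.loss_history_
    assert np.allclose(restored.predict_proba(X[:3]),
                       model.predict_proba(X[:3]), atol=1e-7)


def test_sklearn_param_round_trip():
    m = HypoxiaMILClassifier(pooling="attention", epochs=7)
    params = m.get_params()
    assert params["pooling"] == "attention" and params["epochs"] == 7
    m.set_params(epochs=3)
    assert m.epochs == 3


# --------------------------------------------------------------- evaluation

def test_perfect_separation_scores_auroc_one():
    y = [0, 0, 1, 1, 0, 1]
    p = [0.1, 0.2, 0.9, 0.8, 0.05, 0.95]
    strata = ["normoxic", "normoxic", "low", "high", "normoxic", "high"]
    m = evaluate_split(y, p, strata)
    for grp in ("all", "low", "high"):
        assert m[grp]["auroc"] == 1.0
        assert m[grp]["accuracy"] == 1.0


def test_constant_predictions_are_chance_level():
    m = evaluate_split([0, 1, 0, 1], [0.5] * 4,
                       ["normoxic", "low", "normoxic", "high"])
    assert m["all"]["auroc"] == 0.5


def test_auroc_matches_rank_sum_hand_calculation():
    """4 predictions: U = 3 concordant pairs of 4 → AUROC 0.75."""
    m = evaluate_split([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8],
                       ["normoxic", "normoxic", "low", "low"])
    assert m["all"]["auroc"] == pytest.approx(0.75)


def test_empty_stratum_reported_undefined_and_excluded():
    m = evaluate_split([0, 1], [0.2, 0.9], ["normoxic", "low"])
    assert m["high"]["auroc"] is None
    summary = summarize_splits([m, m])
    assert summary["high"]["auroc"]["mean"] is None
    assert summary["all"]["auroc"]["n_splits"] == 2


# -------------------------------------------------------------- explanation

def test_activation_map_bounded_and_tile_sized(toy_model):
    model, X, _ = toy_model
    cam = model.activation_map(X[1][0])
    assert cam.shape == (64, 64)
    assert cam.min() >= 0.0 and cam.max() <= 1.0


def test_uniform_tile_gives_near_uniform_map(toy_model):
    model, _, _ = toy_model
    cam = model.activation_map(np.full((64, 64, 3), 128, dtype=np.uint8))
    assert cam.max() - cam.min() < 0.1


def test_activation_map_highlights_planted_lesion(mil_experiment):
    """On a normoxic-texture tile with a planted patch of hypoxic-class
    texture, the class-activation map is higher inside the patch."""
    from hypomil.synthetic import render_annotated_tile

    model = mil_experiment["att_model"]
    cfg = mil_experiment["cohort"]["cfg"]
    src = render_annotated_tile(cfg, np.random.default_rng(3), "hypoxic",
                                "lesion", n_cells=6).image
    tile = render_annotated_tile(cfg, np.random.default_rng(5), "normoxic",
                                 "bg", n_cells=6).image.copy()
    tile[64:192, 64:192] = src[64:192, 64:192]
    cam = model.activation_map(tile)
    outside = np.ones((256, 256), dtype=bool)
    outside[64:192, 64:192] = False
    assert cam[~outside].mean() > cam[outside].mean()


def test_model_config_validation():
    with pytest.raises(ValueError, match="lr"):
        ModelConfig(lr=0.0)
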