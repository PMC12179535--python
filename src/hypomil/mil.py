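"""Weakly supervised multiple-instance classification of tile bags.

A slide is represented as a *bag* of tissue tiles carrying a single weak
binary label (hypoxic / normoxic) derived from its gene-expression hypoxia
score.  Each tile is encoded by a convolutional backbone, reduced to a
512-feature vector by global average pooling (plus a linear projection when
the backbone's channel count differs), and the bag is aggregated either by
element-wise max pooling or by gated attention pooling.  The bag feature is
classified as

    L_k = softmax(relu(Pool(F_k^1, …, F_k^N)) · W1 + b1)

(the rectification acts on the pooled bag feature; rectifying the two
logits instead stalls training in a dead zone), trained with cross-entropy
under plain SGD.  Training bags are fresh random
draws of ``bag_size`` tiles per sample each epoch; at inference every
filtered tile of the sample forms the bag.

The public surface is the scikit-learn style :class:`HypoxiaMILClassifier`;
the module-level helpers (:func:`classify_bag`, :func:`aggregate_max`,
:func:`predict_sample`, :func:`score_tile`, :func:`evaluate_split`) are thin
functional views of the same computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (
    accuracy_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.utils.validation import check_is_fitted

from . import autograd as ag
from .autograd import Tensor
from .nn import SGD, Dense, FEATURE_DIM, make_backbone

logger = logging.getLogger(__name__)

__all__ = [
    "Bag",
    "ModelConfig",
    "HypoxiaMILClassifier",
    "classify_bag",
    "aggregate_max",
    "sample_training_bag",
    "predict_sample",
    "score_tile",
    "evaluate_split",
    "summarize_splits",
]


@dataclass
class Bag:
    """An ordered collection of tiles sharing one sample-level weak label."""

    sample_id: str
    tiles: np.ndarray  # (N, H, W, 3)
    label: int | None = None


@dataclass
class ModelConfig:
    """Training configuration; defaults follow the published schedule."""

    backbone: str = "small_cnn"
    pooling: str = "max"
    lr: float = 0.0003
    epochs: int = 100
    bag_size: int = 20
    att_dim: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")


def _prep_tiles(tiles) -> np.ndarray:
    """Stack tiles into an (N, H, W, 3) float32 array scaled to [0, 1]."""
    arr = np.asarray(tiles)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
    return arr


def classify_bag(bag_feature: np.ndarray, W1: np.ndarray, b1: np.ndarray) -> np.ndarray:
    """Pure-numpy classification head: softmax(relu(feature) · W1 + b1)."""
    z = np.maximum(np.asarray(bag_feature, dtype=float).reshape(-1), 0.0) @ W1 + b1
    e = np.exp(z - z.max())
    return e / e.sum()


def aggregate_max(features: np.ndarray) -> np.ndarray:
    """Element-wise maximum over the bag axis (MIL max pooling)."""
    features = np.asarray(features)
    if features.size == 0:
        raise ValueError("cannot aggregate an empty bag")
    return features.max(axis=0)


def sample_training_bag(tiles: np.ndarray, bag_size: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw a fixed-size training bag; with replacement when tiles are scarce."""
    n = len(tiles)
    if n == 0:
        raise ValueError("sample has no tiles to bag")
    if n >= bag_size:
        idx = rng.choice(n, size=bag_size, replace=False)
    else:
        logger.debug("sample has %d < %d tiles; sampling with replacement", n, bag_size)
        idx = rng.choice(n, size=bag_size, replace=True)
    return tiles[idx]


class _MILNet:
    """Backbone + projection + pooling + Eq.-style classification head."""

    def __init__(self, backbone: str, pooling: str, rng: np.random.Generator,
                 att_dim: int = 64):
        if pooling not in ("max", "attention"):
            raise ValueError(f"pooling must be 'max' or 'attention', got {pooling!r}")
        self.pooling = pooling
        self.backbone = make_backbone(backbone, rng)
        self.proj = (Dense(self.backbone.out_channels, FEATURE_DIM, rng)
                     if self.backbone.out_channels != FEATURE_DIM else None)
        if pooling == "attention":
            self.att_v = Dense(FEATURE_DIM, att_dim, rng, bias=False)
            self.att_u = Dense(FEATURE_DIM, att_dim, rng, bias=False)
            self.att_w = Dense(att_dim, 1, rng, bias=False)
        self.head = Dense(FEATURE_DIM, 2, rng)

    def parameters(self):
        params = self.backbone.parameters() + self.head.parameters()
        if self.proj is not None:
            params += self.proj.parameters()
        if self.pooling == "attention":
            params += (self.att_v.parameters() + self.att_u.parameters()
                       + self.att_w.parameters())
        return params

    def tile_features(self, x: Tensor):
        fmap = self.backbone.feature_map(x)
        f = ag.global_avg_pool(fmap)
        if self.proj is not None:
            f = self.proj(f)
        return f, fmap

    def attention(self, f: Tensor) -> Tensor:
        """Gated-attention weights over tiles, (N, 1), softmax-normalised."""
        gate = ag.mul(ag.tanh(self.att_v(f)), ag.sigmoid(self.att_u(f)))
        return ag.softmax(self.att_w(gate), axis=0)

    def aggregate(self, f: Tensor):
        if self.pooling == "max":
            return ag.bag_max(f), None
        a = self.attention(f)
        bag = ag.tsum(ag.mul(f, a), axis=0, keepdims=True)
        return bag, a

    def logits(self, x: Tensor):
        # rectification is applied to the pooled bag feature, before the
        # dense layer: rectifying the two logits instead creates a dead
        # zone (both logits clamped at zero kills every gradient) that
        # halts training; see the methods note for the rationale
        f, fmap = self.tile_features(x)
        bag, attn = self.aggregate(f)
        z = self.head(ag.relu(bag))
        return z, attn, fmap

    def forward(self, tiles) -> dict:
        z, attn, _ = self.logits(Tensor(_prep_tiles(tiles)))
        zr = z.data.reshape(-1)
        e = np.exp(zr - zr.max())
        probs = e / e.sum()
        return {
            "probs": probs,
            "logits": zr.copy(),
            "attention": None if attn is None else attn.data.reshape(-1).copy(),
        }

    def loss(self, tiles, label: int) -> Tensor:
        z, _, _ = self.logits(Tensor(_prep_tiles(tiles)))
        return ag.softmax_cross_entropy(z, int(label))


class HypoxiaMILClassifier(BaseEstimator, ClassifierMixin):
    """Weakly supervised MIL classifier for bags of histology tiles.

    Parameters
    ----------
    backbone : {'small_cnn', 'vgg19_like'}
        Tile encoder. ``small_cnn`` trains in minutes on a CPU and is the
        right choice for synthetic or desk-scale data; ``vgg19_like`` is the
        full-scale architecture (randomly initialised).
    pooling : {'max', 'attention'}
        Bag aggregation: element-wise maximum, or gated attention pooling
        (two-layer tanh/sigmoid gate, softmax over tiles).
    lr, epochs, bag_size
        Plain-SGD learning rate, number of passes over the cohort, and the
        number of tiles drawn per sample per iteration.
    att_dim : int
        Hidden width of the gated-attention scorer.
    random_state : int or None
        Seeds weight initialisation and bag resampling.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the "positive" (hypoxic)
        class whose probability is column 1 of :meth:`predict_proba`.
    loss_history_ : list of float
        Mean training cross-entropy per epoch.
    """

    def __init__(self, backbone="small_cnn", pooling="max", lr=0.0003,
                 epochs=100, bag_size=20, att_dim=64, random_state=None,
                 verbose=0):
        self.backbone = backbone
        self.pooling = pooling
        self.lr = lr
        self.epochs = epochs
        self.bag_size = bag_size
        self.att_dim = att_dim
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ fit
    def fit(self, X: Sequence[np.ndarray], y):
        """Train on a cohort of tile bags.

        Parameters
        ----------
        X : sequence of arrays, each (n_tiles_i, H, W, 3)
            One entry per sample holding all of its tissue-filtered tiles
            (uint8 in [0, 255] or float in [0, 1]).
        y : array-like of shape (n_samples,)
            Binary weak labels.
        """
        cfg = ModelConfig(backbone=self.backbone, pooling=self.pooling,
                          lr=self.lr, epochs=self.epochs,
                          bag_size=self.bag_size, att_dim=self.att_dim)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(f"need exactly 2 classes, got {self.classes_!r}")
        y01 = (y == self.classes_[1]).astype(int)
        if min(np.bincount(y01)) < 2:
            raise ValueError("need at least 2 samples per class for training")

        rng = np.random.default_rng(self.random_state)
        self._net = _MILNet(cfg.backbone, cfg.pooling, rng, att_dim=cfg.att_dim)
        opt = SGD(self._net.parameters(), cfg.lr)
        tiles = [_prep_tiles(x) for x in X]
        self.loss_history_ = []
        n = len(tiles)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for i in order:
                bag = sample_training_bag(tiles[i], cfg.bag_size, rng)
                loss = self._net.loss(bag, y01[i])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, "
                        f"sample index {i}; try a smaller learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            self.loss_history_.append(float(np.mean(losses)))
            if self.verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs} "
                      f"loss {self.loss_history_[-1]:.4f}")
        return self

    # ---------------------------------------------------------- persistence
    def save(self, path):
        """Write a single-file checkpoint (npz archive, config embedded)."""
        import json

        self._check_fitted()
        params = self._net.parameters()
        arrays = {f"param_{i}": p.data for i, p in enumerate(params)}
        arrays["classes"] = self.classes_
        meta = {"params": self.get_params(),
                "loss_history": self.loss_history_}
        np.savez(path, config=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "HypoxiaMILClassifier":
        """Restore an estimator saved with :meth:`save`."""
        import json

        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(archive["config"].tobytes().decode())
            model = cls(**meta["params"])
            rng = np.random.default_rng(model.random_state)
            model._net = _MILNet(model.backbone, model.pooling, rng,
                                 att_dim=model.att_dim)
            for i, p in enumerate(model._net.parameters()):
                data = archive[f"param_{i}"]
                if data.shape != p.data.shape:
                    raise ValueError("checkpoint/architecture shape mismatch")
                p.data = data.astype(p.data.dtype)
            model.classes_ = archive["classes"]
            model.loss_history_ = meta["loss_history"]
        return model

    # ------------------------------------------------------------ inference
    def _check_fitted(self):
        check_is_fitted(self, "_net")

    def predict_proba(self, X) -> np.ndarray:
        """Full-bag probabilities, one row per sample, columns = classes_."""
        self._check_fitted()
        out = np.empty((len(X), 2))
        for i, tiles in enumerate(X):
            out[i] = self._net.forward(tiles)["probs"]
        return out

    def predict(self, X):
        return self.classes_[(self.predict_proba(X)[:, 1] > 0.5).astype(int)]

    def predict_sample(self, tiles: np.ndarray) -> float:
        """Positive-class probability for one sample's full tile bag."""
        self._check_fitted()
        if len(tiles) == 0:
            raise ValueError("sample has zero tiles after filtering; "
                             "mark it unevaluable instead of predicting")
        return float(self._net.forward(tiles)["probs"][1])

    def score_tile(self, tile: np.ndarray) -> np.ndarray:
        """Class probabilities for a bag of one instance (a single tile)."""
        self._check_fitted()
        return self._net.forward(tile[None] if tile.ndim == 3 else tile)["probs"]

    def score_tiles(self, tiles: np.ndarray) -> np.ndarray:
        """Score each tile independently; (n, 2) array of probabilities."""
        return np.stack([self.score_tile(t) for t in np.asarray(tiles)])

    def encode_tiles(self, tiles: np.ndarray) -> np.ndarray:
        """512-feature embedding of each tile (GAP of conv features)."""
        self._check_fitted()
        f, _ = self._net.tile_features(Tensor(_prep_tiles(tiles)))
        return f.data.copy()

    def attention_weights(self, tiles: np.ndarray) -> np.ndarray:
        """Per-tile attention weights (attention pooling only); sums to 1."""
        self._check_fitted()
        out = self._net.forward(tiles)
        if out["attention"] is None:
            raise ValueError("attention weights require pooling='attention'")
        return out["attention"]

    # -------------------------------------------------------------- explain
    def activation_map(self, tile: np.ndarray) -> np.ndarray:
        """Gradient-weighted class-activation map for a single tile.

        Gradients of the winning class score are taken at the last conv
        feature map, averaged spatially into channel weights, combined with
        the activations, rectified, scaled to [0, 1] by the map maximum and
        bilinearly upsampled to tile size.
        """
        self._check_fitted()
        from skimage.transform import resize

        net = self._net
        if not hasattr(net.backbone, "feature_map"):
            raise ValueError("backbone has no spatial feature maps; "
                             "activation maps unsupported")
        x = Tensor(_prep_tiles(tile))
        z, _, fmap = net.logits(x)
        c = int(np.argmax(z.data.reshape(-1)))
        onehot = np.zeros_like(z.data)
        onehot.reshape(-1)[c] = 1.0
        score = ag.tsum(ag.mul(z, Tensor(onehot)))
        for p in net.parameters():
            p.grad = None
        score.backward()
        if fmap.grad is None:
            cam = np.zeros(fmap.data.shape[1:3], dtype=np.float32)
        else:
            weights = fmap.grad.mean(axis=(0, 1, 2))
            cam = np.maximum((fmap.data[0] * weights).sum(axis=-1), 0.0)
        peak = cam.max()
        if peak > 0:
            cam = cam / peak
        h, w = np.asarray(tile).shape[-3:-1]
        return resize(cam, (h, w), order=1, mode="edge",
                      anti_aliasing=False).astype(np.float32)


# ------------------------------------------------------------- thin wrappers

def predict_sample(model: HypoxiaMILClassifier, tiles: np.ndarray) -> float:
    return model.predict_sample(tiles)


def score_tile(model: HypoxiaMILClassifier, tile: np.ndarray) -> np.ndarray:
    return model.score_tile(tile)


# -------------------------------------------------------------- evaluation

def evaluate_split(y_true, y_prob, strata, threshold: float = 0.5) -> dict:
    """Per-stratum test metrics for one train/test split.

    Three comparisons are reported: all hypoxic vs normoxic, low-stratum
    hypoxic vs normoxic, and high-stratum hypoxic vs normoxic.  A group
    missing one of the two classes yields ``None`` metrics (logged), which
    :func:`summarize_splits` excludes from averages.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    strata = np.asarray(strata)
    groups = {
        "all": np.ones(len(y_true), dtype=bool),
        "low": (strata == "normoxic") | (strata == "low"),
        "high": (strata == "normoxic") | (strata == "high"),
    }
    out = {}
    for name, mask in groups.items():
        yt, yp = y_true[mask], y_prob[mask]
        if len(np.unique(yt)) < 2:
            logger.warning("stratum %r has a single class in this split; "
                           "metrics undefined", name)
            out[name] = {m: None for m in
                         ("auroc", "accuracy", "precision", "recall")}
            continue
        pred = (yp > threshold).astype(int)
        out[name] = {
            "auroc": float(roc_auc_score(yt, yp)),
            "accuracy": float(accuracy_score(yt, pred)),
            "precision": float(precision_score(yt, pred, zero_division=0)),
            "recall": float(recall_score(yt, pred, zero_division=0)),
        }
    return out


def summarize_splits(split_metrics: Sequence[dict]) -> dict:
    """Mean ± SD of each metric over splits, skipping undefined entries."""
    summary: dict = {}
    for group in ("all", "low", "high"):
        summary[group] = {}
        for metric in ("auroc", "accuracy", "precision", "recall"):
            vals = [s[group][metric] for s in split_metrics
                    if s[group][metric] is not None]
            summary[group][metric] = {
                "mean": float(np.mean(vals)) if vals else None,
                "sd": float(np.std(vals)) if vals else None,
                "n_splits": len(vals),
            }
    return summary
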