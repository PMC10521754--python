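"""The multimodal MIL network: attention pooling, biomarker encoder,
gated Kronecker tensor fusion, classifier head, and the training loss.

Architecture (one bag at a time):

* image channel — instance features are linearly embedded with a ReLU, a
  gated attention module (a_k proportional to exp(w^T (tanh(V h_k) *
  sigmoid(U h_k)))) produces simplex weights over instances, and the bag
  representation is the attention-weighted sum of embeddings. Permutation
  invariant by construction.
* biomarker channel — the normalized 4-vector passes through a small
  feedforward network with a tanh-bounded output.
* fusion — each modality representation is rescaled elementwise by a
  sigmoid gate computed from both modalities, a constant 1 is appended to
  each gated vector, and the fused representation is the flattened outer
  (Kronecker) product, length (d1+1)(d2+1). The appended ones preserve the
  unimodal sub-blocks inside the product.
* classifier — one hidden ReLU layer to C class logits, softmax to
  probabilities.

Ablation modes "image" and "biomarker" replace the missing channel with a
learned constant vector, keeping the fusion and classifier shapes intact.

The training loss is categorical cross-entropy,
L = -(1/N) sum_i sum_c 1[y_i = c] log P(y_i = c),
with the true-class probability clamped at 1e-12 (never -inf).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, concat, softmax

__all__ = [
    "ModelConfig",
    "BagPrediction",
    "LossBatch",
    "MMILNet",
    "cross_entropy_loss",
    "save_checkpoint",
    "load_checkpoint",
]

LOSS_EPS = 1e-12
MODES = ("fused", "image", "biomarker")


@dataclass
class ModelConfig:
    in_dim: int  # instance feature length after selection
    image_repr_dim: int = 8
    biomarker_repr_dim: int = 8
    attention_hidden_dim: int = 16
    biomarker_hidden_dim: int = 16
    classifier_hidden_dim: int = 32
    n_classes: int = 2
    n_biomarkers: int = 4
    gate_enabled: bool = True
    gated_attention: bool = True
    mode: str = "fused"
    dropout: float = 0.0
    fusion_dim_cap: int = 65536
    seed: int = 0

    def __post_init__(self):
        dims = (
            self.in_dim,
            self.image_repr_dim,
            self.biomarker_repr_dim,
            self.attention_hidden_dim,
            self.biomarker_hidden_dim,
            self.classifier_hidden_dim,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.fused_dim > self.fusion_dim_cap:
            raise ValueError(
                f"fused length {self.fused_dim} exceeds cap {self.fusion_dim_cap}; "
                "use smaller representation dims"
            )

    @property
    def fused_dim(self) -> int:
        return (self.image_repr_dim + 1) * (self.biomarker_repr_dim + 1)


@dataclass
class BagPrediction:
    class_probabilities: np.ndarray  # length C, simplex
    attention_weights: np.ndarray  # length n, simplex
    image_repr: np.ndarray
    biomarker_repr: np.ndarray
    fused_repr: np.ndarray
    prob_tensor: "Tensor | None" = field(default=None, repr=False)


@dataclass
class LossBatch:
    """One evaluated batch of the categorical cross-entropy loss."""

    probs: np.ndarray  # N x C
    labels: np.ndarray  # N

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.loss = float(cross_entropy_loss(Tensor(self.probs), self.labels).data)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return self.probs.shape[1]


def cross_entropy_loss(probs, labels) -> Tensor:
    """L = -(1/N) sum_i log P(y_i); true-class probabilities clamped at 1e-12."""
    if not isinstance(probs, Tensor):
        probs = Tensor(np.asarray(probs, dtype=float))
    labels = np.asarray(labels, dtype=np.int64)
    n, c = probs.data.shape
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= c:
        raise ValueError(f"labels must lie in [0, {c})")
    p_true = probs[np.arange(n), labels]
    if (p_true.data <= LOSS_EPS).any():
        warnings.warn("true-class probability clamped at 1e-12 in loss", RuntimeWarning)
    return -(p_true.clip_min(LOSS_EPS).log().mean())


def _check_finite(stage: str, t: Tensor) -> None:
    if not np.isfinite(t.data).all():
        raise FloatingPointError(f"non-finite values produced at stage {stage!r}")


class MMILNet:
    """The fused bag classifier; parameters live in a flat dict of Tensors."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.training = False
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        rng = np.random.default_rng(config.seed)
        d_in, d1 = config.in_dim, config.image_repr_dim
        d2, da = config.biomarker_repr_dim, config.attention_hidden_dim
        db, dc = config.biomarker_hidden_dim, config.classifier_hidden_dim
        nb, c = config.n_biomarkers, config.n_classes

        def p(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.params = {
            "W_embed": p((d_in, d1), np.sqrt(2.0 / d_in)),
            "b_embed": Tensor(np.zeros((1, d1)), requires_grad=True),
            "V_att": p((d1, da), np.sqrt(1.0 / d1)),
            "U_att": p((d1, da), np.sqrt(1.0 / d1)),
            "w_att": p((da, 1), np.sqrt(1.0 / da)),
            "W_bio1": p((nb, db), np.sqrt(2.0 / nb)),
            "b_bio1": Tensor(np.zeros((1, db)), requires_grad=True),
            "W_bio2": p((db, d2), np.sqrt(1.0 / db)),
            "b_bio2": Tensor(np.zeros((1, d2)), requires_grad=True),
            "image_const": p((1, d1), 0.01),
            "bio_const": p((1, d2), 0.01),
            "A_gate_img": p((d1 + d2, d1), np.sqrt(1.0 / (d1 + d2))),
            "b_gate_img": Tensor(np.zeros((1, d1)), requires_grad=True),
            "A_gate_bio": p((d1 + d2, d2), np.sqrt(1.0 / (d1 + d2))),
            "b_gate_bio": Tensor(np.zeros((1, d2)), requires_grad=True),
            "W_clf1": p((config.fused_dim, dc), np.sqrt(2.0 / config.fused_dim)),
            "b_clf1": Tensor(np.zeros((1, dc)), requires_grad=True),
            "W_clf2": p((dc, c), np.sqrt(1.0 / dc)),
            "b_clf2": Tensor(np.zeros((1, c)), requires_grad=True),
        }

    # -- channel components -----------------------------------------------

    def attention_pool(self, features) -> tuple[Tensor, Tensor]:
        """(bag_repr 1 x d1, weights n x 1) from an n x in_dim feature matrix."""
        X = features if isinstance(features, Tensor) else Tensor(np.atleast_2d(features))
        if X.data.shape[0] == 0:
            raise ValueError("cannot pool an empty bag")
        if not np.isfinite(X.data).all():
            raise FloatingPointError("non-finite instance features")
        P = self.params
        E = (X @ P["W_embed"] + P["b_embed"]).relu()
        scores = (E @ P["V_att"]).tanh()
        if self.config.gated_attention:
            scores = scores * (E @ P["U_att"]).sigmoid()
        logits = scores @ P["w_att"]  # n x 1
        weights = softmax(logits, axis=0)
        bag = weights.T @ E
        _check_finite("attention_pool", bag)
        return bag, weights

    def encode_biomarkers(self, vec) -> Tensor:
        v = np.asarray(getattr(vec, "data", vec), dtype=float).reshape(1, -1)
        if v.shape[1] != self.config.n_biomarkers:
            raise ValueError(
                f"expected {self.config.n_biomarkers} biomarkers, got {v.shape[1]}"
            )
        P = self.params
        h = (Tensor(v) @ P["W_bio1"] + P["b_bio1"]).relu()
        out = (h @ P["W_bio2"] + P["b_bio2"]).tanh()
        _check_finite("encode_biomarkers", out)
        return out

    def gated_tensor_fuse(self, image_repr, biomarker_repr) -> Tensor:
        """Gate each modality, append a 1, and flatten the Kronecker product."""
        img = image_repr if isinstance(image_repr, Tensor) else Tensor(np.atleast_2d(image_repr))
        bio = (
            biomarker_repr
            if isinstance(biomarker_repr, Tensor)
            else Tensor(np.atleast_2d(biomarker_repr))
        )
        P = self.params
        if self.config.gate_enabled:
            joint = concat([img, bio], axis=1)
            g_img = (joint @ P["A_gate_img"] + P["b_gate_img"]).sigmoid()
            g_bio = (joint @ P["A_gate_bio"] + P["b_gate_bio"]).sigmoid()
            img = img * g_img
            bio = bio * g_bio
        one = Tensor(np.ones((1, 1)))
        img1 = concat([img, one], axis=1)
        bio1 = concat([bio, one], axis=1)
        d1p = img1.data.shape[1]
        d2p = bio1.data.shape[1]
        fused = (img1.T @ bio1).reshape(1, d1p * d2p)
        _check_finite("gated_tensor_fuse", fused)
        return fused

    # -- full forward ------------------------------------------------------

    def forward(self, features, biomarkers=None) -> BagPrediction:
        """Bag features (n x in_dim) + normalized biomarker 4-vector -> prediction."""
        cfg = self.config
        P = self.params
        X = np.atleast_2d(np.asarray(getattr(features, "matrix", features), dtype=float))
        n = X.shape[0]

        if cfg.mode == "biomarker":
            bag = P["image_const"]
            weights_np = np.full(n, 1.0 / max(n, 1))
        else:
            bag, weights = self.attention_pool(X)
            weights_np = weights.data.ravel()

        if cfg.mode == "image":
            bio = P["bio_const"]
        else:
            if biomarkers is None:
                raise ValueError("biomarker vector required outside image-only mode")
            bio = self.encode_biomarkers(biomarkers)

        fused = self.gated_tensor_fuse(bag, bio)
        h = (fused @ P["W_clf1"] + P["b_clf1"]).relu()
        if self.training and cfg.dropout > 0:
            keep = 1.0 - cfg.dropout
            mask = self._dropout_rng.random(h.data.shape) < keep
            h = h * Tensor(mask / keep)
        logits = h @ P["W_clf2"] + P["b_clf2"]
        _check_finite("classifier", logits)
        probs = softmax(logits, axis=1)
        return BagPrediction(
            class_probabilities=probs.data.ravel().copy(),
            attention_weights=weights_np,
            image_repr=bag.data.ravel().copy(),
            biomarker_repr=bio.data.ravel().copy(),
            fused_repr=fused.data.ravel().copy(),
            prob_tensor=probs,
        )

    # -- utilities ---------------------------------------------------------

    def parameters(self) -> dict:
        return self.params

    def train_mode(self, on: bool = True) -> "MMILNet":
        self.training = on
        return self

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k!r}")
            if self.params[k].data.shape != v.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            self.params[k].data = np.asarray(v, dtype=np.float64).copy()


def save_checkpoint(model: MMILNet, path: str | Path, extra: dict | None = None) -> Path:
    """Single-archive checkpoint: weights + config + optional fingerprints."""
    path = Path(path)
    meta = {"config": asdict(model.config), "extra": extra or {}}
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        **model.state_dict(),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[MMILNet, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = MMILNet(ModelConfig(**meta["config"]))
    model.load_state_dict(state)
    return model, meta["extra"]
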