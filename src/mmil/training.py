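"""Training loops, fold plans and the Adam optimizer.

Bags are sampled with replacement under inverse-class-frequency weights
(each training batch is class-balanced in expectation), the categorical
cross-entropy loss is backpropagated through the whole network, and Adam
performs the update. Cross-validation folds are stratified by the bag
label; every fitted preprocessing step records the bag ids it saw so
evaluation can audit for train/test leakage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._autodiff import concat
from .model import MMILNet, ModelConfig, cross_entropy_loss

__all__ = [
    "SplitPlan",
    "TrainConfig",
    "Adam",
    "stratified_kfold",
    "make_sampling_weights",
    "train",
    "predict_scores",
]


@dataclass
class SplitPlan:
    k: int
    assignments: dict  # bag_id -> fold index
    stratified: bool
    seed: int

    def fold_ids(self, fold: int) -> list:
        return [b for b, f in self.assignments.items() if f == fold]


def stratified_kfold(labels, k: int, seed: int = 0, bag_ids=None) -> SplitPlan:
    """Label-stratified k-fold partition, deterministic given seed."""
    labels = np.asarray(labels, dtype=np.int64)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds cohort size {n}")
    if bag_ids is None:
        bag_ids = [str(i) for i in range(n)]
    counts = np.bincount(labels)
    if counts.min() < k:
        warnings.warn(
            "a class has fewer members than k; stratification degrades",
            UserWarning,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = {}
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        for i in test_idx:
            assignments[bag_ids[i]] = fold
    return SplitPlan(k=k, assignments=assignments, stratified=True, seed=seed)


def make_sampling_weights(labels) -> np.ndarray:
    """Per-bag weights proportional to 1 / class frequency (sum to 1)."""
    labels = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(labels, minlength=2)
    if (counts == 0).any():
        raise ValueError("weighted sampling needs both classes present")
    w = 1.0 / counts[labels]
    return w / w.sum()


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    epochs: int = 60
    batch_size: int = 8
    seed: int = 0
    fine_tune_from: "MMILNet | None" = None
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("hyperparameters must be positive")


class Adam:
    """Standard Adam with bias correction; skips parameters without gradients."""

    def __init__(self, params: dict, lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def train(
    bags: list,
    biomarkers: np.ndarray,
    labels,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
) -> tuple[MMILNet, dict]:
    """Train an MMILNet on FeatureBags + normalized biomarker rows.

    Returns the trained model and a log with the per-epoch mean loss.
    Raises on a non-finite loss with epoch/step context.
    """
    cfg = train_config or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    n = len(bags)
    if biomarkers.shape[0] != n or len(labels) != n:
        raise ValueError("bags, biomarkers and labels must align")

    if cfg.fine_tune_from is not None:
        model = MMILNet(model_config)
        model.load_state_dict(cfg.fine_tune_from.state_dict())
    else:
        model = MMILNet(model_config)
    model.train_mode(True)

    weights = make_sampling_weights(labels)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), cfg.learning_rate, cfg.adam_betas, cfg.adam_eps)

    epoch_losses = []
    for epoch in range(cfg.epochs):
        order = rng.choice(n, size=n, replace=True, p=weights)
        losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            prob_rows = []
            for i in batch:
                pred = model.forward(bags[i].matrix, biomarkers[i])
                prob_rows.append(pred.prob_tensor)
            probs = concat(prob_rows, axis=0)
            loss = cross_entropy_loss(probs, labels[batch])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {start // cfg.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        epoch_losses.append(float(np.mean(losses)))

    model.train_mode(False)
    log = {
        "epoch_loss": epoch_losses,
        "seed": cfg.seed,
        "epochs": cfg.epochs,
        "learning_rate": cfg.learning_rate,
    }
    return model, log


def predict_scores(model: MMILNet, bags: list, biomarkers: np.ndarray) -> np.ndarray:
    """Positive-class probability per bag (evaluation mode)."""
    model.train_mode(False)
    out = np.empty(len(bags))
    for i, fb in enumerate(bags):
        bio = None if model.config.mode == "image" else biomarkers[i]
        out[i] = model.forward(fb.matrix, bio).class_probabilities[1]
    return out
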