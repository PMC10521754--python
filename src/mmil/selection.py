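"""Weakly supervised selection of discriminative feature dimensions.

Only bag-level labels exist, so per-dimension discriminativeness is scored
distributionally: for each feature dimension, instance values are pooled
over all positive bags and over all negative bags, each pool is compressed
to an equal-width histogram over the combined range, and the two histograms
are compared with a squared maximum mean discrepancy (MMD) under a Gaussian
kernel. The top-scoring dimensions are kept. This is a deliberate
reconstruction: the combination of histogram compression with a two-sample
MMD per dimension is the simplest deterministic reading of a
histogram-plus-MMD selection scheme.

The MMD estimator used throughout is the biased V-statistic
MMD^2 = mean(Kxx) + mean(Kyy) - 2 mean(Kxy), k(x, y) = exp(-|x-y|^2 / 2h^2),
which is >= 0 and exactly 0 for identical samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SelectionResult",
    "mmd_squared",
    "median_heuristic_bandwidth",
    "select_feature_dims",
    "apply_selection",
]


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x[:, None] if x.ndim == 1 else x


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1)


def mmd_squared(sample_x, sample_y, bandwidth: float | None = None) -> float:
    """Biased (V-statistic) squared MMD with a Gaussian kernel.

    ``bandwidth`` defaults to the median heuristic on the pooled samples.
    """
    x, y = _as_2d(sample_x), _as_2d(sample_y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("MMD requires non-empty samples")
    if bandwidth is None:
        bandwidth = median_heuristic_bandwidth(np.vstack([x, y]))
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    g = 1.0 / (2.0 * bandwidth**2)
    kxx = np.exp(-g * _sq_dists(x, x)).mean()
    kyy = np.exp(-g * _sq_dists(y, y)).mean()
    kxy = np.exp(-g * _sq_dists(x, y)).mean()
    return float(max(kxx + kyy - 2.0 * kxy, 0.0))


def median_heuristic_bandwidth(pooled, max_points: int = 512) -> float:
    """Median pairwise distance of the pooled sample (deterministic subsample).

    Falls back to 1.0 when the median distance is zero (near-constant data).
    """
    x = _as_2d(pooled)
    if len(x) > max_points:
        # evenly spaced subsample after lexicographic sort: deterministic
        order = np.lexsort(x.T[::-1])
        idx = np.linspace(0, len(x) - 1, max_points).astype(int)
        x = x[order[idx]]
    d = np.sqrt(_sq_dists(x, x))
    med = float(np.median(d[np.triu_indices(len(x), k=1)]))
    return med if med > 0 else 1.0


def _weighted_mmd_squared(centers_x, px, centers_y, py, bandwidth) -> float:
    """MMD^2 between histogram-weighted samples (bin centers with bin mass)."""
    cx, cy = np.asarray(centers_x, float), np.asarray(centers_y, float)
    g = 1.0 / (2.0 * bandwidth**2)
    kxx = px @ np.exp(-g * (cx[:, None] - cx[None, :]) ** 2) @ px
    kyy = py @ np.exp(-g * (cy[:, None] - cy[None, :]) ** 2) @ py
    kxy = px @ np.exp(-g * (cx[:, None] - cy[None, :]) ** 2) @ py
    return float(max(kxx + kyy - 2.0 * kxy, 0.0))


@dataclass
class SelectionResult:
    """Per-dimension MMD scores and the retained dimension indices."""

    scores: np.ndarray
    kept_dims: np.ndarray  # sorted ascending
    n_keep: int
    bandwidths: np.ndarray  # per-dimension kernel bandwidth used
    seen_bag_ids: tuple = ()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scores": self.scores.tolist(),
                    "kept_dims": self.kept_dims.tolist(),
                    "n_keep": self.n_keep,
                    "bandwidths": self.bandwidths.tolist(),
                },
                indent=1,
            )
        )

    @staticmethod
    def from_json(path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return SelectionResult(
            scores=np.asarray(d["scores"]),
            kept_dims=np.asarray(d["kept_dims"], dtype=np.int64),
            n_keep=d["n_keep"],
            bandwidths=np.asarray(d["bandwidths"]),
        )


def select_feature_dims(
    pos_bags,
    neg_bags,
    n_keep: int | None = None,
    n_hist_bins: int = 50,
) -> SelectionResult:
    """Score every feature dimension and keep the ``n_keep`` best.

    ``pos_bags`` / ``neg_bags`` are FeatureBags (or bare matrices) from each
    class. Scores are symmetric in the class labels; a zero-variance
    dimension scores 0. ``n_keep`` defaults to half the feature dimension.
    """
    pos = [getattr(b, "matrix", b) for b in pos_bags]
    neg = [getattr(b, "matrix", b) for b in neg_bags]
    if not pos or not neg:
        raise ValueError("need at least one bag per class")
    X = np.vstack(pos)
    Y = np.vstack(neg)
    d = X.shape[1]
    if n_keep is None:
        n_keep = max(1, d // 2)
    if not 1 <= n_keep <= d:
        raise ValueError(f"n_keep must lie in [1, {d}], got {n_keep}")

    scores = np.zeros(d)
    bandwidths = np.ones(d)
    for j in range(d):
        x, y = X[:, j], Y[:, j]
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        if hi <= lo:
            continue  # zero variance pooled: score stays 0
        edges = np.linspace(lo, hi, n_hist_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        px = np.histogram(x, bins=edges)[0] / len(x)
        py = np.histogram(y, bins=edges)[0] / len(y)
        h = median_heuristic_bandwidth(np.concatenate([x, y]))
        bandwidths[j] = h
        scores[j] = _weighted_mmd_squared(centers, px, centers, py, h)

    # top-n_keep by score; ties broken toward the lower index for determinism
    order = np.lexsort((np.arange(d), -scores))
    kept = np.sort(order[:n_keep])
    seen = tuple(
        getattr(b, "bag_id", None) for b in list(pos_bags) + list(neg_bags)
    )
    return SelectionResult(
        scores=scores,
        kept_dims=kept.astype(np.int64),
        n_keep=n_keep,
        bandwidths=bandwidths,
        seen_bag_ids=seen,
    )


def apply_selection(bag, result: SelectionResult):
    """Column-subset a FeatureBag to the retained dimensions."""
    from .features import FeatureBag

    if result.kept_dims.max(initial=-1) >= bag.matrix.shape[1]:
        raise ValueError(
            f"selection indices exceed bag feature_dim {bag.matrix.shape[1]}"
        )
    return FeatureBag(
        bag_id=bag.bag_id,
        matrix=bag.matrix[:, result.kept_dims],
        label=bag.label,
        coords=bag.coords,
    )
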