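"""Model interpretation: per-tile LNM probability maps, heatmaps, and a
histomic characterization of high-probability tiles.

A tile's LNM probability is defined by singleton-bag inference: the tile is
pushed through the image channel as a one-instance bag with the patient's
normalized biomarker vector held fixed, and the positive-class probability
is recorded (a neutral-biomarker mode yields pure-image maps; raw attention
weights are available through the same map structure). Maps can be rendered
as grid heatmaps with a monotone colormap or summarized as histograms.

High-probability tiles are characterized with four interpretable histomic
feature families: nucleus count, mean nucleus area, mean solidity, Haralick
sum-average texture, and mean first-nearest-neighbor distance between
nucleus centroids. Nuclei are segmented by grayscale inversion + Otsu
thresholding + small-object removal (color-deconvolution channels only make
sense for real H&E input; the synthetic tiles are handled by the grayscale
route).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import cKDTree
from skimage.color import rgb2gray
from skimage.feature import graycomatrix
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import remove_small_objects

from .model import MMILNet
from .stats import wilcoxon_rank_sum

__all__ = [
    "TileScoreMap",
    "HistomicFeatureVector",
    "score_tiles",
    "score_histogram",
    "render_heatmap",
    "extract_histomic_features",
    "compare_top_tiles",
]

HISTOMIC_FEATURES = (
    "nucleus_count",
    "mean_nucleus_area",
    "mean_solidity",
    "haralick_sum_average",
    "mean_first_neighbor_distance",
)


@dataclass
class TileScoreMap:
    bag_id: str
    entries: list  # (grid_row, grid_col, probability)
    grid_shape: tuple
    colormap: str = "inferno"

    def __post_init__(self):
        probs = np.array([p for _, _, p in self.entries], dtype=float)
        if len(probs) and (not np.isfinite(probs).all() or probs.min() < 0 or probs.max() > 1):
            raise ValueError("tile probabilities must be finite and in [0, 1]")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p for _, _, p in self.entries], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["grid_row", "grid_col", "probability"])


@dataclass
class HistomicFeatureVector:
    nucleus_count: int
    mean_nucleus_area: float  # px^2; NaN if no nuclei
    mean_solidity: float  # (0, 1]; NaN if no nuclei
    haralick_sum_average: float  # gray-level units
    mean_first_neighbor_distance: float  # px; NaN with < 2 nuclei

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in HISTOMIC_FEATURES}


def score_tiles(
    model: MMILNet,
    feature_bag,
    biomarker_vec,
    expected_fingerprint: dict | None = None,
    fingerprint: dict | None = None,
    use_attention: bool = False,
) -> TileScoreMap:
    """Singleton-bag LNM probability per tile (or attention weights).

    ``expected_fingerprint``/``fingerprint`` guard against pairing a model
    with features from a different backbone/selection.
    """
    if expected_fingerprint is not None and expected_fingerprint != fingerprint:
        raise ValueError("checkpoint/feature fingerprint mismatch")
    X = feature_bag.matrix
    coords = feature_bag.coords
    if use_attention:
        pred = model.forward(X, biomarker_vec)
        probs = pred.attention_weights
        # attention weights are simplex over tiles, rescale to [0,1] by max
        probs = probs / probs.max() if probs.max() > 0 else probs
    else:
        probs = np.empty(len(X))
        for i in range(len(X)):
            pred = model.forward(X[i : i + 1], biomarker_vec)
            probs[i] = pred.class_probabilities[1]
    grid_shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
    entries = [
        (int(r), int(c), float(p)) for (r, c), p in zip(coords, probs)
    ]
    return TileScoreMap(bag_id=feature_bag.bag_id, entries=entries, grid_shape=grid_shape)


def score_histogram(score_map: TileScoreMap, n_bins: int = 20) -> np.ndarray:
    """Counts over uniform bins of [0, 1]; sums to the number of tiles."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if not score_map.entries:
        raise ValueError("empty score map")
    counts, _ = np.histogram(score_map.probabilities, bins=n_bins, range=(0.0, 1.0))
    return counts


def render_heatmap(
    score_map: TileScoreMap, out_path: str | Path, cell_px: int = 16
) -> Path:
    """Grid heatmap PNG: one colored cell per tile, monotone colormap
    (0 -> cold, 1 -> hot), transparent unretained cells, legend strip."""
    from matplotlib import colormaps

    if not score_map.entries:
        raise ValueError("empty score map")
    cmap = colormaps[score_map.colormap]
    rows, cols = score_map.grid_shape
    rgba = np.zeros((rows * cell_px, cols * cell_px, 4), dtype=np.uint8)
    for r, c, p in score_map.entries:
        color = (np.array(cmap(p)) * 255).astype(np.uint8)
        rgba[r * cell_px : (r + 1) * cell_px, c * cell_px : (c + 1) * cell_px] = color
    # legend: vertical gradient strip (probability 1 at top) with a gap column
    legend = np.zeros((rows * cell_px, cell_px + 4, 4), dtype=np.uint8)
    grad = np.linspace(1.0, 0.0, rows * cell_px)
    legend[:, 4:] = (cmap(grad)[:, None, :] * 255).astype(np.uint8)
    canvas = np.concatenate([rgba, legend], axis=1)
    out_path = Path(out_path)
    Image.fromarray(canvas, mode="RGBA").save(out_path)
    return out_path


def _segment_nuclei(tile_rgb: np.ndarray, min_size: int = 9):
    gray = rgb2gray(np.asarray(tile_rgb))
    inverted = 1.0 - gray  # nuclei are dark
    if np.ptp(inverted) < 1e-6:
        return np.zeros(gray.shape, dtype=np.int32)
    thr = threshold_otsu(inverted)
    mask = inverted > thr
    # remove specks below min_size pixels (max_size is an inclusive threshold)
    mask = remove_small_objects(mask, max_size=min_size - 1)
    return cc_label(mask)


def extract_histomic_features(
    tile_rgb: np.ndarray, gray_levels: int = 8, min_size: int = 9
) -> HistomicFeatureVector:
    """Nucleus morphology + GLCM texture + nearest-neighbor spacing.

    Haralick sum-average is sum_k k * p_{x+y}(k) over the symmetric,
    normalized co-occurrence matrix (distance 1, averaged over the four
    directions) on the ``gray_levels``-quantized grayscale tile. A constant
    tile at quantized level g has sum-average 2 g. A tile with no detected
    nuclei yields count 0 and NaN morphology features (not an error).
    """
    tile_rgb = np.asarray(tile_rgb)
    gray = rgb2gray(tile_rgb)
    quant = np.clip((gray * gray_levels).astype(int), 0, gray_levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        quant,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=gray_levels,
        symmetric=True,
        normed=True,
    )
    p = glcm[:, :, 0, :].mean(axis=-1)
    i_idx, j_idx = np.indices(p.shape)
    sum_avg = float(((i_idx + j_idx) * p).sum())

    labels = _segment_nuclei(tile_rgb, min_size=min_size)
    props = regionprops(labels)
    count = len(props)
    if count == 0:
        return HistomicFeatureVector(0, float("nan"), float("nan"), sum_avg, float("nan"))
    areas = np.array([r.area for r in props], dtype=float)
    solidity = np.array([r.solidity for r in props], dtype=float)
    if count >= 2:
        centroids = np.array([r.centroid for r in props])
        dists, _ = cKDTree(centroids).query(centroids, k=2)
        nn = float(dists[:, 1].mean())
    else:
        nn = float("nan")
    return HistomicFeatureVector(
        nucleus_count=count,
        mean_nucleus_area=float(areas.mean()),
        mean_solidity=float(solidity.mean()),
        haralick_sum_average=sum_avg,
        mean_first_neighbor_distance=nn,
    )


def compare_top_tiles(
    score_maps: list,
    tile_bags: list,
    labels,
    q: int = 5,
    gray_levels: int = 8,
) -> pd.DataFrame:
    """Rank-sum comparison of histomic features between high-probability
    tiles of positive bags and high-(negative-)probability tiles of negative
    bags.

    From every node-positive bag the q tiles with the highest LNM
    probability are taken; from every node-negative bag the q tiles with the
    lowest (i.e. the most confidently negative). Returns one row per
    histomic feature with group medians and the two-sided rank-sum p.
    """
    labels = np.asarray(labels)
    rows_pos, rows_neg = [], []
    for smap, bag, y in zip(score_maps, tile_bags, labels):
        probs = smap.probabilities
        qq = min(q, len(probs))
        if qq < q:
            warnings.warn(f"bag {smap.bag_id}: q clamped to {qq} tiles", UserWarning)
        order = np.argsort(probs, kind="stable")
        chosen = order[-qq:] if y == 1 else order[:qq]
        target = rows_pos if y == 1 else rows_neg
        for i in chosen:
            fv = extract_histomic_features(bag.tiles[i].image, gray_levels=gray_levels)
            target.append(fv.as_dict())
    if not rows_pos or not rows_neg:
        raise ValueError("need at least one bag per class")
    df_pos = pd.DataFrame(rows_pos)
    df_neg = pd.DataFrame(rows_neg)
    out = []
    for feat in HISTOMIC_FEATURES:
        a = df_pos[feat].dropna().to_numpy()
        b = df_neg[feat].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            stat, p = float("nan"), float("nan")
        else:
            stat, p = wilcoxon_rank_sum(a, b)
        out.append(
            {
                "feature": feat,
                "median_lnm_pos": float(np.median(a)) if len(a) else float("nan"),
                "median_lnm_neg": float(np.median(b)) if len(b) else float("nan"),
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(out)
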