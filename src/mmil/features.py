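"""Instance-level feature extraction: tiles -> fixed-length vectors.

Each tile in a bag is mapped through a frozen convolutional backbone to a
feature row; the bag becomes an n_instances x feature_dim matrix. Backbones
are pluggable through a registry so the downstream MIL model only sees
``feature_dim``. The default backbone is a small two-stage convolutional
network with seeded random weights and mean/std global pooling — frozen, so
extraction is deterministic and needs no label information.

Preprocessing is fixed and recorded here as constants: pixel values are
scaled to [0, 1] and standardized with PREPROC_MEAN / PREPROC_STD per
channel; tiles are resized to the backbone's input size when needed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .tiling import TileBag

__all__ = [
    "BackboneSpec",
    "FeatureBag",
    "get_backbone",
    "extract_features",
    "cache_features",
    "load_features",
]

PREPROC_MEAN = 0.5
PREPROC_STD = 0.25


@dataclass(frozen=True)
class BackboneSpec:
    """Which instance extractor to use.

    ``name`` selects from the registry ("tinyconv" is the default CPU
    backbone). ``feature_dim`` is inferred from the architecture, never set
    by hand. ``seed`` fixes the random weight initialization.
    """

    name: str = "tinyconv"
    pretrained: bool = False
    input_size: int = 64
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return get_backbone(self).feature_dim

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class FeatureBag:
    """A bag after feature extraction: one row per tile, plus coordinates."""

    bag_id: str
    matrix: np.ndarray  # n_instances x feature_dim
    label: int | None
    coords: np.ndarray  # n_instances x 2 (grid_row, grid_col)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if not np.isfinite(self.matrix).all():
            raise ValueError(f"bag {self.bag_id}: non-finite feature entries")

    @property
    def n_instances(self) -> int:
        return self.matrix.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.matrix.shape[1]


class TinyConvBackbone:
    """Two convolution stages (5x5, stride 2, ReLU) with seeded random
    weights, followed by per-channel global mean and standard-deviation
    pooling. Output length: 2 x conv2 channels = 32.

    Random frozen convolutions act as a generic texture projector: channel
    statistics respond strongly to nucleus density and chromatin-like blob
    structure, which is the discriminative content of the tiles.
    """

    name = "tinyconv"
    c1, c2, k = 8, 16, 5

    def __init__(self, spec: BackboneSpec):
        rng = np.random.default_rng(spec.seed)
        self.input_size = spec.input_size
        self.w1 = rng.normal(0.0, np.sqrt(2.0 / (3 * self.k * self.k)),
                             size=(self.k * self.k * 3, self.c1))
        self.w2 = rng.normal(0.0, np.sqrt(2.0 / (self.c1 * self.k * self.k)),
                             size=(self.k * self.k * self.c1, self.c2))
        self.feature_dim = 2 * self.c2

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, k: int, stride: int) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(0, 1))
        win = win[::stride, ::stride]  # (H', W', C, k, k)
        h, wd = win.shape[:2]
        cols = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, -1)
        # column layout: (k, k, C) flattened — matches weight shape (k*k*C, out)
        return (cols @ w).reshape(h, wd, -1)

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        x = self._preprocess(tile)
        a1 = np.maximum(self._conv(x, self.w1, self.k, 2), 0.0)
        a2 = np.maximum(self._conv(a1, self.w2, self.k, 2), 0.0)
        flat = a2.reshape(-1, self.c2)
        return np.concatenate([flat.mean(axis=0), flat.std(axis=0)])

    def _preprocess(self, tile: np.ndarray) -> np.ndarray:
        if tile.ndim != 3 or tile.shape[2] != 3:
            raise ValueError(f"expected HxWx3 RGB tile, got shape {tile.shape}")
        x = tile.astype(np.float64) / 255.0
        if tile.shape[0] != self.input_size or tile.shape[1] != self.input_size:
            from skimage.transform import resize

            x = resize(x, (self.input_size, self.input_size, 3), anti_aliasing=True)
        return (x - PREPROC_MEAN) / PREPROC_STD


_REGISTRY = {"tinyconv": TinyConvBackbone}
_INSTANCES: dict = {}


def get_backbone(spec: BackboneSpec):
    if spec.name not in _REGISTRY:
        raise ValueError(f"unknown backbone {spec.name!r}; known: {sorted(_REGISTRY)}")
    key = (spec.name, spec.input_size, spec.seed)
    if key not in _INSTANCES:
        _INSTANCES[key] = _REGISTRY[spec.name](spec)
    return _INSTANCES[key]


def extract_features(bag: TileBag, spec: BackboneSpec) -> FeatureBag:
    """One feature row per tile; deterministic for fixed spec."""
    if len(bag) == 0:
        raise ValueError(f"bag {bag.bag_id} is empty; nothing to extract")
    backbone = get_backbone(spec)
    rows = [backbone(t.image) for t in bag.tiles]
    coords = [(t.grid_row, t.grid_col) for t in bag.tiles]
    return FeatureBag(
        bag_id=bag.bag_id,
        matrix=np.vstack(rows),
        label=bag.label,
        coords=np.asarray(coords),
    )


def _bag_checksum(fb: FeatureBag) -> str:
    h = hashlib.sha256()
    h.update(fb.matrix.tobytes())
    h.update(fb.coords.tobytes())
    return h.hexdigest()[:16]


def cache_features(bags: list, path: str | Path, spec: BackboneSpec) -> Path:
    """Write FeatureBags + JSON manifest; lossless round trip via load_features."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "backbone": spec.fingerprint(),
        "feature_dim": int(bags[0].feature_dim),
        "bags": {},
    }
    for fb in bags:
        np.savez(
            path / f"{fb.bag_id}.npz",
            matrix=fb.matrix,
            coords=fb.coords,
            label=np.int64(-1 if fb.label is None else fb.label),
        )
        manifest["bags"][fb.bag_id] = _bag_checksum(fb)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path / "manifest.json"


def load_features(
    path: str | Path,
    spec: BackboneSpec | None = None,
    tile_bags: list | None = None,
) -> list:
    """Load cached FeatureBags, verifying checksums and feature_dim.

    If ``tile_bags`` is given, bags missing from the cache are recomputed
    with ``spec`` (idempotent partial-cache completion); present bags are
    never re-extracted.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    out = []
    cached_ids = set(manifest["bags"])
    for bag_id, checksum in manifest["bags"].items():
        with np.load(path / f"{bag_id}.npz") as z:
            label = int(z["label"])
            fb = FeatureBag(
                bag_id=bag_id,
                matrix=z["matrix"],
                label=None if label < 0 else label,
                coords=z["coords"],
            )
        if fb.feature_dim != manifest["feature_dim"]:
            raise ValueError(
                f"cache manifest feature_dim {manifest['feature_dim']} != "
                f"stored {fb.feature_dim} for bag {bag_id}"
            )
        if _bag_checksum(fb) != checksum:
            raise ValueError(f"stale cache: checksum mismatch for bag {bag_id}")
        out.append(fb)
    if tile_bags is not None:
        if spec is None:
            raise ValueError("spec required to complete a partial cache")
        for tb in tile_bags:
            if tb.bag_id not in cached_ids:
                out.append(extract_features(tb, spec))
    return out
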