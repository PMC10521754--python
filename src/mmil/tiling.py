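"""Tile extraction from slide rasters and ROI-overlap filtering.

A slide image (or an assembled pseudo-slide) plus a binary region-of-interest
mask is cut into a non-overlapping grid of square tiles; tiles with
insufficient overlap with the annotated cancer region are discarded before
they enter the MIL bag. Conventions used throughout the package: 0-based
(row, col) indices, half-open pixel boxes [r0, r1) x [c0, c1), row-major tile
enumeration, no padding of partial edge tiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "RoiMask",
    "Tile",
    "TileBag",
    "compute_tile_grid",
    "compute_roi_overlap",
    "filter_tiles",
    "tile_image",
    "load_image",
    "load_mask",
]

DEFAULT_MIN_OVERLAP = 0.2  # tiles overlapping the ROI less than this are excluded


@dataclass
class RoiMask:
    """Binary ROI raster on the same pixel grid as the slide image.

    ``resolution`` is microns per pixel, recorded as metadata only (the
    nominal scan level is 20x / 0.5 um per pixel); no rescaling is performed.
    """

    pixels: np.ndarray
    resolution: float = 0.5

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        uniq = np.unique(self.pixels)
        if not np.all(np.isin(uniq, [0, 1])):
            # accept 0/255 8-bit masks
            if np.all(np.isin(uniq, [0, 255])):
                self.pixels = (self.pixels > 0).astype(np.uint8)
            else:
                raise ValueError("ROI mask must be binary (0/1 or 0/255)")
        else:
            self.pixels = self.pixels.astype(np.uint8)


@dataclass
class Tile:
    bag_id: str
    grid_row: int
    grid_col: int
    pixel_bbox: tuple  # (r0, r1, c0, c1), half-open
    roi_overlap: float = np.nan
    image: np.ndarray | None = None


@dataclass
class TileBag:
    """One patient's bag of tiles with a bag-level LNM label.

    Tile order carries no semantic meaning (the MIL pooling downstream is
    permutation invariant); it is kept stable only for reproducibility.
    """

    bag_id: str
    tiles: list = field(default_factory=list)
    label: int | None = None

    def __len__(self) -> int:
        return len(self.tiles)


def compute_tile_grid(image_shape, tile_size: int, stride: int | None = None):
    """Enumerate tile bounding boxes row-major over an image.

    Tiles whose box would exceed the image are dropped (no padding). A tile
    larger than the image yields an empty grid.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    stride = tile_size if stride is None else stride
    if stride <= 0:
        raise ValueError("stride must be positive")
    h, w = image_shape[0], image_shape[1]
    boxes = []
    for gr, r0 in enumerate(range(0, h - tile_size + 1, stride)):
        for gc, c0 in enumerate(range(0, w - tile_size + 1, stride)):
            boxes.append((gr, gc, (r0, r0 + tile_size, c0, c0 + tile_size)))
    return boxes


def compute_roi_overlap(tile_bbox, mask: RoiMask) -> float:
    """Exact fraction of the tile's pixels lying inside the ROI."""
    r0, r1, c0, c1 = tile_bbox
    h, w = mask.pixels.shape
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        raise ValueError(f"tile bbox {tile_bbox} exceeds mask bounds {(h, w)}")
    area = (r1 - r0) * (c1 - c0)
    inside = int(mask.pixels[r0:r1, c0:c1].sum())
    return inside / area


def filter_tiles(tiles, min_overlap: float = DEFAULT_MIN_OVERLAP):
    """Keep tiles with roi_overlap >= min_overlap, preserving order.

    The boundary is inclusive: a tile at exactly the threshold is kept
    (tiles with *less* than the threshold overlap are the ones excluded).
    """
    return [t for t in tiles if t.roi_overlap >= min_overlap]


def tile_image(
    image: np.ndarray,
    mask: RoiMask | np.ndarray,
    bag_id: str,
    tile_size: int,
    stride: int | None = None,
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    label: int | None = None,
) -> TileBag:
    """Cut a slide raster into a filtered TileBag."""
    if not isinstance(mask, RoiMask):
        mask = RoiMask(mask)
    if mask.pixels.shape != image.shape[:2]:
        raise ValueError(
            f"mask shape {mask.pixels.shape} != image shape {image.shape[:2]}"
        )
    tiles = []
    for gr, gc, bbox in compute_tile_grid(image.shape, tile_size, stride):
        r0, r1, c0, c1 = bbox
        t = Tile(
            bag_id=bag_id,
            grid_row=gr,
            grid_col=gc,
            pixel_bbox=bbox,
            roi_overlap=compute_roi_overlap(bbox, mask),
            image=image[r0:r1, c0:c1],
        )
        tiles.append(t)
    return TileBag(bag_id=bag_id, tiles=filter_tiles(tiles, min_overlap), label=label)


def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB slide/tile raster (PNG/TIFF) as uint8 HxWx3."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def load_mask(path: str | Path, resolution: float = 0.5) -> RoiMask:
    """Read a single-channel mask PNG (255 = ROI)."""
    with Image.open(path) as im:
        return RoiMask(np.asarray(im.convert("L")), resolution=resolution)
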