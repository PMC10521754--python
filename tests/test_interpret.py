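"""Tile score maps, heatmap rendering and histomic feature extraction."""

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from mmil.features import FeatureBag
from mmil.interpret import (
    TileScoreMap,
    compare_top_tiles,
    extract_histomic_features,
    render_heatmap,
    score_histogram,
    score_tiles,
)
from mmil.model import MMILNet, ModelConfig
from mmil.tiling import Tile, TileBag


def _feature_bag(rng, n=6, dim=6, bag_id="b"):
    coords = np.array([(i // 3, i % 3) for i in range(n)])
    return FeatureBag(bag_id, rng.normal(size=(n, dim)), 1, coords)


def _net(dim=6):
    return MMILNet(ModelConfig(in_dim=dim, seed=0))


def test_scores_in_unit_interval_and_duplicates_identical(rng):
    fb = _feature_bag(rng)
    fb.matrix[1] = fb.matrix[0]
    smap = score_tiles(_net(), fb, rng.random(4))
    p = smap.probabilities
    assert ((p >= 0) & (p <= 1)).all()
    assert p[0] == p[1]


def test_score_map_invariant_to_tile_order(rng):
    fb = _feature_bag(rng)
    net = _net()
    bio = rng.random(4)
    a = score_tiles(net, fb, bio)
    perm = rng.permutation(len(fb.matrix))
    fb2 = FeatureBag("b", fb.matrix[perm], 1, fb.coords[perm])
    b = score_tiles(net, fb2, bio)
    assert dict(((r, c), p) for r, c, p in a.entries) == dict(
        ((r, c), p) for r, c, p in b.entries
    )


def test_fingerprint_mismatch_raises(rng):
    fb = _feature_bag(rng)
    with pytest.raises(ValueError, match="fingerprint"):
        score_tiles(_net(), fb, rng.random(4),
                    expected_fingerprint={"kept": [1]}, fingerprint={"kept": [2]})


def test_histogram_counts_and_edges(rng):
    fb = _feature_bag(rng, n=10)
    smap = score_tiles(_net(), fb, rng.random(4))
    counts = score_histogram(smap, n_bins=7)
    assert counts.sum() == 10
    zero_map = TileScoreMap("z", [(0, i, 0.0) for i in range(5)], (1, 5))
    zc = score_histogram(zero_map, n_bins=10)
    assert zc[0] == 5 and zc[1:].sum() == 0
    with pytest.raises(ValueError):
        score_histogram(smap, n_bins=0)
    with pytest.raises(ValueError):
        score_histogram(TileScoreMap("e", [], (0, 0)), n_bins=5)


def test_score_map_rejects_out_of_range_probabilities():
    with pytest.raises(ValueError):
        TileScoreMap("x", [(0, 0, 1.5)], (1, 1))


def test_heatmap_monotone_colors_and_determinism(tmp_path):
    smap = TileScoreMap("m", [(0, 0, 0.0), (0, 1, 1.0), (1, 0, 0.5), (1, 1, 0.5)], (2, 2))
    p1 = render_heatmap(smap, tmp_path / "a.png", cell_px=4)
    p2 = render_heatmap(smap, tmp_path / "b.png", cell_px=4)
    assert p1.read_bytes() == p2.read_bytes()
    img = np.asarray(Image.open(p1))
    # cell centers: luminance ordering must follow probability ordering
    lum = img[..., :3].sum(axis=2).astype(float)
    v0, v1, vmid = lum[2, 2], lum[2, 6], lum[6, 2]
    assert v0 < vmid < v1  # inferno: dark at 0, bright at 1
    assert lum[6, 6] == vmid  # equal probabilities, equal colors
    with pytest.raises(ValueError):
        render_heatmap(TileScoreMap("e", [], (0, 0)), tmp_path / "e.png")


def test_heatmap_leaves_unretained_cells_transparent(tmp_path):
    smap = TileScoreMap("m", [(0, 0, 0.8)], (2, 2), colormap="viridis")
    img = np.asarray(Image.open(render_heatmap(smap, tmp_path / "t.png", cell_px=4)))
    assert img[2, 2, 3] == 255  # retained cell opaque
    assert img[6, 6, 3] == 0  # missing grid cell transparent


def test_histomic_single_square_oracle():
    tile = np.full((32, 32, 3), 255, dtype=np.uint8)
    tile[10:20, 10:20] = 20
    fv = extract_histomic_features(tile)
    assert fv.nucleus_count == 1
    assert fv.mean_nucleus_area == 100.0
    assert fv.mean_solidity == 1.0
    assert np.isnan(fv.mean_first_neighbor_distance)  # needs >= 2 nuclei


def test_histomic_regular_grid_spacing():
    tile = np.full((64, 64, 3), 255, dtype=np.uint8)
    spacing = 16
    for r in range(8, 64, spacing):
        for c in range(8, 64, spacing):
            tile[r - 2 : r + 2, c - 2 : c + 2] = 10
    fv = extract_histomic_features(tile)
    assert fv.nucleus_count == 16
    assert fv.mean_first_neighbor_distance == pytest.approx(spacing)


def test_histomic_constant_tile_sum_average_is_2g():
    for g_level, rgb in [(7, 255), (0, 10)]:
        tile = np.full((16, 16, 3), rgb, dtype=np.uint8)
        fv = extract_histomic_features(tile, gray_levels=8)
        assert fv.haralick_sum_average == pytest.approx(2 * g_level)


def test_histomic_blank_tile_zero_nuclei_not_an_error():
    fv = extract_histomic_features(np.full((16, 16, 3), 255, dtype=np.uint8))
    assert fv.nucleus_count == 0
    assert np.isnan(fv.mean_nucleus_area) and np.isnan(fv.mean_solidity)


def _tile_bag_from_images(images, bag_id="b", label=1):
    tiles = [
        Tile(bag_id, 0, j, (0, 32, 0, 32), 1.0, img) for j, img in enumerate(images)
    ]
    return TileBag(bag_id, tiles, label)


def test_compare_top_tiles_identical_populations_p_near_one(rng):
    imgs = []
    for _ in range(6):
        tile = np.full((32, 32, 3), 255, dtype=np.uint8)
        tile[5:12, 5:12] = 30
        imgs.append(tile)
    bags = [_tile_bag_from_images(imgs, "p", 1), _tile_bag_from_images(imgs, "n", 0)]
    maps = [
        TileScoreMap("p", [(0, j, 0.5) for j in range(6)], (1, 6)),
        TileScoreMap("n", [(0, j, 0.5) for j in range(6)], (1, 6)),
    ]
    out = compare_top_tiles(maps, bags, [1, 0], q=6)
    assert set(out["feature"]) == {
        "nucleus_count", "mean_nucleus_area", "mean_solidity",
        "haralick_sum_average", "mean_first_neighbor_distance",
    }
    finite = out["p_value"].dropna()
    assert (finite > 0.9).all()


def test_compare_top_tiles_clamps_q_with_warning(rng):
    img = np.full((32, 32, 3), 255, dtype=np.uint8)
    img[2:8, 2:8] = 30
    bags = [_tile_bag_from_images([img], "p", 1), _tile_bag_from_images([img], "n", 0)]
    maps = [
        TileScoreMap("p", [(0, 0, 0.9)], (1, 1)),
        TileScoreMap("n", [(0, 0, 0.1)], (1, 1)),
    ]
    with pytest.warns(UserWarning, match="clamped"):
        out = compare_top_tiles(maps, bags, [1, 0], q=5)
    assert isinstance(out, pd.DataFrame) and len(out) == 5
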