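"""Self-contained synthetic cohorts for exercising the MMIL pipeline.

Real LNM cohorts pair gigapixel H&E slides with serum tumor biomarkers and a
surgically confirmed nodal-status label; none of that is redistributable, so
this module fabricates cohorts carrying the same statistical structure the
pipeline assumes:

* every patient is a bag of square RGB tiles; tiles are blob textures with
  nucleus-like dark ellipses scattered at a Poisson rate;
* bags from node-positive patients contain a fraction of "key" tiles whose
  nucleus density is multiplied by ``density_ratio`` (node-positive tumors
  show denser tumor-cell populations), giving the image channel a weak,
  instance-level signal that only bag-level labels supervise;
* the four serum markers (CEA, CA125, CA19-9, AFP) are log-normal with
  class-dependent medians taken from clinical T3-stage values, so the
  biomarker channel carries a modest, complementary signal;
* a fraction of biomarker cells is masked completely at random (never the
  label), exercising the imputation stage.

Fixed seed => bit-identical cohort.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as _ellipse

from .biomarkers import MARKERS
from .tiling import Tile, TileBag, tile_image, load_image, load_mask

__all__ = [
    "MARKERS",
    "DEFAULT_BIOMARKER_PARAMS",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# Log-normal (mu, sigma) per class; exp(mu) targets the clinical per-class
# medians of a T3-stage colorectal cohort (units: CEA/AFP ng/mL, CA125/CA19-9
# U/mL). Sigmas are calibrated so the biomarker channel is learnable from a
# cohort of tens of patients while CA19-9 stays the most discriminative
# marker; they are much tighter than clinical marker tails (see the methods
# note on what the generator does and does not emulate).
DEFAULT_BIOMARKER_PARAMS = {
    "CEA": {"pos": (math.log(5.06), 0.22), "neg": (math.log(3.45), 0.22)},
    "CA125": {"pos": (math.log(11.90), 0.22), "neg": (math.log(11.10), 0.22)},
    "CA19_9": {"pos": (math.log(12.11), 0.18), "neg": (math.log(8.13), 0.18)},
    "AFP": {"pos": (math.log(2.44), 0.18), "neg": (math.log(2.48), 0.18)},
}

# Texture-process constants (8-bit RGB).
_BACKGROUND_RGB = np.array([235.0, 215.0, 225.0])  # pale eosin-like field
_NUCLEUS_RGB = np.array([100.0, 80.0, 150.0])  # hematoxylin-like dark purple
_NOISE_SIGMA = 8.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    ``tiles_per_bag`` may be an int or an inclusive ``(lo, hi)`` range.
    ``nucleus_rate`` is the mean ellipse count on a background tile at 64 px;
    it scales with tile area. Key tiles multiply the rate by
    ``density_ratio``.
    """

    n_patients: int = 80
    positive_fraction: float = 0.5
    tiles_per_bag: int | tuple = 20
    key_tile_fraction: float = 0.06
    tile_size: int = 64
    density_ratio: float = 3.0
    nucleus_rate: float = 6.0
    stain_offset: tuple = (0, 0, 0)  # additive RGB shift, emulates staining protocol drift
    biomarker_params: dict = field(
        default_factory=lambda: {
            m: {c: tuple(v) for c, v in d.items()}
            for m, d in DEFAULT_BIOMARKER_PARAMS.items()
        }
    )
    missing_rate: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.key_tile_fraction <= 0.0:
            raise ValueError(
                "key_tile_fraction must be > 0: with no key tiles, "
                "positive bags would be indistinguishable from negative ones"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        lo, hi = self._tile_range()
        if lo <= 0 or hi < lo:
            raise ValueError("tiles_per_bag must be a positive count or range")
        if self.density_ratio <= 1.0:
            raise ValueError("density_ratio must exceed 1")
        if len(self.stain_offset) != 3:
            raise ValueError("stain_offset must be an RGB triple")

    def _tile_range(self) -> tuple:
        if isinstance(self.tiles_per_bag, (tuple, list)):
            lo, hi = self.tiles_per_bag
            return int(lo), int(hi)
        return int(self.tiles_per_bag), int(self.tiles_per_bag)


@dataclass
class SyntheticCohort:
    bags: list  # list[TileBag]
    biomarkers: "object"  # pandas.DataFrame with MARKERS + label columns
    labels: np.ndarray
    key_flags: list  # per bag, boolean array marking key tiles
    config: SyntheticConfig

    def __post_init__(self):
        n = len(self.bags)
        if not (n == len(self.labels) == len(self.biomarkers) == len(self.key_flags)):
            raise ValueError("cohort components disagree on patient count")


def _draw_tile(
    rng: np.random.Generator,
    tile_size: int,
    rate: float,
    stain_offset=(0, 0, 0),
) -> np.ndarray:
    """One blob-texture tile: noisy pale field + Poisson-placed dark ellipses."""
    img = np.empty((tile_size, tile_size, 3), dtype=np.float64)
    img[:] = _BACKGROUND_RGB + np.asarray(stain_offset, dtype=np.float64)
    img += rng.normal(0.0, _NOISE_SIGMA, size=img.shape)
    scale = tile_size / 64.0
    n_nuclei = rng.poisson(rate)
    for _ in range(n_nuclei):
        r = rng.uniform(0, tile_size)
        c = rng.uniform(0, tile_size)
        r_rad = rng.uniform(2.5, 5.5) * scale
        c_rad = rng.uniform(2.5, 5.5) * scale
        rot = rng.uniform(0.0, np.pi)
        rr, cc = _ellipse(r, c, r_rad, c_rad, shape=(tile_size, tile_size), rotation=rot)
        color = _NUCLEUS_RGB + np.asarray(stain_offset, dtype=np.float64) + rng.normal(0.0, 10.0, size=3)
        img[rr, cc] = color + rng.normal(0.0, 5.0, size=(len(rr), 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Deterministically generate tiles, labels and biomarkers from a config."""
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_pos = int(round(n * config.positive_fraction))
    labels = np.zeros(n, dtype=np.int64)
    labels[rng.permutation(n)[:n_pos]] = 1

    lo, hi = config._tile_range()
    bags, key_flags = [], []
    for i in range(n):
        pid = f"P{i:04d}"
        n_tiles = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        if labels[i] == 1:
            keys = rng.random(n_tiles) < config.key_tile_fraction
            # construction guarantee: at least one key tile whenever the
            # expected count reaches one
            if not keys.any() and config.key_tile_fraction * n_tiles >= 1.0:
                keys[int(rng.integers(n_tiles))] = True
        else:
            keys = np.zeros(n_tiles, dtype=bool)
        tiles = []
        for j in range(n_tiles):
            rate = config.nucleus_rate * (config.tile_size / 64.0) ** 2
            if keys[j]:
                rate *= config.density_ratio
            img = _draw_tile(rng, config.tile_size, rate, config.stain_offset)
            tiles.append(
                Tile(
                    bag_id=pid,
                    grid_row=0,
                    grid_col=j,
                    pixel_bbox=(0, config.tile_size, 0, config.tile_size),
                    roi_overlap=1.0,
                    image=img,
                )
            )
        bags.append(TileBag(bag_id=pid, tiles=tiles, label=int(labels[i])))
        key_flags.append(keys)

    rows = {}
    for m in MARKERS:
        mu_pos, sd_pos = config.biomarker_params[m]["pos"]
        mu_neg, sd_neg = config.biomarker_params[m]["neg"]
        vals = np.where(
            labels == 1,
            rng.lognormal(mu_pos, sd_pos, size=n),
            rng.lognormal(mu_neg, sd_neg, size=n),
        )
        rows[m] = vals
    table = pd.DataFrame(rows)
    if config.missing_rate > 0:
        mask = rng.random((n, len(MARKERS))) < config.missing_rate
        table = table.mask(mask)
    table.insert(0, "patient_id", [b.bag_id for b in bags])
    table["label"] = labels

    return SyntheticCohort(
        bags=bags, biomarkers=table, labels=labels, key_flags=key_flags, config=config
    )


def _bag_grid(n_tiles: int) -> tuple:
    cols = int(math.ceil(math.sqrt(n_tiles)))
    rows = int(math.ceil(n_tiles / cols))
    return rows, cols


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, force: bool = False) -> Path:
    """Write a cohort to disk: pseudo-slide + mask PNGs, biomarker CSV, manifest.

    Each patient's tiles are assembled row-major into one slide raster; grid
    cells beyond the tile count stay white with a zeroed mask, so re-tiling
    the slide with the standard ROI-overlap filter recovers exactly the
    original bag. Refuses to overwrite an existing manifest unless ``force``.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    ts = cohort.config.tile_size
    patients = []
    for bag, keys in zip(cohort.bags, cohort.key_flags):
        n_tiles = len(bag)
        rows, cols = _bag_grid(n_tiles)
        slide = np.full((rows * ts, cols * ts, 3), 255, dtype=np.uint8)
        mask = np.zeros((rows * ts, cols * ts), dtype=np.uint8)
        for j, tile in enumerate(bag.tiles):
            r, c = divmod(j, cols)
            slide[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = tile.image
            mask[r * ts : (r + 1) * ts, c * ts : (c + 1) * ts] = 255
        Image.fromarray(slide).save(out / "slides" / f"{bag.bag_id}.png")
        Image.fromarray(mask, mode="L").save(out / "masks" / f"{bag.bag_id}.png")
        patients.append(
            {
                "patient_id": bag.bag_id,
                "label": int(bag.label),
                "n_tiles": n_tiles,
                "grid": [rows, cols],
                "key_tiles": [int(j) for j in np.flatnonzero(keys)],
            }
        )

    csv_table = cohort.biomarkers.copy()
    csv_table.to_csv(out / "biomarkers.csv", index=False)

    cfg = asdict(cohort.config)
    cfg["tiles_per_bag"] = (
        list(cohort.config.tiles_per_bag)
        if isinstance(cohort.config.tiles_per_bag, (tuple, list))
        else cohort.config.tiles_per_bag
    )
    manifest = {"tile_size": ts, "config": cfg, "patients": patients}
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Round-trip reader: rebuilds bags through the standard tiling path."""
    from .biomarkers import read_biomarker_table

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    if isinstance(cfg_dict.get("tiles_per_bag"), list):
        cfg_dict["tiles_per_bag"] = tuple(cfg_dict["tiles_per_bag"])
    cfg_dict["stain_offset"] = tuple(cfg_dict.get("stain_offset", (0, 0, 0)))
    cfg_dict["biomarker_params"] = {
        m: {c: tuple(v) for c, v in d.items()}
        for m, d in cfg_dict["biomarker_params"].items()
    }
    config = SyntheticConfig(**cfg_dict)
    ts = manifest["tile_size"]

    bags, key_flags, labels = [], [], []
    for rec in manifest["patients"]:
        pid = rec["patient_id"]
        img = load_image(src / "slides" / f"{pid}.png")
        mask = load_mask(src / "masks" / f"{pid}.png")
        bag = tile_image(img, mask, pid, tile_size=ts, label=rec["label"])
        if len(bag) != rec["n_tiles"]:
            raise ValueError(f"{pid}: retiled bag has {len(bag)} tiles, expected {rec['n_tiles']}")
        bags.append(bag)
        keys = np.zeros(rec["n_tiles"], dtype=bool)
        keys[rec["key_tiles"]] = True
        key_flags.append(keys)
        labels.append(rec["label"])

    table = read_biomarker_table(src / "biomarkers.csv")
    return SyntheticCohort(
        bags=bags,
        biomarkers=table,
        labels=np.asarray(labels, dtype=np.int64),
        key_flags=key_flags,
        config=config,
    )
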