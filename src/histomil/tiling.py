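"""Slide tiling: tissue masking, grid tile extraction, filtering, storage.

A slide is cut into a non-overlapping grid of fixed-size tiles anchored at
the top-left corner.  A single global Otsu threshold on the grayscale
histogram separates (darker) tissue from the bright background; tiles with
more than 60% background or with low grayscale contrast are discarded, and
at most ``max_tiles`` tiles are kept per slide (uniform random subsample
when the cap binds).  Kept tiles round-trip losslessly through an HDF5
container, one file per slide.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.color import rgb2gray

from .errors import DegenerateHistogramError, FormatError
from .synthetic import SlideRecord

DEFAULT_TILE_SIZE = 256
DEFAULT_BG_MAX = 0.60
#: The low-contrast rule: grayscale standard deviation (0-255 scale) below
#: this value marks a blank/blurred tile.  Chosen to reject featureless
#: tiles without touching textured tissue.
DEFAULT_CONTRAST_MIN = 8.0
DEFAULT_MAX_TILES = 4000


@dataclass
class TissueMask:
    """Boolean tissue mask (True = tissue) plus the Otsu cut used to build it."""

    mask: np.ndarray
    otsu_threshold: int


@dataclass
class TileRecord:
    tile_id: str
    origin: tuple[int, int]
    pixels: np.ndarray
    background_fraction: float
    contrast_stat: float


@dataclass
class TileStore:
    """Filtered tiles of one slide plus extraction metadata."""

    slide_id: str
    tiles: list[TileRecord] = field(default_factory=list)
    n_candidates: int = 0
    extraction_seed: int = 0
    tile_size: int = DEFAULT_TILE_SIZE
    warning: bool = False

    @property
    def n_kept(self) -> int:
        return len(self.tiles)


def _to_gray_u8(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale on the 0-255 integer scale."""
    if image.ndim == 2:
        gray = image.astype(np.float64)
    else:
        gray = rgb2gray(image) * 255.0
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Cut point c in 1..255 maximizing between-class variance of {<c} vs {>=c}.

    Ties are broken toward the smallest cut.  Equivalent to exhaustively
    scoring all 256 cut points on the 256-bin histogram.
    """
    hist = np.bincount(gray.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    omega = np.cumsum(hist) / total            # weight of class {<= k}
    mu = np.cumsum(hist * np.arange(256)) / total
    mu_total = mu[-1]
    w0 = omega[:-1]                            # cut c = k+1 for k in 0..254
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateHistogramError("constant image: Otsu histogram has one bin")
    mu0 = np.where(w0 > 0, mu[:-1] / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(w1 > 0, (mu_total - mu[:-1]) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    return int(np.argmax(sigma_b)) + 1


def compute_tissue_mask(slide: SlideRecord | np.ndarray) -> TissueMask:
    """Global Otsu tissue mask: pixels darker than the threshold are tissue."""
    if isinstance(slide, SlideRecord):
        image, name = slide.image, slide.slide_id
    else:
        image, name = np.asarray(slide), "<array>"
    if image.size == 0:
        raise DegenerateHistogramError(f"slide {name}: empty image")
    gray = _to_gray_u8(image)
    try:
        thr = otsu_threshold(gray)
    except DegenerateHistogramError as exc:
        raise DegenerateHistogramError(f"slide {name}: {exc}") from exc
    return TissueMask(mask=gray < thr, otsu_threshold=thr)


def _subsample_seed(seed: int, slide_id: str) -> int:
    return (int(seed) ^ zlib.crc32(slide_id.encode())) & 0x7FFFFFFF


def extract_tiles(
    slide: SlideRecord,
    mask: TissueMask,
    tile_size: int = DEFAULT_TILE_SIZE,
    bg_max: float = DEFAULT_BG_MAX,
    contrast_min: float = DEFAULT_CONTRAST_MIN,
    max_tiles: int = DEFAULT_MAX_TILES,
    seed: int = 0,
) -> TileStore:
    """Grid-extract, filter and (if needed) subsample tiles from one slide.

    A tile is kept iff its background fraction is <= ``bg_max`` (strictly
    more than ``bg_max`` background discards it) AND its grayscale standard
    deviation is >= ``contrast_min``.  If more than ``max_tiles`` survive, a
    uniform random subsample of exactly ``max_tiles`` is drawn with a
    per-slide seed derived from (seed, slide_id); the draw is over tile ids,
    so it does not depend on grid traversal order.
    """
    image = slide.image
    h, w = image.shape[:2]
    store = TileStore(
        slide_id=slide.slide_id,
        extraction_seed=seed,
        tile_size=tile_size,
    )
    if h < tile_size or w < tile_size:
        store.warning = True
        return store
    if mask.mask.shape != (h, w):
        raise FormatError("tissue mask shape does not match slide shape")

    n_rows, n_cols = h // tile_size, w // tile_size
    store.n_candidates = n_rows * n_cols
    n_pix = tile_size * tile_size
    bg_limit = int(np.floor(bg_max * n_pix + 1e-9))  # integer test: exact at the boundary

    gray = _to_gray_u8(image).astype(np.float64)
    kept: list[TileRecord] = []
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * tile_size, c * tile_size
            tile_mask = mask.mask[y : y + tile_size, x : x + tile_size]
            n_bg = n_pix - int(tile_mask.sum())
            contrast = float(gray[y : y + tile_size, x : x + tile_size].std())
            if n_bg <= bg_limit and contrast >= contrast_min:
                kept.append(
                    TileRecord(
                        tile_id=f"{slide.slide_id}:{r}_{c}",
                        origin=(y, x),
                        pixels=image[y : y + tile_size, x : x + tile_size],
                        background_fraction=n_bg / n_pix,
                        contrast_stat=contrast,
                    )
                )
    if len(kept) > max_tiles:
        rng = np.random.default_rng(_subsample_seed(seed, slide.slide_id))
        pick = np.sort(rng.choice(len(kept), size=max_tiles, replace=False))
        kept = [kept[i] for i in pick]
    store.tiles = kept
    return store


# --- HDF5 container -----------------------------------------------------

_REQUIRED_DATASETS = ("tiles", "origins", "background_fraction", "contrast_stat")


def save_tile_store(store: TileStore, path) -> None:
    ts = store.tile_size
    n = store.n_kept
    tiles = np.zeros((n, ts, ts, 3), dtype=np.uint8)
    origins = np.zeros((n, 2), dtype=np.int64)
    bg = np.zeros(n, dtype=np.float64)
    contrast = np.zeros(n, dtype=np.float64)
    for i, t in enumerate(store.tiles):
        tiles[i] = t.pixels
        origins[i] = t.origin
        bg[i] = t.background_fraction
        contrast[i] = t.contrast_stat
    with h5py.File(path, "w") as f:
        f.create_dataset("tiles", data=tiles)
        f.create_dataset("origins", data=origins)
        f.create_dataset("background_fraction", data=bg)
        f.create_dataset("contrast_stat", data=contrast)
        f.attrs["slide_id"] = store.slide_id
        f.attrs["n_candidates"] = store.n_candidates
        f.attrs["extraction_seed"] = store.extraction_seed
        f.attrs["tile_size"] = store.tile_size
        f.attrs["warning"] = store.warning


def load_tile_store(path) -> TileStore:
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise FormatError(f"tile store {path}: missing dataset {name!r}")
        tiles = f["tiles"][...]
        if tiles.ndim != 4 or tiles.shape[-1] != 3:
            raise FormatError(
                f"tile store {path}: dataset 'tiles' has shape {tiles.shape}, "
                "expected (n, size, size, 3)"
            )
        origins = f["origins"][...]
        bg = f["background_fraction"][...]
        contrast = f["contrast_stat"][...]
        slide_id = str(f.attrs["slide_id"])
        store = TileStore(
            slide_id=slide_id,
            n_candidates=int(f.attrs["n_candidates"]),
            extraction_seed=int(f.attrs["extraction_seed"]),
            tile_size=int(f.attrs.get("tile_size", DEFAULT_TILE_SIZE)),
            warning=bool(f.attrs.get("warning", False)),
        )
    n = tiles.shape[0]
    ts = store.tile_size
    for i in range(n):
        y, x = int(origins[i, 0]), int(origins[i, 1])
        store.tiles.append(
            TileRecord(
                tile_id=f"{slide_id}:{y // ts}_{x // ts}",
                origin=(y, x),
                pixels=tiles[i],
                background_fraction=float(bg[i]),
                contrast_stat=float(contrast[i]),
            )
        )
    return store


def tile_store_io(store: TileStore | None, path, mode: str) -> TileStore:
    """Single-entry I/O: ``mode='write'`` saves ``store``; ``'read'`` loads."""
    if mode == "write":
        if store is None:
            raise FormatError("write mode requires a store")
        save_tile_store(store, path)
        return store
    if mode == "read":
        return load_tile_store(path)
    raise FormatError(f"unknown mode {mode!r}")


def resample_slide(slide: SlideRecord, factor: float = 1.0) -> SlideRecord:
    """Magnification hook: rescale the slide image by ``factor``.

    Inputs are assumed to be at working resolution already, so the default
    is a no-op; a factor < 1 downsamples (anti-aliased) for slides scanned
    at a higher magnification than the pipeline expects.
    """
    if factor == 1.0:
        return slide
    from skimage.transform import rescale

    img = rescale(slide.image, factor, channel_axis=2, anti_aliasing=factor < 1.0)
    img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return SlideRecord(
        slide_id=slide.slide_id,
        patient_id=slide.patient_id,
        dataset_id=slide.dataset_id,
        class_label=slide.class_label,
        image=img,
        group_label=slide.group_label,
    )


def tile_slide(
    slide: SlideRecord,
    tile_size: int = DEFAULT_TILE_SIZE,
    bg_max: float = DEFAULT_BG_MAX,
    contrast_min: float = DEFAULT_CONTRAST_MIN,
    max_tiles: int = DEFAULT_MAX_TILES,
    seed: int = 0,
    resample_factor: float = 1.0,
) -> TileStore:
    """Convenience: optional resampling + Otsu mask + tile extraction."""
    slide = resample_slide(slide, resample_factor)
    mask = compute_tissue_mask(slide)
    return extract_tiles(
        slide, mask,
        tile_size=tile_size, bg_max=bg_max,
        contrast_min=contrast_min, max_tiles=max_tiles, seed=seed,
    )
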