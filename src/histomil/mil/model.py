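"""Weakly-supervised multiple-instance learning on tile bags.

Each slide contributes ``tiles_per_slide`` randomly drawn tiles, split into
consecutive bags of ``bag_size``; every tile inherits the slide's global
label.  Per-tile features from the backbone are arithmetic-mean pooled over
the bag and a linear head produces the bag-level class probabilities.  The
model is trained end-to-end with AdamW and cross-entropy on bag labels,
with early stopping on patient-level validation accuracy; only the
backbone's trainable tail and the head receive updates.

Slides hold only a handful of unique tiles at desk scale, so the frozen
part of the backbone is evaluated once per (tile, flip, normalizer)
combination and memoized; this cache is a pure function of its inputs and
does not affect numerics.
"""

from __future__ import annotations

import copy
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ..errors import ConfigurationError, EmptyStoreError
from ..stain import ReinhardFit, apply_reinhard
from ..tiling import TileRecord, TileStore
from . import nn
from .backbone import SmallCNN, make_backbone

logger = logging.getLogger(__name__)

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


@dataclass
class ModelConfig:
    """Hyperparameters of the MIL classifier.

    ``batch_size`` counts tiles per optimizer step, grouped by whole bags:
    the step granularity is ``max(1, batch_size // bag_size)`` bags.
    ``head_width`` documents the feature width entering the head in the
    (unavailable) ResNet-50 mode; with ``small_cnn`` the head input is the
    backbone's feature dimension.
    """

    bag_size: int = 100
    tiles_per_slide: int = 200
    backbone: str = "small_cnn"
    head_width: int = 2048
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 64
    max_epochs: int = 100
    patience: int = 20
    augment_flips: bool = True
    input_mean: tuple[float, float, float] = IMAGENET_MEAN
    input_std: tuple[float, float, float] = IMAGENET_STD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tiles_per_slide % self.bag_size != 0:
            raise ConfigurationError("tiles_per_slide must be a multiple of bag_size")
        if self.patience >= self.max_epochs:
            raise ConfigurationError("patience must be < max_epochs")
        if min(self.learning_rate, self.bag_size, self.batch_size) <= 0:
            raise ConfigurationError("rates and sizes must be positive")

    @property
    def n_bags_per_slide(self) -> int:
        return self.tiles_per_slide // self.bag_size

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("input_mean", "input_std"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Bag:
    """A fixed-size collection of tiles carrying the slide's global label."""

    slide_id: str
    label: str
    tiles: list[TileRecord]
    bag_index: int = 0


@dataclass
class SlideSample:
    """A slide's identity plus its tile store: the unit fed to training."""

    slide_id: str
    patient_id: str
    class_label: str
    store: TileStore
    dataset_id: str = ""
    group_label: str | None = None


# --- sampling and preprocessing ----------------------------------------


def sample_bag_indices(n_kept: int, config: ModelConfig, rng: np.random.Generator) -> np.ndarray:
    """Tile indices of shape (n_bags, bag_size).

    Draws ``min(tiles_per_slide, n_kept)`` tiles without replacement; a
    short draw is topped up by re-drawing fresh permutations of the store,
    so tiles are reused as evenly as possible and every slide yields exactly
    ``tiles_per_slide / bag_size`` bags.
    """
    if n_kept == 0:
        return np.zeros((0, config.bag_size), dtype=np.intp)
    need = config.tiles_per_slide
    parts = []
    got = 0
    while got < need:
        perm = rng.permutation(n_kept)
        take = min(n_kept, need - got)
        parts.append(perm[:take])
        got += take
    draw = np.concatenate(parts)
    return draw.reshape(config.n_bags_per_slide, config.bag_size)


def sample_bags(
    store: TileStore,
    config: ModelConfig,
    rng_state: np.random.Generator,
    label: str = "",
) -> list[Bag]:
    """Materialize the bags of one slide (empty list for an empty store)."""
    if store.n_kept == 0:
        logger.warning("slide %s has no tiles; excluded from bagging", store.slide_id)
        return []
    idx = sample_bag_indices(store.n_kept, config, rng_state)
    return [
        Bag(
            slide_id=store.slide_id,
            label=label,
            tiles=[store.tiles[i] for i in row],
            bag_index=b,
        )
        for b, row in enumerate(idx)
    ]


def preprocess_tile(
    tile: TileRecord | np.ndarray,
    config: ModelConfig,
    training: bool = False,
    rng_state: np.random.Generator | None = None,
) -> np.ndarray:
    """8-bit RGB tile -> standardized float32 tensor of shape (3, size, size).

    Scales to [0, 1], optionally applies independent horizontal/vertical
    flips (each with probability 1/2, training only), then subtracts and
    divides the configured per-channel mean and std.
    """
    pixels = tile.pixels if isinstance(tile, TileRecord) else np.asarray(tile)
    x = pixels.astype(np.float32) / 255.0
    if training and config.augment_flips:
        if rng_state is None:
            raise ConfigurationError("training-time preprocessing needs an RNG")
        if rng_state.random() < 0.5:
            x = x[:, ::-1]
        if rng_state.random() < 0.5:
            x = x[::-1]
    x = (x - np.asarray(config.input_mean, dtype=np.float32)) / np.asarray(
        config.input_std, dtype=np.float32
    )
    return np.ascontiguousarray(x.transpose(2, 0, 1))


def _standardize_batch(batch_u8: np.ndarray, config: ModelConfig) -> np.ndarray:
    """(N, H, W, 3) uint8 -> standardized float32, channels last."""
    x = batch_u8.astype(np.float32) / 255.0
    return (x - np.asarray(config.input_mean, dtype=np.float32)) / np.asarray(
        config.input_std, dtype=np.float32
    )


def _flip_u8(pixels: np.ndarray, fh: bool, fv: bool) -> np.ndarray:
    if fh:
        pixels = pixels[:, ::-1]
    if fv:
        pixels = pixels[::-1]
    return pixels


# --- frozen-prefix feature cache ----------------------------------------

_PREFIX_CACHE: dict[tuple, np.ndarray] = {}


def clear_prefix_cache() -> None:
    _PREFIX_CACHE.clear()


def _tile_crc(tile: TileRecord) -> int:
    crc = getattr(tile, "_crc", None)
    if crc is None:
        crc = zlib.crc32(np.ascontiguousarray(tile.pixels).tobytes())
        tile._crc = crc
    return crc


def _prefix_features(
    backbone: SmallCNN,
    store: TileStore,
    items: list[tuple[int, bool, bool]],
    config: ModelConfig,
    normalizer: ReinhardFit | None,
) -> np.ndarray:
    """Frozen-prefix features for (tile_index, flip_h, flip_v) items; memoized."""
    norm_key = normalizer.key() if normalizer is not None else None
    base = (tuple(config.input_mean), tuple(config.input_std), norm_key)
    keys = []
    missing = []
    for idx, fh, fv in items:
        tile = store.tiles[idx]
        key = (tile.tile_id, _tile_crc(tile), fh, fv, base)
        keys.append(key)
        if key not in _PREFIX_CACHE:
            missing.append((key, idx, fh, fv))
    # Normalize once per unique tile, then flip.
    if missing:
        normed: dict[int, np.ndarray] = {}
        for _, idx, _, _ in missing:
            if idx not in normed:
                pix = store.tiles[idx].pixels
                if normalizer is not None:
                    pix = apply_reinhard(pix, normalizer)
                normed[idx] = pix
        batch_keys = [m[0] for m in missing]
        batch = np.stack(
            [_flip_u8(normed[idx], fh, fv) for _, idx, fh, fv in missing]
        )
        for start in range(0, len(batch), 2):
            chunk = _standardize_batch(batch[start : start + 2], config)
            feats = backbone.forward_prefix(chunk)
            for j, key in enumerate(batch_keys[start : start + 2]):
                _PREFIX_CACHE[key] = feats[j].astype(np.float32)
    return np.stack([_PREFIX_CACHE[k] for k in keys])


# --- the model ----------------------------------------------------------


class MILModel:
    """Backbone + mean pooling + linear head."""

    def __init__(self, config: ModelConfig) -> None:
        self.config = config
        self.backbone = make_backbone(config.backbone, seed=config.seed)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 29]))
        d = self.backbone.feature_dim
        self.head = {
            "wh": nn.xavier_init(rng, d, 2),
            "bh": np.zeros(2),
        }

    @property
    def feature_dim(self) -> int:
        return self.backbone.feature_dim

    def head_logits(self, features: np.ndarray) -> np.ndarray:
        return features.astype(np.float64) @ self.head["wh"] + self.head["bh"]

    def tile_features(self, tiles_u8: np.ndarray) -> np.ndarray:
        """(N, size, size, 3) uint8 (already stain-normalized) -> (N, D)."""
        feats = []
        for start in range(0, len(tiles_u8), 2):
            chunk = _standardize_batch(tiles_u8[start : start + 2], self.config)
            prefix = self.backbone.forward_prefix(chunk)
            feats.append(self.backbone.forward_trainable(prefix))
        return np.concatenate(feats) if feats else np.zeros((0, self.feature_dim))

    def trainable_params(self) -> dict[str, np.ndarray]:
        return {**self.backbone.trainable, **self.head}

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.trainable_params().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k in self.backbone.trainable:
            self.backbone.trainable[k][...] = snap[k]
        for k in self.head:
            self.head[k][...] = snap[k]


def forward_bag(bag: Bag, model: MILModel) -> tuple[np.ndarray, np.ndarray]:
    """Mean-pool per-tile features over the bag, then apply the linear head.

    Returns (pooled_feature, class_probs); probs are (p_control, p_tumor).
    """
    if not bag.tiles:
        raise EmptyStoreError(f"bag {bag.slide_id}:{bag.bag_index} is empty")
    tiles = np.stack([t.pixels for t in bag.tiles])
    feats = model.tile_features(tiles)
    if feats.shape[1] != model.head["wh"].shape[0]:
        raise ConfigurationError("feature dimension does not match the head")
    pooled = feats.mean(axis=0)
    probs = nn.softmax(model.head_logits(pooled[None, :]))[0]
    return pooled, probs


@dataclass
class TrainedModel:
    """Training outcome: parameters at the best-validation epoch plus history."""

    model: MILModel
    config: ModelConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = 0

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {
            f"frozen_{k}": v for k, v in self.model.backbone.frozen.items()
        }
        arrays.update(
            {f"trainable_{k}": v for k, v in self.model.backbone.trainable.items()}
        )
        arrays.update({f"head_{k}": v for k, v in self.model.head.items()})
        np.savez(out / "params.npz", **arrays)
        meta = {
            "config": self.config.to_dict(),
            "history": self.history,
            "best_epoch": self.best_epoch,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir) -> "TrainedModel":
        out = Path(out_dir)
        meta = json.loads((out / "model.json").read_text())
        config = ModelConfig.from_dict(meta["config"])
        model = MILModel(config)
        with np.load(out / "params.npz") as npz:
            for k in model.backbone.frozen:
                model.backbone.frozen[k] = npz[f"frozen_{k}"]
            for k in model.backbone.trainable:
                model.backbone.trainable[k] = npz[f"trainable_{k}"]
            for k in model.head:
                model.head[k] = npz[f"head_{k}"]
        return cls(
            model=model,
            config=config,
            history=meta["history"],
            best_epoch=meta["best_epoch"],
        )


# --- training -----------------------------------------------------------


def _entity_set(slides: list[SlideSample]) -> set[tuple[str, str]]:
    return {(s.patient_id, s.class_label) for s in slides}


def _bag_forward_unique(
    model: MILModel,
    store: TileStore,
    slots: list[tuple[int, bool, bool]],
    normalizer: ReinhardFit | None,
    want_cache: bool = False,
):
    """Forward a bag given (tile, flip) slots, deduplicating repeated slots."""
    uniq: dict[tuple[int, bool, bool], int] = {}
    counts: list[int] = []
    for slot in slots:
        if slot in uniq:
            counts[uniq[slot]] += 1
        else:
            uniq[slot] = len(counts)
            counts.append(1)
    items = list(uniq.keys())
    prefix = _prefix_features(model.backbone, store, items, model.config, normalizer)
    weights = np.asarray(counts, dtype=np.float64) / len(slots)
    if want_cache:
        feats, cache = model.backbone.forward_trainable(prefix, want_cache=True)
        return feats, weights, cache
    feats = model.backbone.forward_trainable(prefix)
    return feats, weights, None


def _slide_probs(
    model: MILModel,
    store: TileStore,
    config: ModelConfig,
    rng: np.random.Generator,
    normalizer: ReinhardFit | None,
) -> np.ndarray:
    """Mean of bag-level probabilities over the slide's bags (no flips)."""
    if store.n_kept == 0:
        raise EmptyStoreError(f"slide {store.slide_id} has an empty tile store")
    idx = sample_bag_indices(store.n_kept, config, rng)
    bag_probs = []
    for row in idx:
        slots = [(int(i), False, False) for i in row]
        feats, weights, _ = _bag_forward_unique(model, store, slots, normalizer)
        pooled = weights @ feats.astype(np.float64)
        bag_probs.append(nn.softmax(model.head_logits(pooled[None, :]))[0])
    return np.mean(bag_probs, axis=0)


def _val_patient_accuracy(
    model: MILModel,
    val_slides: list[SlideSample],
    config: ModelConfig,
    normalizer: ReinhardFit | None,
) -> float:
    """Patient-level accuracy on the validation slides (fixed bag draws)."""
    from ..evaluation import aggregate_patient_probability  # local: avoids cycle

    by_entity: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in val_slides:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, zlib.crc32(s.slide_id.encode())])
        )
        probs = _slide_probs(model, s.store, config, rng, normalizer)
        by_entity.setdefault((s.patient_id, s.class_label), []).append(probs)
    correct = 0
    for (_, cls), plist in by_entity.items():
        final = aggregate_patient_probability(plist)
        pred = "tumor" if final[1] >= final[0] else "control"
        correct += pred == cls
    return correct / len(by_entity)


def train_model(
    train_slides: list[SlideSample],
    val_slides: list[SlideSample],
    config: ModelConfig,
    normalizer: ReinhardFit | None = None,
) -> TrainedModel:
    """Train the MIL classifier with early stopping on validation accuracy.

    Fully reproducible given ``config.seed``; frozen backbone parameters are
    asserted byte-identical before and after training.
    """
    if not train_slides or not val_slides:
        raise ConfigurationError("train and validation sets must be non-empty")
    if len({s.class_label for s in val_slides}) < 2:
        raise ConfigurationError("validation set must contain both classes")
    overlap = _entity_set(train_slides) & _entity_set(val_slides)
    if overlap:
        raise ConfigurationError(f"train/val entity overlap: {sorted(overlap)[:3]}")

    usable = [s for s in train_slides if s.store.n_kept > 0]
    for s in train_slides:
        if s.store.n_kept == 0:
            logger.warning("slide %s has no tiles; excluded from training", s.slide_id)

    model = MILModel(config)
    frozen_before = model.backbone.frozen_bytes()
    params = model.trainable_params()
    optimizer = nn.AdamW(
        params, lr=config.learning_rate, weight_decay=config.weight_decay
    )
    stopper = nn.EarlyStopper(config.patience)
    bags_per_step = max(1, config.batch_size // config.bag_size)
    history: list[dict] = []
    best_snapshot = model.snapshot()

    root = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 101])
    epoch_seeds = root.generate_state(config.max_epochs)

    onehot = {"control": np.array([1.0, 0.0]), "tumor": np.array([0.0, 1.0])}

    for epoch in range(1, config.max_epochs + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(epoch_seeds[epoch - 1])]))
        order = rng.permutation(len(usable))
        losses = []
        pending: list[tuple] = []

        def _flush(pending_bags):
            if not pending_bags:
                return
            grads = {k: np.zeros_like(v) for k, v in params.items()}
            for feats, weights, cache, label, store_ref in pending_bags:
                feats64 = feats.astype(np.float64)
                pooled = weights @ feats64
                logits = model.head_logits(pooled[None, :])[0]
                probs = nn.softmax(logits)
                loss = -np.log(max(probs @ onehot[label], 1e-12))
                losses.append(loss)
                dlogits = (probs - onehot[label]) / len(pending_bags)
                grads["wh"] += np.outer(pooled, dlogits)
                grads["bh"] += dlogits
                dpooled = model.head["wh"] @ dlogits
                dfeat = np.outer(weights, dpooled).astype(np.float32)
                bb = model.backbone.backward_trainable(dfeat, cache)
                grads["w3"] += bb["w3"]
                grads["b3"] += bb["b3"]
            optimizer.step(grads)

        for si in order:
            slide = usable[si]
            idx = sample_bag_indices(slide.store.n_kept, config, rng)
            for row in idx:
                slots = []
                for i in row:
                    fh = bool(rng.random() < 0.5) if config.augment_flips else False
                    fv = bool(rng.random() < 0.5) if config.augment_flips else False
                    slots.append((int(i), fh, fv))
                feats, weights, cache = _bag_forward_unique(
                    model, slide.store, slots, normalizer, want_cache=True
                )
                pending.append((feats, weights, cache, slide.class_label, slide.store))
                if len(pending) >= bags_per_step:
                    _flush(pending)
                    pending = []
        _flush(pending)

        val_metric = _val_patient_accuracy(model, val_slides, config, normalizer)
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_metric": val_metric}
        )
        improved = val_metric > stopper.best_metric
        should_stop = stopper.update(epoch, val_metric)
        if improved:
            best_snapshot = model.snapshot()
        if should_stop:
            break

    model.restore(best_snapshot)
    assert model.backbone.frozen_bytes() == frozen_before, "frozen parameters changed"
    return TrainedModel(
        model=model,
        config=copy.deepcopy(config),
        history=history,
        best_epoch=stopper.best_epoch,
    )


# --- inference ----------------------------------------------------------


def predict_slide(
    model: TrainedModel | MILModel,
    store: TileStore,
    config: ModelConfig | None = None,
    rng_state: np.random.Generator | None = None,
    normalizer: ReinhardFit | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Slide-level probabilities plus per-tile probabilities.

    The slide probability is the arithmetic mean of the bag-level class
    probabilities over the slide's bags; per-tile probabilities run the head
    on each tile's un-pooled feature (a bag of one).
    """
    mil = model.model if isinstance(model, TrainedModel) else model
    config = config or mil.config
    if store.n_kept == 0:
        raise EmptyStoreError(f"slide {store.slide_id} has an empty tile store")
    rng = rng_state or np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF]))
    slide_probs = _slide_probs(mil, store, config, rng, normalizer)
    items = [(i, False, False) for i in range(store.n_kept)]
    prefix = _prefix_features(mil.backbone, store, items, config, normalizer)
    feats = mil.backbone.forward_trainable(prefix)
    per_tile = nn.softmax(mil.head_logits(feats))
    return slide_probs, per_tile


def extract_slide_feature(
    model: TrainedModel | MILModel,
    store: TileStore,
    config: ModelConfig | None = None,
    rng_state: np.random.Generator | None = None,
    normalizer: ReinhardFit | None = None,
) -> np.ndarray:
    """Mean of bag-pooled (pre-head) features over the slide's bags."""
    mil = model.model if isinstance(model, TrainedModel) else model
    config = config or mil.config
    if store.n_kept == 0:
        raise EmptyStoreError(f"slide {store.slide_id} has an empty tile store")
    rng = rng_state or np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF]))
    idx = sample_bag_indices(store.n_kept, config, rng)
    pooled = []
    for row in idx:
        slots = [(int(i), False, False) for i in row]
        feats, weights, _ = _bag_forward_unique(mil, store, slots, normalizer)
        pooled.append(weights @ feats.astype(np.float64))
    return np.mean(pooled, axis=0)
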