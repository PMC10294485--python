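"""MIL classifier contracts: bagging, preprocessing, pooling, training mechanics."""

import numpy as np
import pytest

from histomil import (
    Bag,
    MILModel,
    ModelConfig,
    SlideSample,
    TileStore,
    TrainedModel,
    forward_bag,
    predict_slide,
    preprocess_tile,
    sample_bags,
    train_model,
)
from histomil.errors import (
    BackboneUnavailableError,
    ConfigurationError,
    EmptyStoreError,
)
from histomil.mil.model import sample_bag_indices, clear_prefix_cache
from histomil.mil.nn import EarlyStopper
from histomil.tiling import TileRecord


def _store(rng, n_tiles, slide_id="s1", size=256):
    tiles = [
        TileRecord(
            tile_id=f"{slide_id}:{i}",
            origin=(0, i * size),
            pixels=rng.integers(0, 255, size=(size, size, 3)).astype(np.uint8),
            background_fraction=0.1,
            contrast_stat=40.0,
        )
        for i in range(n_tiles)
    ]
    return TileStore(slide_id=slide_id, tiles=tiles, n_candidates=n_tiles)


@pytest.fixture
def cfg():
    return ModelConfig(max_epochs=5, patience=2, seed=0)


class TestConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ConfigurationError):
            ModelConfig(bag_size=100, tiles_per_slide=150)
        with pytest.raises(ConfigurationError):
            ModelConfig(patience=100, max_epochs=100)

    def test_resnet_backbone_unavailable(self):
        with pytest.raises(BackboneUnavailableError):
            MILModel(ModelConfig(backbone="resnet50_imagenet"))


class TestSampleBags:
    def test_full_store_gives_two_bags_of_distinct_tiles(self, rng, cfg):
        idx = sample_bag_indices(4000, cfg, rng)
        assert idx.shape == (2, 100)
        assert len(np.unique(idx)) == 200

    def test_short_store_topped_up_with_reuse(self, rng, cfg):
        idx = sample_bag_indices(150, cfg, rng)
        assert idx.shape == (2, 100)
        counts = np.bincount(idx.ravel(), minlength=150)
        assert (counts >= 1).all()
        assert (counts == 2).sum() == 50  # exactly 50 tiles drawn twice

    def test_exhaustive_draw_single_bag(self, rng):
        cfg = ModelConfig(bag_size=100, tiles_per_slide=100)
        idx = sample_bag_indices(100, cfg, rng)
        assert idx.shape == (1, 100)
        assert sorted(idx.ravel()) == list(range(100))

    def test_empty_store_excluded_with_empty_result(self, rng, cfg):
        store = TileStore(slide_id="empty")
        assert sample_bags(store, cfg, rng) == []


class TestPreprocessTile:
    def test_inference_is_deterministic_identity_standardization(self, rng):
        cfg = ModelConfig(input_mean=(0, 0, 0), input_std=(1, 1, 1))
        tile = rng.integers(0, 255, size=(256, 256, 3)).astype(np.uint8)
        a = preprocess_tile(tile, cfg, training=False)
        b = preprocess_tile(tile, cfg, training=False)
        assert np.array_equal(a, b)
        assert np.allclose(a, (tile.astype(np.float32) / 255.0).transpose(2, 0, 1))

    def test_imagenet_standardization(self, rng):
        cfg = ModelConfig()
        tile = rng.integers(0, 255, size=(32, 32, 3)).astype(np.uint8)
        out = preprocess_tile(tile, cfg, training=False)
        expected = (tile / 255.0 - np.array(cfg.input_mean)) / np.array(cfg.input_std)
        assert np.allclose(out, expected.transpose(2, 0, 1), atol=1e-6)

    def test_double_horizontal_flip_is_identity(self, rng):
        tile = rng.integers(0, 255, size=(16, 16, 3)).astype(np.uint8)
        assert np.array_equal(tile[:, ::-1][:, ::-1], tile)

    def test_training_flips_follow_rng(self, rng):
        cfg = ModelConfig()
        tile = np.zeros((8, 8, 3), np.uint8)
        tile[0, 0] = 255

        class FakeRng:
            def __init__(self, vals):
                self.vals = list(vals)

            def random(self):
                return self.vals.pop(0)

        out = preprocess_tile(tile, cfg, training=True, rng_state=FakeRng([0.1, 0.9]))
        # horizontal flip applied, vertical not: marker moves to top-right
        marker = np.unravel_index(np.argmax(out[0]), out[0].shape)
        assert marker == (0, 7)


class TestForwardBag:
    def test_permutation_invariance(self, rng, cfg):
        store = _store(rng, 12)
        model = MILModel(cfg)
        tiles = store.tiles[:8]
        bag_a = Bag("s1", "tumor", tiles)
        bag_b = Bag("s1", "tumor", tiles[::-1])
        fa, pa = forward_bag(bag_a, model)
        fb, pb = forward_bag(bag_b, model)
        assert np.allclose(fa, fb, atol=1e-5)
        assert np.allclose(pa, pb, atol=1e-5)

    def test_identical_tiles_pool_to_single_feature(self, rng, cfg):
        store = _store(rng, 1)
        model = MILModel(cfg)
        bag1 = Bag("s1", "tumor", store.tiles * 10)
        bag_single = Bag("s1", "tumor", store.tiles)
        f10, _ = forward_bag(bag1, model)
        f1, _ = forward_bag(bag_single, model)
        assert np.allclose(f10, f1, atol=1e-5)

    def test_probabilities_on_simplex(self, rng, cfg):
        model = MILModel(cfg)
        store = _store(rng, 5)
        _, probs = forward_bag(Bag("s1", "control", store.tiles), model)
        assert probs.shape == (2,)
        assert probs.min() >= 0
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_pooling_matches_manual_average_oracle(self, rng, cfg):
        # forward_bag must equal: per-tile features averaged by hand, then
        # the linear head applied to the average.
        from histomil.mil.nn import softmax

        model = MILModel(cfg)
        store = _store(rng, 6)
        bag = Bag("s1", "tumor", store.tiles)
        pooled, probs = forward_bag(bag, model)
        per_tile = model.tile_features(np.stack([t.pixels for t in bag.tiles]))
        manual = per_tile.mean(axis=0)
        assert np.allclose(pooled, manual, atol=1e-5)
        assert np.allclose(probs, softmax(model.head_logits(manual[None, :]))[0], atol=1e-5)


class TestEarlyStopping:
    def test_stops_at_best_epoch_plus_patience_on_scripted_metric(self):
        # metric improves at epochs 1..3 then plateaus
        scripted = [0.5, 0.6, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7, 0.7]
        stopper = EarlyStopper(patience=4)
        stopped_at = None
        for epoch, m in enumerate(scripted, start=1):
            if stopper.update(epoch, m):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 3
        assert stopped_at == 3 + 4

    def test_plateau_from_start(self):
        stopper = EarlyStopper(patience=2)
        assert not stopper.update(1, 0.5)   # first value is an improvement over -inf
        assert not stopper.update(2, 0.5)
        assert stopper.update(3, 0.5)
        assert stopper.best_epoch == 1


def _training_cohort(rng, n_per_class=4, n_tiles=8, size=64):
    """Tiny synthetic-texture cohort with an obvious class difference."""
    slides = []
    for cls, bright in (("control", 60), ("tumor", 180)):
        for i in range(n_per_class):
            tiles = []
            for j in range(n_tiles):
                base = rng.integers(bright - 30, bright + 30, size=(size, size, 3))
                tiles.append(
                    TileRecord(
                        tile_id=f"{cls}{i}:{j}",
                        origin=(0, j * size),
                        pixels=base.astype(np.uint8),
                        background_fraction=0.0,
                        contrast_stat=30.0,
                    )
                )
            store = TileStore(slide_id=f"{cls}{i}", tiles=tiles, n_candidates=n_tiles,
                              tile_size=size)
            slides.append(
                SlideSample(slide_id=f"{cls}{i}", patient_id=f"p_{cls}{i}",
                            class_label=cls, store=store)
            )
    return slides


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(bag_size=8, tiles_per_slide=16, max_epochs=4, patience=2, seed=3)


class TestTraining:
    def test_determinism_and_frozen_conservation(self, tiny_cfg):
        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        train = [s for s in slides if not s.slide_id.endswith("0")]
        val = [s for s in slides if s.slide_id.endswith("0")]

        clear_prefix_cache()
        m1 = train_model(train, val, tiny_cfg)
        m2 = train_model(train, val, tiny_cfg)
        assert m1.history == m2.history
        for k, v in m1.model.trainable_params().items():
            assert np.array_equal(v, m2.model.trainable_params()[k])
        # frozen backbone identical to a freshly built one, byte for byte
        fresh = MILModel(tiny_cfg)
        assert m1.model.backbone.frozen_bytes() == fresh.backbone.frozen_bytes()
        assert m1.best_epoch <= len(m1.history)

    def test_validation_must_contain_both_classes(self, tiny_cfg):
        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        train = [s for s in slides if not s.slide_id.endswith("0")]
        val = [s for s in slides if s.slide_id == "control0"]
        with pytest.raises(ConfigurationError):
            train_model(train, val, tiny_cfg)

    def test_train_val_entity_overlap_rejected(self, tiny_cfg):
        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        with pytest.raises(ConfigurationError):
            train_model(slides, slides[:2] + slides[-2:], tiny_cfg)

    def test_predict_slide_contracts(self, tiny_cfg):
        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        train = [s for s in slides if not s.slide_id.endswith("0")]
        val = [s for s in slides if s.slide_id.endswith("0")]
        trained = train_model(train, val, tiny_cfg)

        store = val[0].store
        probs, per_tile = predict_slide(trained, store, rng_state=np.random.default_rng(5))
        assert probs.shape == (2,) and probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert per_tile.shape == (store.n_kept, 2)
        assert np.allclose(per_tile.sum(axis=1), 1.0, atol=1e-9)

        with pytest.raises(EmptyStoreError):
            predict_slide(trained, TileStore(slide_id="void"))

    def test_slide_probs_average_bag_probs(self, tiny_cfg):
        # With two bags, the slide probability is the mean of the two
        # bag-level probabilities.
        from histomil.mil.model import _slide_probs, sample_bag_indices, _bag_forward_unique
        from histomil.mil.nn import softmax

        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        model = MILModel(tiny_cfg)
        store = slides[0].store
        probs = _slide_probs(model, store, tiny_cfg, np.random.default_rng(9), None)
        idx = sample_bag_indices(store.n_kept, tiny_cfg, np.random.default_rng(9))
        manual = []
        for row in idx:
            feats, w, _ = _bag_forward_unique(model, store, [(int(i), False, False) for i in row], None)
            manual.append(softmax(model.head_logits((w @ feats.astype(np.float64))[None, :]))[0])
        assert np.allclose(probs, np.mean(manual, axis=0), atol=1e-12)

    def test_model_save_load_roundtrip(self, tiny_cfg, tmp_path):
        rng = np.random.default_rng(0)
        slides = _training_cohort(rng)
        train = [s for s in slides if not s.slide_id.endswith("0")]
        val = [s for s in slides if s.slide_id.endswith("0")]
        trained = train_model(train, val, tiny_cfg)
        trained.save(tmp_path / "model")
        back = TrainedModel.load(tmp_path / "model")
        for k, v in trained.model.trainable_params().items():
            assert np.array_equal(v, back.model.trainable_params()[k])
        assert back.best_epoch == trained.best_epoch
        assert back.history == trained.history
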