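"""Batch-effect diagnosis: do learned slide features separate classes or datasets?

A model that latched onto dataset-specific stain rather than biology shows
a characteristic signature: in feature space, a slide's nearest neighbors
share its dataset of origin more often than its class.  The
``confounding_index`` (k-NN dataset purity minus k-NN class purity)
operationalizes the visual cluster-plot diagnosis as a single testable
number: positive values mean the features encode origin over biology.

The 2-D embedding is a reporting convenience only; every quantitative
claim is made on the original feature vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError
from .mil.model import MILModel, ModelConfig, SlideSample, TrainedModel, extract_slide_feature
from .stain import ReinhardFit

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """One pooled feature vector per slide plus its class and dataset labels."""

    features: np.ndarray
    slide_ids: list[str]
    class_labels: list[str]
    dataset_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.features)
        if not (len(self.slide_ids) == len(self.class_labels) == len(self.dataset_ids) == n):
            raise ParameterError("feature table columns disagree in length")
        if np.isnan(self.features).any():
            raise ParameterError("feature table contains missing values")


@dataclass
class SeparationReport:
    k: int
    purity_class: float
    purity_dataset: float
    confounding_index: float
    embedding_2d: np.ndarray | None = None


def extract_pooled_features(
    model: TrainedModel | MILModel,
    samples: list[SlideSample],
    config: ModelConfig | None = None,
    normalizer: ReinhardFit | None = None,
    seed: int = 0,
) -> FeatureTable:
    """Per-slide mean bag-pooled (pre-head) features; empty stores are skipped."""
    import zlib

    feats, sids, classes, datasets = [], [], [], []
    for s in samples:
        if s.store.n_kept == 0:
            logger.warning("slide %s has no tiles; skipped in feature extraction", s.slide_id)
            continue
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(s.slide_id.encode())])
        )
        feats.append(
            extract_slide_feature(model, s.store, config, rng_state=rng, normalizer=normalizer)
        )
        sids.append(s.slide_id)
        classes.append(s.class_label)
        datasets.append(s.dataset_id)
    return FeatureTable(
        features=np.asarray(feats, dtype=np.float64),
        slide_ids=sids,
        class_labels=classes,
        dataset_ids=datasets,
    )


def knn_label_purity(features: np.ndarray, labels: list[str], k: int = 10) -> float:
    """Mean fraction of each row's k nearest neighbors sharing its label.

    Euclidean distance on the raw features, self excluded, distance ties
    broken by row order.  Constant labels give purity 1.0 (with a warning):
    there is nothing to separate.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    n = len(features)
    if n <= k:
        raise ParameterError(f"need more rows ({n}) than neighbors (k={k})")
    if len(np.unique(labels)) < 2:
        logger.warning("constant labels: k-NN purity is trivially 1.0")
        return 1.0
    dist = cdist(features, features)
    np.fill_diagonal(dist, np.inf)
    nearest = np.argsort(dist, axis=1, kind="stable")[:, :k]
    same = labels[nearest] == labels[:, None]
    return float(same.mean())


def embed_2d(features: np.ndarray, seed: int = 0) -> np.ndarray:
    """Deterministic 2-D UMAP embedding of the feature rows (reporting only)."""
    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n < 10:
        raise ParameterError(
            f"n={n} is too small for a 2-D embedding; use k-NN purity directly"
        )
    import umap

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(15, n - 1),
        random_state=int(seed) & 0x7FFFFFFF,
    )
    coords = reducer.fit_transform(features)
    if not np.isfinite(coords).all():
        raise ParameterError("embedding produced non-finite coordinates")
    return np.asarray(coords, dtype=np.float64)


def diagnose_separation(
    table: FeatureTable,
    k: int = 10,
    seed: int = 0,
    with_embedding: bool = True,
) -> SeparationReport:
    """Class vs dataset k-NN purity and their difference (the confounding index)."""
    purity_class = knn_label_purity(table.features, table.class_labels, k=k)
    purity_dataset = knn_label_purity(table.features, table.dataset_ids, k=k)
    embedding = embed_2d(table.features, seed=seed) if with_embedding else None
    return SeparationReport(
        k=k,
        purity_class=purity_class,
        purity_dataset=purity_dataset,
        confounding_index=purity_dataset - purity_class,
        embedding_2d=embedding,
    )
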