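"""Patient-wise evaluation: folds, aggregation, metrics, protocols.

The evaluation unit is the *entity* (patient_id, class_label): a patient
owning both a tumor and a control slide contributes one entity per class,
because the two represent different tissue states.  Folds partition
entities, so no entity's slides ever straddle train and test; stratified
folds balance classes to within one entity.

A patient's final probability for a class is the arithmetic mean of the
class probability over the patient's slides of that entity, with a softmax
applied to the mean vector when more than one slide contributed; a single
slide's prediction is used directly.  All metrics (accuracy, binary F1 with
tumor as the positive class, AUC on the tumor probability) are computed at
the patient level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .errors import ConfigurationError, LeakageError, ManifestError, ParameterError
from .mil.model import (
    ModelConfig,
    SlideSample,
    TrainedModel,
    _slide_probs,
    train_model,
)
from .stain import ReinhardFit
from .tiling import TileStore

logger = logging.getLogger(__name__)

Entity = tuple[str, str]  # (patient_id, class_label)


@dataclass
class SplitPlan:
    k: int
    assignments: dict[Entity, int]
    seed: int
    group_names: list[str] | None = None

    def fold_entities(self, fold: int) -> list[Entity]:
        return sorted(e for e, f in self.assignments.items() if f == fold)

    def complement_entities(self, fold: int) -> list[Entity]:
        return sorted(e for e, f in self.assignments.items() if f != fold)


@dataclass
class PatientPrediction:
    patient_id: str
    class_label: str
    final_probs: np.ndarray
    n_slides_used: int


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    auc: float | None
    confusion: np.ndarray
    per_fold: list["MetricsReport"] | None = None
    mean_sd: dict[str, tuple[float, float]] | None = None


def _entities_of(manifest: pd.DataFrame) -> list[Entity]:
    ents = manifest[["patient_id", "class_label"]].drop_duplicates()
    return [tuple(r) for r in ents.itertuples(index=False)]


def _check_manifest(manifest: pd.DataFrame) -> None:
    per_patient = manifest.groupby("patient_id")["dataset_id"].nunique()
    bad = per_patient[per_patient > 1]
    if len(bad):
        raise ManifestError(
            f"patients appear in multiple datasets: {list(bad.index[:3])}"
        )


def make_patient_folds(
    manifest: pd.DataFrame,
    k: int,
    seed: int = 0,
    group_by: str | None = None,
) -> SplitPlan:
    """Patient-wise folds over entities.

    Stratified mode: entities of each class are shuffled and dealt
    round-robin into ``k`` folds, so per-fold class counts deviate from
    perfect stratification by at most one.  Grouped mode: one fold per
    distinct value of ``group_by`` (``k`` is overridden), each fold pure in
    its group — the per-country protocol.
    """
    _check_manifest(manifest)
    if group_by is not None:
        if group_by not in manifest.columns:
            raise ParameterError(f"manifest lacks column {group_by!r}")
        groups = sorted(g for g in manifest[group_by].unique())
        assignments: dict[Entity, int] = {}
        for ent in _entities_of(manifest):
            sub = manifest[manifest["patient_id"] == ent[0]]
            g = sub[group_by].iloc[0]
            assignments[ent] = groups.index(g)
        return SplitPlan(k=len(groups), assignments=assignments, seed=seed, group_names=groups)

    entities = _entities_of(manifest)
    rng = np.random.default_rng(seed)
    assignments = {}
    for cls in sorted({c for _, c in entities}):
        cls_entities = sorted(e for e in entities if e[1] == cls)
        if len(cls_entities) < k:
            raise ConfigurationError(
                f"class {cls!r} has {len(cls_entities)} entities, fewer than k={k}"
            )
        order = rng.permutation(len(cls_entities))
        for pos, idx in enumerate(order):
            assignments[cls_entities[idx]] = pos % k
    return SplitPlan(k=k, assignments=assignments, seed=seed)


def split_train_val(
    entities: list[Entity],
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Entity], list[Entity]]:
    """80-20 train/validation split of entities, stratified by class."""
    rng = np.random.default_rng(seed)
    train: list[Entity] = []
    val: list[Entity] = []
    for cls in sorted({c for _, c in entities}):
        cls_entities = sorted(e for e in entities if e[1] == cls)
        order = rng.permutation(len(cls_entities))
        n_val = max(1, int(round(val_fraction * len(cls_entities))))
        for pos, idx in enumerate(order):
            (val if pos < n_val else train).append(cls_entities[idx])
    return sorted(train), sorted(val)


def aggregate_patient_probability(
    slide_probs: list[np.ndarray] | np.ndarray,
    softmax_single: bool = False,
) -> np.ndarray:
    """Patient-level probability from the patient's slide probabilities.

    Componentwise arithmetic mean over the N slides followed by a softmax of
    the mean vector.  With a single slide the prediction is used directly
    (no softmax) unless ``softmax_single`` asks for the uniform rule.
    """
    probs = np.asarray(slide_probs, dtype=np.float64)
    if probs.ndim != 2 or len(probs) == 0:
        raise ParameterError("need a non-empty list of probability vectors")
    if len(probs) == 1 and not softmax_single:
        return probs[0]
    mean = probs.mean(axis=0)
    e = np.exp(mean - mean.max())
    return e / e.sum()


def compute_metrics(predictions: list[PatientPrediction]) -> MetricsReport:
    """Patient-level accuracy, binary F1 (tumor positive), AUC, confusion.

    Argmax ties break toward tumor (conservative for a screening task).
    AUC is undefined (None) when only one class is present.
    """
    if not predictions:
        raise ParameterError("no predictions to score")
    y_true = np.array([p.class_label == "tumor" for p in predictions], dtype=int)
    p_tumor = np.array([p.final_probs[1] for p in predictions], dtype=float)
    y_pred = np.array([p.final_probs[1] >= p.final_probs[0] for p in predictions], dtype=int)
    confusion = np.zeros((2, 2), dtype=int)
    for t, pr in zip(y_true, y_pred):
        confusion[t, pr] += 1
    accuracy = float(np.trace(confusion) / confusion.sum())
    f1 = float(f1_score(y_true, y_pred, pos_label=1, zero_division=0))
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, p_tumor))
    return MetricsReport(accuracy=accuracy, f1=f1, auc=auc, confusion=confusion)


# --- protocols ----------------------------------------------------------


@dataclass
class CohortData:
    """A manifest plus one tile store per slide."""

    name: str
    manifest: pd.DataFrame
    stores: dict[str, TileStore]

    def samples(self, entities: set[Entity] | None = None) -> list[SlideSample]:
        out = []
        for row in self.manifest.itertuples(index=False):
            ent = (row.patient_id, row.class_label)
            if entities is not None and ent not in entities:
                continue
            out.append(
                SlideSample(
                    slide_id=row.slide_id,
                    patient_id=row.patient_id,
                    class_label=row.class_label,
                    store=self.stores[row.slide_id],
                    dataset_id=row.dataset_id,
                    group_label=getattr(row, "group_label", None),
                )
            )
        return out


def merge_cohorts(name: str, cohorts: list[CohortData]) -> CohortData:
    manifest = pd.concat([c.manifest for c in cohorts], ignore_index=True)
    stores: dict[str, TileStore] = {}
    for c in cohorts:
        dup = set(stores) & set(c.stores)
        if dup:
            raise ManifestError(f"duplicate slide ids across cohorts: {sorted(dup)[:3]}")
        stores.update(c.stores)
    _check_manifest(manifest)
    return CohortData(name=name, manifest=manifest, stores=stores)


def check_leakage(
    train: list[SlideSample],
    test: list[SlideSample],
    patient_strict: bool = False,
) -> None:
    """Raise if train and test share entities, same-class patients, or slides.

    ``patient_strict`` additionally rejects any shared patient id, even
    across classes — the right check when train and test are different
    cohorts (within one cohort, a dual-class patient's two entities may
    legitimately fall on opposite sides of a split).
    """
    train_ents = {(s.patient_id, s.class_label) for s in train}
    test_ents = {(s.patient_id, s.class_label) for s in test}
    shared = train_ents & test_ents
    if shared:
        raise LeakageError(f"entities in both train and test: {sorted(shared)[:3]}")
    shared_slides = {s.slide_id for s in train} & {s.slide_id for s in test}
    if shared_slides:
        raise LeakageError(f"slides in both train and test: {sorted(shared_slides)[:3]}")
    if patient_strict:
        shared_pids = {s.patient_id for s in train} & {s.patient_id for s in test}
        if shared_pids:
            raise LeakageError(
                f"patients in both train and test cohorts: {sorted(shared_pids)[:3]}"
            )


def predict_patients(
    trained: TrainedModel,
    samples: list[SlideSample],
    normalizer: ReinhardFit | None = None,
    seed: int = 0,
    softmax_single: bool = False,
) -> list[PatientPrediction]:
    """Slide predictions aggregated to one prediction per entity."""
    import zlib as _zlib

    by_entity: dict[Entity, list[np.ndarray]] = {}
    for s in samples:
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, _zlib.crc32(s.slide_id.encode())])
        )
        probs = _slide_probs(trained.model, s.store, trained.config, rng, normalizer)
        by_entity.setdefault((s.patient_id, s.class_label), []).append(probs)
    return [
        PatientPrediction(
            patient_id=pid,
            class_label=cls,
            final_probs=aggregate_patient_probability(plist, softmax_single=softmax_single),
            n_slides_used=len(plist),
        )
        for (pid, cls), plist in sorted(by_entity.items())
    ]


def _summarize_folds(fold_reports: list[MetricsReport]) -> MetricsReport:
    def stats(values):
        arr = np.array([v for v in values if v is not None], dtype=float)
        return (float(arr.mean()), float(arr.std())) if len(arr) else (float("nan"), float("nan"))

    acc = stats([r.accuracy for r in fold_reports])
    f1 = stats([r.f1 for r in fold_reports])
    auc = stats([r.auc for r in fold_reports])
    confusion = sum(r.confusion for r in fold_reports)
    return MetricsReport(
        accuracy=acc[0],
        f1=f1[0],
        auc=auc[0],
        confusion=confusion,
        per_fold=fold_reports,
        mean_sd={"accuracy": acc, "f1": f1, "auc": auc},
    )


@dataclass
class ProtocolResult:
    report: MetricsReport
    models: list[TrainedModel] = field(default_factory=list)


def _train_on_entities(
    cohort: CohortData,
    entities: list[Entity],
    config: ModelConfig,
    normalizer: ReinhardFit | None,
    seed: int,
) -> TrainedModel:
    train_ents, val_ents = split_train_val(entities, seed=seed)
    train_s = cohort.samples(set(train_ents))
    val_s = cohort.samples(set(val_ents))
    cfg = ModelConfig.from_dict({**config.to_dict(), "seed": seed & 0x7FFFFFFF})
    return train_model(train_s, val_s, cfg, normalizer=normalizer)


def run_protocol(
    cohorts: dict[str, CohortData],
    config: ModelConfig,
    mode: str,
    k: int = 5,
    seed: int = 0,
    normalizer: ReinhardFit | None = None,
    group_by: str | None = None,
    permute_labels: bool = False,
) -> ProtocolResult:
    """The study's three evaluation protocols on arbitrary cohorts.

    ``cv``: patient-wise stratified k-fold CV on cohorts['train'] (each
    fold's training part is further split 80-20 into train/validation);
    ``train_full_test_other``: fit on 80% of cohorts['train'] (20%
    validation), evaluate on cohorts['test']; ``train_all_test_holdout``:
    pool every cohort except 'test' for training, evaluate on
    cohorts['test'].  Metrics are always patient-level.  ``permute_labels``
    shuffles entity labels before training (negative control); test labels
    stay truthful.
    """
    if mode not in {"cv", "train_full_test_other", "train_all_test_holdout"}:
        raise ParameterError(f"unknown mode {mode!r}")

    if mode == "cv":
        cohort = cohorts["train"]
        manifest = cohort.manifest
        if permute_labels:
            manifest = _permute_entity_labels(manifest, seed)
            cohort = CohortData(cohort.name, manifest, cohort.stores)
        plan = make_patient_folds(manifest, k=k, seed=seed, group_by=group_by)
        fold_reports = []
        models = []
        for fold in range(plan.k):
            test_ents = plan.fold_entities(fold)
            train_ents = plan.complement_entities(fold)
            trained = _train_on_entities(
                cohort, train_ents, config, normalizer, seed=(seed * 97 + fold) & 0x7FFFFFFF
            )
            test_s = cohort.samples(set(test_ents))
            check_leakage(cohort.samples(set(train_ents)), test_s)
            preds = predict_patients(trained, test_s, normalizer, seed=seed)
            fold_reports.append(compute_metrics(preds))
            models.append(trained)
        return ProtocolResult(report=_summarize_folds(fold_reports), models=models)

    if mode == "train_full_test_other":
        train_cohort = cohorts["train"]
        test_cohort = cohorts["test"]
    else:
        train_cohort = merge_cohorts(
            "pooled", [c for name, c in sorted(cohorts.items()) if name != "test"]
        )
        test_cohort = cohorts["test"]

    train_manifest = train_cohort.manifest
    if permute_labels:
        train_manifest = _permute_entity_labels(train_manifest, seed)
        train_cohort = CohortData(train_cohort.name, train_manifest, train_cohort.stores)
    entities = _entities_of(train_manifest)
    trained = _train_on_entities(train_cohort, entities, config, normalizer, seed=seed)
    test_s = test_cohort.samples()
    check_leakage(train_cohort.samples(), test_s, patient_strict=True)
    preds = predict_patients(trained, test_s, normalizer, seed=seed)
    return ProtocolResult(report=compute_metrics(preds), models=[trained])


def _permute_entity_labels(manifest: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Shuffle class labels across entities (slides of one entity move together)."""
    entities = _entities_of(manifest)
    rng = np.random.default_rng(seed + 13)
    labels = [c for _, c in entities]
    perm = rng.permutation(len(labels))
    new_label = {entities[i]: labels[perm[pos]] for pos, i in enumerate(range(len(entities)))}
    out = manifest.copy()
    out["class_label"] = [
        new_label[(r.patient_id, r.class_label)] for r in manifest.itertuples(index=False)
    ]
    return out
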