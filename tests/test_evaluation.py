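"""Patient-wise evaluation: folds, aggregation rule, metrics, leakage guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histomil import (
    PatientPrediction,
    aggregate_patient_probability,
    compute_metrics,
    make_patient_folds,
)
from histomil.errors import ConfigurationError, LeakageError, ManifestError, ParameterError
from histomil.evaluation import check_leakage, split_train_val, _permute_entity_labels
from histomil.mil.model import SlideSample
from histomil.tiling import TileStore


def _manifest(n_control, n_tumor, dataset="D1", dual=0, group_cycle=None):
    rows = []
    idx = 0
    for _ in range(dual):
        pid = f"{dataset}-P{idx:03d}"; idx += 1
        for cls in ("control", "tumor"):
            rows.append((f"{pid}_{cls}", pid, dataset, cls))
    for cls, n in (("control", n_control - dual), ("tumor", n_tumor - dual)):
        for _ in range(n):
            pid = f"{dataset}-P{idx:03d}"; idx += 1
            rows.append((f"{pid}_{cls}", pid, dataset, cls))
    df = pd.DataFrame(rows, columns=["slide_id", "patient_id", "dataset_id", "class_label"])
    if group_cycle:
        pids = sorted(df["patient_id"].unique())
        gmap = {p: group_cycle[i % len(group_cycle)] for i, p in enumerate(pids)}
        df["group_label"] = df["patient_id"].map(gmap)
    else:
        df["group_label"] = ""
    df["path"] = ""
    return df


class TestFolds:
    def test_perfect_stratification(self):
        plan = make_patient_folds(_manifest(20, 20), k=10, seed=1)
        for fold in range(10):
            ents = plan.fold_entities(fold)
            by_class = {"control": 0, "tumor": 0}
            for _, cls in ents:
                by_class[cls] += 1
            assert by_class == {"control": 2, "tumor": 2}

    def test_stratification_within_one_when_uneven(self):
        plan = make_patient_folds(_manifest(13, 17), k=5, seed=3)
        for cls, total in (("control", 13), ("tumor", 17)):
            counts = [
                sum(1 for _, c in plan.fold_entities(f) if c == cls) for f in range(5)
            ]
            assert sum(counts) == total
            assert max(counts) - min(counts) <= 1

    def test_dual_class_patient_is_two_entities(self):
        manifest = _manifest(5, 5, dual=2)
        plan = make_patient_folds(manifest, k=5, seed=0)
        dual_pids = [p for p in manifest["patient_id"].unique()
                     if manifest[manifest["patient_id"] == p]["class_label"].nunique() == 2]
        for pid in dual_pids:
            assert (pid, "control") in plan.assignments
            assert (pid, "tumor") in plan.assignments
        # every slide of one entity shares that entity's fold by construction
        assert len(plan.assignments) == 10

    def test_grouped_mode_one_pure_fold_per_group(self):
        groups = [f"G{i}" for i in range(12)]
        manifest = _manifest(12, 12, group_cycle=groups)
        plan = make_patient_folds(manifest, k=5, seed=0, group_by="group_label")
        assert plan.k == 12
        for fold, g in enumerate(plan.group_names):
            for pid, _ in plan.fold_entities(fold):
                assert manifest[manifest["patient_id"] == pid]["group_label"].iloc[0] == g

    def test_patient_in_two_datasets_rejected(self):
        df = _manifest(3, 3, dual=1)  # the dual patient owns two rows
        df.loc[df.index[0], "dataset_id"] = "D2"
        with pytest.raises(ManifestError):
            make_patient_folds(df, k=3)

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(ConfigurationError):
            make_patient_folds(_manifest(4, 10), k=5)

    def test_split_train_val_is_stratified_and_disjoint(self):
        ents = [(f"p{i}", "control") for i in range(10)] + [(f"q{i}", "tumor") for i in range(10)]
        train, val = split_train_val(ents, val_fraction=0.2, seed=4)
        assert len(val) == 4 and len(train) == 16
        assert not (set(train) & set(val))
        assert sum(1 for _, c in val if c == "tumor") == 2


class TestAggregation:
    def test_two_slide_example(self):
        # mean of (0.8,0.2) and (0.6,0.4) is (0.7,0.3); softmax of that is
        # (e^0.7, e^0.3) normalized.
        out = aggregate_patient_probability([np.array([0.8, 0.2]), np.array([0.6, 0.4])])
        expected = np.exp([0.7, 0.3]) / np.exp([0.7, 0.3]).sum()
        assert np.allclose(out, expected, atol=1e-12)
        assert out[0] == pytest.approx(0.5986876601124521, abs=1e-9)

    def test_single_slide_used_directly(self):
        out = aggregate_patient_probability([np.array([0.9, 0.1])])
        assert np.array_equal(out, [0.9, 0.1])

    def test_single_slide_softmax_variant(self):
        out = aggregate_patient_probability([np.array([0.9, 0.1])], softmax_single=True)
        expected = np.exp([0.9, 0.1]) / np.exp([0.9, 0.1]).sum()
        assert np.allclose(out, expected)

    def test_symmetric_fixed_point(self):
        out = aggregate_patient_probability([np.array([0.5, 0.5])] * 2)
        assert np.allclose(out, [0.5, 0.5])

    def test_matches_independent_oracle_on_random_lists(self, rng):
        # independent implementation: plain mean then softmax, written
        # differently from the library path
        def oracle(plist):
            m = sum(plist) / len(plist)
            if len(plist) == 1:
                return plist[0]
            z = [float(np.exp(v)) for v in m]
            return np.array([v / sum(z) for v in z])

        for _ in range(1000):
            n = int(rng.integers(1, 6))
            raw = rng.random((n, 2))
            plist = [r / r.sum() for r in raw]
            assert np.allclose(
                aggregate_patient_probability(plist), oracle(plist), atol=1e-9
            )

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            aggregate_patient_probability([])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_output_always_on_simplex(self, ps):
        plist = [np.array([p, 1.0 - p]) for p in ps]
        out = aggregate_patient_probability(plist)
        assert out.min() >= 0.0
        assert out.sum() == pytest.approx(1.0, abs=1e-9)


def _pred(pid, cls, p_tumor):
    return PatientPrediction(pid, cls, np.array([1.0 - p_tumor, p_tumor]), 1)


class TestMetrics:
    def test_perfect_predictions(self):
        preds = [_pred(f"a{i}", "tumor", 0.9) for i in range(3)] + [
            _pred(f"b{i}", "control", 0.1) for i in range(3)
        ]
        rep = compute_metrics(preds)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0 and rep.auc == 1.0

    def test_confusion_example(self):
        # rows = truth (control, tumor); [[3,1],[2,4]] -> accuracy 0.7
        preds = (
            [_pred(f"c{i}", "control", 0.2) for i in range(3)]
            + [_pred("c3", "control", 0.8)]
            + [_pred(f"t{i}", "tumor", 0.3) for i in range(2)]
            + [_pred(f"t{i+2}", "tumor", 0.7) for i in range(4)]
        )
        rep = compute_metrics(preds)
        assert np.array_equal(rep.confusion, [[3, 1], [2, 4]])
        assert rep.accuracy == pytest.approx(0.7)

    def test_auc_equals_pairwise_ranking_oracle(self, rng):
        preds = [
            _pred(f"p{i}", "tumor" if rng.random() < 0.5 else "control", float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9])))
            for i in range(40)
        ]
        if len({p.class_label for p in preds}) < 2:
            preds[0] = _pred("p0", "tumor", 0.5)
        rep = compute_metrics(preds)
        tum = [p.final_probs[1] for p in preds if p.class_label == "tumor"]
        ctl = [p.final_probs[1] for p in preds if p.class_label == "control"]
        wins = sum((t > c) + 0.5 * (t == c) for t in tum for c in ctl)
        assert rep.auc == pytest.approx(wins / (len(tum) * len(ctl)), abs=1e-12)

    def test_tie_breaks_toward_tumor(self):
        rep = compute_metrics([_pred("p", "tumor", 0.5)])
        assert rep.confusion[1, 1] == 1

    def test_single_class_auc_undefined(self):
        rep = compute_metrics([_pred("p1", "tumor", 0.8), _pred("p2", "tumor", 0.6)])
        assert rep.auc is None
        assert rep.accuracy == 1.0

    def test_confusion_sums_to_entities_on_random_input(self, rng):
        preds = [
            _pred(f"p{i}", rng.choice(["control", "tumor"]), float(rng.random()))
            for i in range(57)
        ]
        rep = compute_metrics(preds)
        assert rep.confusion.sum() == 57
        assert 0.0 <= rep.accuracy <= 1.0 and 0.0 <= rep.f1 <= 1.0


class TestLeakage:
    def _samples(self, pids_classes):
        return [
            SlideSample(f"{p}_{c}_{i}", p, c, TileStore(slide_id=f"{p}_{c}_{i}"))
            for i, (p, c) in enumerate(pids_classes)
        ]

    def test_shared_entity_raises(self):
        train = self._samples([("p1", "tumor"), ("p2", "control")])
        test = self._samples([("p1", "tumor")])
        with pytest.raises(LeakageError):
            check_leakage(train, test)

    def test_strict_mode_rejects_cross_class_patient_overlap(self):
        train = self._samples([("p1", "tumor")])
        test = self._samples([("p1", "control")])
        with pytest.raises(LeakageError):
            check_leakage(train, test, patient_strict=True)

    def test_cross_class_patient_is_allowed(self):
        # independent-entity rule: same patient, different class is allowed
        train = self._samples([("p1", "tumor")])
        test = self._samples([("p1", "control")])
        check_leakage(train, test)

    def test_disjoint_ok(self):
        check_leakage(
            self._samples([("p1", "tumor")]), self._samples([("p2", "tumor")])
        )


class TestLabelPermutation:
    def test_moves_entity_labels_coherently(self):
        manifest = _manifest(6, 6)
        out = _permute_entity_labels(manifest, seed=5)
        # label counts preserved, slides of one patient keep a single label
        assert sorted(out["class_label"]) == sorted(manifest["class_label"])
        assert (out.groupby("patient_id")["class_label"].nunique() == 1).all()
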