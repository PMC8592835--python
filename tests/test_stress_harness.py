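import numpy as np
import pandas as pd
import pytest

from histostress import (
    CLASS_ORDER,
    ConfusionSummary,
    PredictionRecord,
    breakdown_by_class,
    classify,
    compute_metrics,
    filter_baseline,
    misclassification_overlap,
    report,
    run_stress_test,
)
from histostress.errors import ClassifierContractError


class AlwaysTumor:
    def predict_proba(self, patches):
        return np.tile([0.0, 0.0, 1.0], (len(patches), 1))


class BadProbabilities:
    def predict_proba(self, patches):
        return np.tile([0.5, 0.5, 0.5], (len(patches), 1))


def random_records(rng, n):
    classes = [rng.choice(CLASS_ORDER) for _ in range(2 * n)]
    return [
        PredictionRecord(f"p{i}", classes[2 * i], classes[2 * i + 1], (1.0, 0.0, 0.0))
        for i in range(n)
    ]


class TestClassify:
    def test_empty_input_gives_empty_output(self, toy_classifier):
        assert classify(toy_classifier, []) == []

    def test_toy_classifier_is_perfect_on_clean_patches(self, toy_classifier, small_dataset):
        records = classify(
            toy_classifier,
            [lp.patch for lp in small_dataset],
            [lp.true_class for lp in small_dataset],
        )
        assert all(r.predicted_class == r.true_class for r in records)

    def test_probabilities_sum_to_one_and_order_preserved(self, toy_classifier, small_dataset):
        patches = [lp.patch for lp in small_dataset[:10]]
        records = classify(toy_classifier, patches)
        assert [r.patch_id for r in records] == [p.id for p in patches]
        for r in records:
            assert abs(sum(r.probabilities) - 1.0) < 1e-6
            assert r.predicted_class == CLASS_ORDER[int(np.argmax(r.probabilities))]

    def test_contract_violation_raises(self, small_dataset):
        with pytest.raises(ClassifierContractError):
            classify(BadProbabilities(), [lp.patch for lp in small_dataset[:3]])


class TestComputeMetrics:
    def test_all_correct_gives_f1_one(self):
        records = [PredictionRecord("a", "TUMOR", "TUMOR", (0, 0, 1)),
                   PredictionRecord("b", "GLAND", "GLAND", (1, 0, 0))]
        assert compute_metrics(records).f1 == 1.0

    def test_closed_form_counts(self):
        s = ConfusionSummary(tp=3, fp=1, fn=1, tn=5)
        assert s.precision == 0.75
        assert s.recall == 0.75
        assert s.f1 == 0.75

    def test_zero_denominator_rule(self):
        s = ConfusionSummary(tp=0, fp=2, fn=0, tn=3)
        assert s.precision == 0.0 and s.f1 == 0.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([])

    def test_matches_brute_force_oracle_on_random_records(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            records = random_records(rng, int(rng.integers(1, 30)))
            summary = compute_metrics(records)
            tp = sum(r.true_class == "TUMOR" and r.predicted_class == "TUMOR" for r in records)
            fp = sum(r.true_class != "TUMOR" and r.predicted_class == "TUMOR" for r in records)
            fn = sum(r.true_class == "TUMOR" and r.predicted_class != "TUMOR" for r in records)
            tn = len(records) - tp - fp - fn
            assert (summary.tp, summary.fp, summary.fn, summary.tn) == (tp, fp, fn, tn)
            assert summary.n == len(records)


class TestFilterBaseline:
    def test_perfect_classifier_keeps_everything(self, toy_classifier, small_dataset):
        kept = filter_baseline(small_dataset, toy_classifier)
        assert len(kept) == len(small_dataset)

    def test_always_tumor_keeps_only_tumor(self, small_dataset):
        kept = filter_baseline(small_dataset, AlwaysTumor())
        assert kept and all(lp.true_class == "TUMOR" for lp in kept)

    def test_retained_set_baseline_f1_is_one(self, small_dataset):
        clf = AlwaysTumor()
        kept = filter_baseline(small_dataset, clf)
        records = classify(clf, [lp.patch for lp in kept], [lp.true_class for lp in kept])
        assert compute_metrics(records).f1 == 1.0


class TestBreakdownByClass:
    def test_all_correct_gives_zeros(self):
        records = [PredictionRecord("a", "TUMOR", "TUMOR", (0, 0, 1))]
        assert breakdown_by_class(records) == {"fp_gland": 0, "fp_nongland": 0, "fn_tumor": 0}

    def test_single_gland_fp(self):
        records = [PredictionRecord("a", "GLAND", "TUMOR", (0, 0, 1))]
        out = breakdown_by_class(records)
        assert out == {"fp_gland": 1, "fp_nongland": 0, "fn_tumor": 0}

    def test_reconciles_with_confusion_summary(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            records = random_records(rng, int(rng.integers(1, 40)))
            out = breakdown_by_class(records)
            summary = compute_metrics(records)
            assert out["fp_gland"] + out["fp_nongland"] == summary.fp
            assert out["fn_tumor"] == summary.fn


class TestMisclassificationOverlap:
    def test_disjoint_sets(self):
        out = misclassification_overlap({"A": {"a"}, "B": {"b"}})
        assert out[("A",)] == 1 and out[("B",)] == 1 and out[("A", "B")] == 0

    def test_identical_sets(self):
        out = misclassification_overlap({"A": {"x", "y"}, "B": {"x", "y"}})
        assert out[("A", "B")] == 2 and out[("A",)] == 0 and out[("B",)] == 0

    def test_arity_bounds(self):
        with pytest.raises(ValueError):
            misclassification_overlap({"A": set()})

    def test_matches_exhaustive_membership_oracle(self):
        rng = np.random.default_rng(99)
        universe = [f"id{i}" for i in range(300)]
        for n_sets in (2, 3, 4, 5):
            sets = {
                chr(65 + i): set(rng.choice(universe, size=rng.integers(0, 150), replace=False))
                for i in range(n_sets)
            }
            regions = misclassification_overlap(sets)
            union = set().union(*sets.values())
            assert sum(regions.values()) == len(union)
            for uid in union:
                member = tuple(sorted(name for name, s in sets.items() if uid in s))
                assert regions[member] >= 1
            # per-region recount by brute force
            for key, count in regions.items():
                brute = sum(
                    1 for uid in union
                    if tuple(sorted(n for n, s in sets.items() if uid in s)) == key
                )
                assert brute == count


class TestRunStressTest:
    def test_identity_artifact_stays_at_f1_one(self, toy_classifier, small_dataset):
        filtered = filter_baseline(small_dataset, toy_classifier)
        curve = run_stress_test(filtered, toy_classifier, "identity", [1, 1, 1], seed=5)
        assert curve.f1_values() == [1.0, 1.0, 1.0, 1.0]
        assert curve.levels[0] == "baseline"
        assert all(not s for s in curve.misclassified)

    def test_same_seed_reproduces_curve(self, toy_classifier, small_dataset, template_bank):
        filtered = filter_baseline(small_dataset, toy_classifier)[:20]
        kwargs = dict(templates=template_bank, seed=11)
        a = run_stress_test(filtered, toy_classifier, "squamous", [1, 2], **kwargs)
        b = run_stress_test(filtered, toy_classifier, "squamous", [1, 2], **kwargs)
        assert a.f1_values() == b.f1_values()
        assert a.misclassified == b.misclassified

    def test_unknown_artifact_rejected(self, toy_classifier, small_dataset):
        with pytest.raises(ValueError):
            run_stress_test(small_dataset, toy_classifier, "vignetting", [1], seed=0)

    def test_empty_ladder_rejected(self, toy_classifier, small_dataset):
        with pytest.raises(ValueError):
            run_stress_test(small_dataset, toy_classifier, "focus", [], seed=0)

    def test_staining_sweep_must_not_normalize(self, toy_classifier, small_dataset):
        with pytest.raises(ValueError):
            run_stress_test(
                small_dataset, toy_classifier, "staining", ["S01"], normalize_first=True
            )


class TestReport:
    def test_csv_and_plot_written(self, tmp_path, toy_classifier, small_dataset):
        filtered = filter_baseline(small_dataset, toy_classifier)[:12]
        curve = run_stress_test(filtered, toy_classifier, "focus", [2, 6, 10], seed=1)
        paths = report([curve], tmp_path)
        frame = pd.read_csv(tmp_path / "focus.csv")
        assert len(frame) == 4  # baseline + 3 levels
        assert np.allclose(frame["f1"].to_numpy(), curve.f1_values())
        png = tmp_path / "focus.png"
        assert png.exists() and png.stat().st_size > 0
        assert set(paths) == {tmp_path / "focus.csv", png}

    def test_empty_report_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            report([], tmp_path)
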