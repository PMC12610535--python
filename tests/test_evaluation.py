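"""Metric suite, cluster bootstrap, kappa, model comparison, CV drivers."""

import itertools

import numpy as np
import pandas as pd
import pytest

from herdstress.evaluation import (
    chronological_split,
    cluster_bootstrap_ci,
    compare_models,
    compute_metrics,
    forward_chaining_folds,
    loco_forward_chaining,
    power_simulation,
    run_ablation,
    subset_cows,
    weighted_kappa,
)


def _year_frame(n_cows: int, year: int = 2023) -> pd.DataFrame:
    dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    return pd.DataFrame(
        [(f"cow_{i}", d.date()) for i in range(n_cows) for d in dates],
        columns=["cow_id", "date"],
    )


class TestChronologicalSplit:
    def test_ten_cows_full_year(self):
        split = chronological_split(_year_frame(10))
        assert split["n_train_cow_days"] == 2430
        assert split["n_test_cow_days"] == 1220

    def test_one_cow(self):
        split = chronological_split(_year_frame(1))
        assert (split["n_train_cow_days"], split["n_test_cow_days"]) == (243, 122)

    def test_leap_year_documented_divergence(self):
        split = chronological_split(_year_frame(1, year=2024))
        assert (split["n_train_cow_days"], split["n_test_cow_days"]) == (244, 122)

    def test_boundary_is_september_first(self):
        frame = pd.DataFrame(
            {"cow_id": "c1", "date": [pd.Timestamp("2023-08-31"), pd.Timestamp("2023-09-01")]}
        )
        split = chronological_split(frame)
        assert split["train_mask"].tolist() == [True, False]
        assert split["test_mask"].tolist() == [False, True]

    def test_overlapping_months_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            chronological_split(_year_frame(1), train_months=(1, 2), test_months=(2, 3))


def _oracle_metrics(cm: np.ndarray) -> dict:
    """Accuracy and macro precision/recall/F1 computed cell by cell."""
    n = cm.sum()
    acc = sum(cm[i, i] for i in range(3)) / n
    precs, recs, f1s = [], [], []
    for c in range(3):
        tp = cm[c, c]
        fp = sum(cm[r, c] for r in range(3)) - tp
        fn = sum(cm[c, r] for r in range(3)) - tp
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return {
        "accuracy": acc,
        "precision_macro": float(np.mean(precs)),
        "recall_macro": float(np.mean(recs)),
        "f1_macro": float(np.mean(f1s)),
    }


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y]
        rep = compute_metrics(y, y, probs)
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0
        assert rep.roc_auc_ovr_macro == 1.0

    def test_confusion_matrix_accounting(self):
        y_true = np.array([0, 0, 1, 2])
        y_pred = np.array([0, 1, 1, 1])
        rep = compute_metrics(y_true, y_pred)
        assert rep.confusion.sum() == 4
        assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / 4)

    def test_exhaustive_small_confusion_matrices_match_oracle(self):
        """Every 3x3 confusion matrix with n <= 6 agrees with the
        per-cell hand oracle."""
        checked = 0
        for n in range(1, 7):
            for cells in itertools.combinations_with_replacement(range(9), n):
                cm = np.zeros((3, 3), dtype=int)
                for flat in cells:
                    cm[flat // 3, flat % 3] += 1
                y_true = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], cm.ravel())
                y_pred = np.repeat([0, 1, 2, 0, 1, 2, 0, 1, 2], cm.ravel())
                rep = compute_metrics(y_true, y_pred)
                oracle = _oracle_metrics(cm)
                for key, val in oracle.items():
                    assert getattr(rep, key) == pytest.approx(val, abs=1e-12), cm
                checked += 1
        assert checked == sum(
            1 for n in range(1, 7)
            for _ in itertools.combinations_with_replacement(range(9), n)
        )

    def test_null_probabilities_have_auc_half(self):
        rng = np.random.default_rng(0)
        n = 10_000
        y = rng.integers(0, 3, n)
        probs = rng.dirichlet(np.ones(3), size=n)
        rep = compute_metrics(y, probs.argmax(axis=1), probs)
        assert rep.roc_auc_ovr_macro == pytest.approx(0.5, abs=0.02)

    def test_absent_class_warned_and_excluded(self):
        y = np.array([0, 1, 0, 1])
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(UserWarning, match="absent"):
            rep = compute_metrics(y, y, probs)
        assert set(rep.pr_auc_per_class) == {0, 1}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_metrics(np.zeros(3, dtype=int), np.zeros(4, dtype=int))


class TestClusterBootstrap:
    def test_constant_metric_gives_zero_width(self):
        frames = {f"c{i}": (np.array([1, 1, 0, 1]), np.array([1, 1, 0, 1])) for i in range(4)}
        ci = cluster_bootstrap_ci(
            lambda t, p: float(np.mean(t == p)), frames, n_boot=200, seed=0
        )
        assert ci["lo"] == ci["hi"] == ci["point"] == 1.0

    def test_three_cow_interval_matches_exhaustive_enumeration(self):
        """With 3 cows holding constant per-cow values {0, 1, 2}, the
        27 equally likely resamples give a 10th/90th percentile of
        1/3 and 5/3 for the pooled mean."""
        frames = {"a": (np.array([0.0]),), "b": (np.array([1.0]),), "c": (np.array([2.0]),)}
        means = [
            (i + j + k) / 3.0
            for i, j, k in itertools.product([0, 1, 2], repeat=3)
        ]
        assert np.quantile(means, 0.10) == pytest.approx(1 / 3)
        assert np.quantile(means, 0.90) == pytest.approx(5 / 3)
        ci = cluster_bootstrap_ci(
            lambda x: float(np.mean(x)), frames, n_boot=4000, level=0.80, seed=1
        )
        assert ci["lo"] == pytest.approx(1 / 3, abs=1e-12)
        assert ci["hi"] == pytest.approx(5 / 3, abs=1e-12)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(2)
        frames = {f"c{i}": (rng.normal(size=30),) for i in range(6)}
        ci = cluster_bootstrap_ci(lambda x: float(np.mean(x)), frames, n_boot=500, seed=3)
        assert ci["lo"] <= ci["point"] <= ci["hi"]

    def test_single_cow_rejected(self):
        with pytest.raises(ValueError, match="2 cows"):
            cluster_bootstrap_ci(lambda x: 0.0, {"a": (np.zeros(3),)})

    def test_coverage_calibration_for_gaussian_per_cow_metric(self):
        """95% cluster-bootstrap CIs cover a known mean in roughly 95%
        of simulated herds."""
        rng = np.random.default_rng(4)
        n_herds, covered = 300, 0
        for _ in range(n_herds):
            frames = {f"c{i}": (rng.normal(0.8, 0.05, size=10),) for i in range(60)}
            ci = cluster_bootstrap_ci(
                lambda x: float(np.mean(x)), frames, n_boot=600,
                seed=int(rng.integers(2**31)),
            )
            covered += ci["lo"] <= 0.8 <= ci["hi"]
        # percentile bootstrap under-covers slightly at finite cluster counts
        assert covered / n_herds == pytest.approx(0.95, abs=0.03)


class TestWeightedKappa:
    def test_identical_vectors(self):
        y = np.array([0, 1, 2, 1, 0, 2])
        for w in (None, "linear", "quadratic"):
            assert weighted_kappa(y, y, w) == pytest.approx(1.0)

    def test_independent_labels_give_zero(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 100_000)
        b = rng.integers(0, 3, 100_000)
        assert weighted_kappa(a, b, "linear") == pytest.approx(0.0, abs=0.01)
        assert weighted_kappa(a, b, "quadratic") == pytest.approx(0.0, abs=0.015)

    def test_hand_built_contingency_table(self):
        """Linear-weighted kappa recomputed from the weight matrix."""
        # observed table rows=rater A, cols=rater B
        table = np.array([[10, 2, 0], [3, 8, 1], [0, 2, 4]])
        a = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], table.ravel())
        b = np.repeat([0, 1, 2, 0, 1, 2, 0, 1, 2], table.ravel())
        n = table.sum()
        w = np.abs(np.subtract.outer(np.arange(3), np.arange(3))) / 2.0
        po = (w * table / n).sum()
        pe = (w * np.outer(table.sum(1) / n, table.sum(0) / n)).sum()
        expected = 1.0 - po / pe
        assert weighted_kappa(a, b, "linear") == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa(np.array([]), np.array([]))


class TestCompareModels:
    def test_identical_models_give_zero_delta_and_p_one(self):
        cows = {f"c{i}": 0.8 for i in range(8)}
        out = compare_models({"m": cows, "b": dict(cows)}, "m", ["b"])
        assert out.loc[0, "delta_mean"] == 0.0
        assert out.loc[0, "p_holm"] == pytest.approx(1.0)

    def test_single_comparison_adjustment_is_identity(self):
        rng = np.random.default_rng(6)
        a = {f"c{i}": v for i, v in enumerate(rng.normal(0.8, 0.02, 10))}
        b = {k: v - 0.05 for k, v in a.items()}
        out = compare_models({"m": a, "b": b}, "m", ["b"], seed=0)
        assert out.loc[0, "p_holm"] == pytest.approx(out.loc[0, "p_raw"])

    def test_holm_step_down_matches_hand_execution(self):
        rng = np.random.default_rng(7)
        prop = {f"c{i}": v for i, v in enumerate(rng.normal(0.85, 0.01, 10))}
        baselines = {}
        for j, shift in enumerate((0.10, 0.05, 0.002, 0.0005)):
            baselines[f"b{j}"] = {k: v - shift + rng.normal(0, 0.01) for k, v in prop.items()}
        metrics = {"m": prop, **baselines}
        out = compare_models(metrics, "m", list(baselines), seed=1)
        raw = out["p_raw"].to_numpy()
        order = np.argsort(raw)
        adjusted = np.empty(4)
        running = 0.0
        for rank, idx in enumerate(order):  # hand-executed step-down
            running = max(running, (4 - rank) * raw[idx])
            adjusted[idx] = min(1.0, running)
        assert np.allclose(out["p_holm"].to_numpy(), adjusted)

    def test_unpaired_cows_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            compare_models({"m": {"a": 1.0}, "b": {"z": 1.0}}, "m", ["b"])

    def test_positive_effect_has_positive_cohens_d(self):
        rng = np.random.default_rng(8)
        a = {f"c{i}": v for i, v in enumerate(rng.normal(0.85, 0.02, 10))}
        b = {k: v - 0.08 for k, v in a.items()}
        out = compare_models({"m": a, "b": b}, "m", ["b"], seed=2)
        assert out.loc[0, "cohens_d"] > 1.0


class TestCVDrivers:
    def test_forward_chaining_blocks_are_ordered(self):
        times = np.arange(100)
        folds = list(forward_chaining_folds(times, 3))
        assert len(folds) == 3
        prev_end = -1
        for train_t, val_t in folds:
            assert train_t.max() < val_t.min()
            assert train_t.max() > prev_end
            prev_end = train_t.max()

    def test_loco_structure_and_partition(self, herd60):
        small = subset_cows(herd60, ["cow_01", "cow_02", "cow_03"])

        def fit_predict(train_ds, test_ds, inner):
            assert len(train_ds.cow_ids) == 2 and len(test_ds.cow_ids) == 1
            assert len(inner) == 3
            return pd.DataFrame({"cow_id": test_ds.cow_ids})

        results = loco_forward_chaining(small, fit_predict)
        held = [r["held_out"] for r in results]
        assert sorted(held) == ["cow_01", "cow_02", "cow_03"]
        covered = [r["predictions"]["cow_id"].iloc[0] for r in results]
        assert sorted(covered) == sorted(held)

    def test_loco_training_artifacts_isolated_from_held_out_cow(self, herd60):
        """Poisoning the held-out cow's budgets must not change anything
        fitted on the training cows."""
        from herdstress.activity import calibrate_weights

        small = subset_cows(herd60, ["cow_01", "cow_02", "cow_03"])
        poisoned = subset_cows(small, small.cow_ids)
        sel = poisoned.behavior["cow_id"] == "cow_03"
        poisoned.behavior.loc[sel, "eat_min"] = 60.0

        captured = {}

        def fit_predict(train_ds, test_ds, inner):
            w = calibrate_weights(train_ds.behavior, mode="contrast")
            captured.setdefault(test_ds.cow_ids[0], []).append(w.as_array)
            return pd.DataFrame({"cow_id": test_ds.cow_ids})

        loco_forward_chaining(small, fit_predict)
        loco_forward_chaining(poisoned, fit_predict)
        # the fold holding out cow_03 trains on cows 1-2 only: identical
        assert np.allclose(captured["cow_03"][0], captured["cow_03"][1])

    def test_loco_needs_two_cows(self, herd60):
        one = subset_cows(herd60, ["cow_01"])
        with pytest.raises(ValueError, match="2 cows"):
            loco_forward_chaining(one, lambda *a: None)


class TestPower:
    def test_size_equals_level_under_null(self):
        out = power_simulation(n_sims=800, delta_f1=0.0, seed=0)
        assert out["power"] == pytest.approx(0.05, abs=0.025)

    def test_large_effect_gives_full_power(self):
        out = power_simulation(n_sims=200, delta_f1=0.30, per_cow_sd=0.02, seed=1)
        assert out["power"] > 0.99

    def test_doubling_sims_moves_within_binomial_error(self):
        a = power_simulation(n_sims=400, delta_f1=0.05, seed=2)
        b = power_simulation(n_sims=800, delta_f1=0.05, seed=2)
        se = np.sqrt(a["power"] * (1 - a["power"]) / 400 + b["power"] * (1 - b["power"]) / 800)
        assert abs(a["power"] - b["power"]) < 4 * max(se, 0.01)

    def test_zero_sims_rejected(self):
        with pytest.raises(ValueError):
            power_simulation(n_sims=0)
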