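"""Evaluation harness.

Chronological train/test splitting, leave-one-cow-out (LOCO) +
forward-chaining cross-validation, the classification metric suite with
cow-level cluster-bootstrap confidence intervals, weighted kappa
agreement, Holm-Bonferroni pairwise model comparison and the
pre-specified ablation arms.

All inference respects the hierarchical structure of the data: hourly
records are repeated measures nested in cows, so uncertainty is always
resampled at the cow level, never at the record level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    average_precision_score,
    cohen_kappa_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
)
from statsmodels.stats.multitest import multipletests

from .synthetic import HerdDataset

__all__ = [
    "EvalReport",
    "chronological_split",
    "subset_cows",
    "forward_chaining_folds",
    "loco_forward_chaining",
    "compute_metrics",
    "cluster_bootstrap_ci",
    "weighted_kappa",
    "compare_models",
    "ABLATION_ARMS",
    "run_ablation",
    "power_simulation",
]

_CLASSES = np.array([0, 1, 2])

ABLATION_ARMS = (
    "full", "no_vet", "no_thi", "no_vet_no_thi",
    "no_harmonics", "no_coherence", "no_circadian_filter",
)


@dataclass
class EvalReport:
    accuracy: float
    precision_macro: float
    recall_macro: float
    f1_macro: float
    per_class: dict[int, dict[str, float]]
    confusion: np.ndarray
    roc_auc_ovr_macro: float | None = None
    pr_auc_per_class: dict[int, float] | None = None
    pr_auc_macro: float | None = None
    n: int = 0

    def to_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "precision_macro": self.precision_macro,
            "recall_macro": self.recall_macro,
            "f1_macro": self.f1_macro,
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "confusion": self.confusion.tolist(),
            "n": self.n,
        }
        if self.roc_auc_ovr_macro is not None:
            out["roc_auc_ovr_macro"] = self.roc_auc_ovr_macro
        if self.pr_auc_macro is not None:
            out["pr_auc_macro"] = self.pr_auc_macro
            out["pr_auc_per_class"] = {str(k): v for k, v in self.pr_auc_per_class.items()}
        return out


def chronological_split(
    dates: pd.DataFrame,
    train_months: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8),
    test_months: tuple[int, ...] = (9, 10, 11, 12),
) -> dict:
    """Split cow-day rows by calendar month (train Jan-Aug, test Sep-Dec).

    ``dates`` needs columns cow_id and date. The partition must be disjoint
    and exhaustive over the months present. Returns masks and cow-day
    counts; for 10 cows over a non-leap year the counts are 2430/1220.
    """
    if set(train_months) & set(test_months):
        raise ValueError("train and test months overlap")
    months = pd.to_datetime(dates["date"]).dt.month
    train_mask = months.isin(train_months).to_numpy()
    test_mask = months.isin(test_months).to_numpy()
    return {
        "train_mask": train_mask,
        "test_mask": test_mask,
        "n_train_cow_days": int(train_mask.sum()),
        "n_test_cow_days": int(test_mask.sum()),
    }


def subset_cows(dataset: HerdDataset, cows: list[str]) -> HerdDataset:
    keep = set(cows)

    def _f(frame: pd.DataFrame | None) -> pd.DataFrame | None:
        if frame is None:
            return None
        if "cow_id" not in frame.columns:
            return frame.copy()
        return frame[frame["cow_id"].isin(keep)].reset_index(drop=True)

    return HerdDataset(
        behavior=_f(dataset.behavior), weather=dataset.weather.copy(),
        vet=_f(dataset.vet), milk=_f(dataset.milk), truth=_f(dataset.truth),
        config=dataset.config,
    )


def forward_chaining_folds(times: np.ndarray, n_folds: int = 3):
    """Expanding-window chronological folds over sorted unique times.

    Yields (train_times, val_times) with the train block always strictly
    preceding its validation block.
    """
    uniq = np.sort(np.unique(times))
    edges = np.linspace(0, len(uniq), n_folds + 2).astype(int)
    for k in range(1, n_folds + 1):
        train_t = uniq[: edges[k]]
        val_t = uniq[edges[k] : edges[k + 1]]
        if len(train_t) and len(val_t):
            yield train_t, val_t


def loco_forward_chaining(
    dataset: HerdDataset,
    fit_predict,
    n_inner: int = 3,
) -> list[dict]:
    """Leave-one-cow-out outer loop with chronological inner folds.

    ``fit_predict(train_ds, test_ds, inner_folds)`` must fit every
    artifact (activity weights, scalers, thresholds, model) on the
    training herd only and return a prediction frame for the held-out
    cow. Returns one result dict per outer fold.
    """
    cows = dataset.cow_ids
    if len(cows) < 2:
        raise ValueError("LOCO needs at least 2 cows")
    results = []
    for held_out in cows:
        train_ds = subset_cows(dataset, [c for c in cows if c != held_out])
        test_ds = subset_cows(dataset, [held_out])
        times = pd.to_datetime(train_ds.behavior["timestamp"]).to_numpy()
        inner = list(forward_chaining_folds(times, n_inner))
        preds = fit_predict(train_ds, test_ds, inner)
        results.append({"held_out": held_out, "predictions": preds})
    return results


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    probabilities: np.ndarray | None = None,
) -> EvalReport:
    """Standard multi-class metric suite.

    Macro averages are unweighted over classes; ROC-AUC and PR-AUC are
    one-vs-rest per class then macro-averaged. Classes absent from the
    truth are excluded from the AUC macro averages with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch between truth and predictions")
    if len(y_true) == 0:
        raise ValueError("no predictions to score")
    cm = confusion_matrix(y_true, y_pred, labels=_CLASSES)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=_CLASSES, zero_division=0
    )
    present = np.unique(y_true)
    report = EvalReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        f1_macro=float(f1.mean()),
        per_class={
            int(c): {"precision": float(prec[c]), "recall": float(rec[c]), "f1": float(f1[c])}
            for c in _CLASSES
        },
        confusion=cm,
        n=len(y_true),
    )
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        missing = sorted(set(_CLASSES.tolist()) - set(present.tolist()))
        if missing:
            warnings.warn(
                f"classes {missing} absent from truth; excluded from macro AUC"
            )
        aucs, pr_aucs = {}, {}
        for c in present:
            if len(present) < 2:
                break
            yc = (y_true == c).astype(int)
            aucs[int(c)] = float(roc_auc_score(yc, probabilities[:, c]))
            pr_aucs[int(c)] = float(average_precision_score(yc, probabilities[:, c]))
        if aucs:
            report.roc_auc_ovr_macro = float(np.mean(list(aucs.values())))
            report.pr_auc_per_class = pr_aucs
            report.pr_auc_macro = float(np.mean(list(pr_aucs.values())))
    return report


def cluster_bootstrap_ci(
    metric_fn,
    frames: dict[str, tuple],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> dict:
    """Percentile bootstrap CI resampling whole cows.

    ``frames`` maps cow_id to the tuple of per-record arrays the metric
    needs (e.g. ``(y_true, y_pred)``); ``metric_fn(*pooled_arrays)``
    computes the statistic on the pooled resample. Returns the point
    estimate (all cows once) and the percentile interval.
    """
    cows = sorted(frames)
    if len(cows) < 2:
        raise ValueError("cluster bootstrap needs at least 2 cows (clusters)")
    n_parts = len(next(iter(frames.values())))

    def _pool(selected):
        return [
            np.concatenate([np.asarray(frames[c][j]) for c in selected])
            for j in range(n_parts)
        ]

    point = float(metric_fn(*_pool(cows)))
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        sel = rng.choice(cows, size=len(cows), replace=True)
        vals[b] = metric_fn(*_pool(sel))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [alpha, 1.0 - alpha])
    return {"point": point, "lo": float(lo), "hi": float(hi), "level": level, "n_boot": n_boot}


def weighted_kappa(
    labels_a: np.ndarray, labels_b: np.ndarray, weighting: str | None = "linear"
) -> float:
    """Cohen's kappa with linear/quadratic ordinal weighting (or none)."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) == 0:
        raise ValueError("empty label vectors")
    if len(labels_a) != len(labels_b):
        raise ValueError("label vectors differ in length")
    if weighting not in (None, "linear", "quadratic"):
        raise ValueError("weighting must be None, 'linear' or 'quadratic'")
    return float(
        cohen_kappa_score(labels_a, labels_b, labels=_CLASSES, weights=weighting)
    )


def compare_models(
    per_cow_metrics: dict[str, dict[str, float]],
    proposed: str,
    baselines: list[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired cow-level comparison of a proposed model against baselines.

    For each baseline, the per-cow metric deltas (proposed - baseline) are
    bootstrap-resampled at the cow level for a CI and a two-sided p-value,
    the p-values are Holm-Bonferroni adjusted across the m comparisons,
    and the effect size is Cohen's d on the paired deltas.
    """
    rng = np.random.default_rng(seed)
    rows = []
    raw_ps = []
    for base in baselines:
        cows = sorted(set(per_cow_metrics[proposed]) & set(per_cow_metrics[base]))
        if len(cows) < len(per_cow_metrics[proposed]) or len(cows) < len(per_cow_metrics[base]):
            raise ValueError(f"unpaired cows between {proposed!r} and {base!r}")
        deltas = np.array(
            [per_cow_metrics[proposed][c] - per_cow_metrics[base][c] for c in cows]
        )
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = rng.choice(deltas, size=len(deltas), replace=True).mean()
        # two-sided percentile bootstrap p-value for mean delta != 0
        p_low = float(np.mean(boots <= 0.0))
        p_high = float(np.mean(boots >= 0.0))
        p_raw = min(1.0, 2.0 * min(p_low, p_high, 0.5) + (1.0 / n_boot))
        sd = deltas.std(ddof=1) if len(deltas) > 1 else 0.0
        rows.append(
            {
                "comparison": f"{proposed} vs {base}",
                "delta_mean": float(deltas.mean()),
                "delta_lo": float(np.quantile(boots, 0.025)),
                "delta_hi": float(np.quantile(boots, 0.975)),
                "p_raw": p_raw,
                "cohens_d": float(deltas.mean() / sd) if sd > 0 else np.inf * np.sign(deltas.mean()) if deltas.mean() != 0 else 0.0,
                "n_cows": len(cows),
            }
        )
        raw_ps.append(p_raw)
    adj = multipletests(raw_ps, method="holm")[1] if raw_ps else []
    out = pd.DataFrame(rows)
    out["p_holm"] = adj
    return out


def run_ablation(
    arm: str,
    dataset: HerdDataset,
    seed: int = 0,
    full_result: dict | None = None,
    labeling_config=None,
    model_config=None,
    horizon: int = 0,
    stride: int = 2,
    split_fraction: float | None = None,
) -> dict:
    """Run one pre-specified ablation arm end to end.

    Labeling arms (no_vet / no_thi / no_vet_no_thi) re-derive the labels
    with the corresponding flag forced off; feature arms modify only the
    model inputs: no_harmonics disables harmonic retention in the
    band-pass, no_coherence zeroes the coherence channel, and
    no_circadian_filter feeds the raw (unfiltered) activity in place of
    the circadian reconstruction. Everything else, including seeds, is
    identical to the full arm. Deltas are reported against ``full_result``
    (computed here when not supplied).
    """
    from .models.sequences import make_sequences
    from .models.train import ModelConfig, predict, train_lstm
    from .pipeline import LabelingConfig, run_pipeline
    from .spectral import SpectralConfig

    if arm not in ABLATION_ARMS:
        raise ValueError(f"unknown ablation arm {arm!r}; choose from {ABLATION_ARMS}")
    labeling_config = labeling_config or LabelingConfig()
    model_config = model_config or ModelConfig(seed=seed)

    lc = labeling_config
    if arm == "no_vet":
        lc = replace(lc, use_vet=False)
    elif arm == "no_thi":
        lc = replace(lc, use_thi=False)
    elif arm == "no_vet_no_thi":
        lc = replace(lc, use_vet=False, use_thi=False)
    elif arm == "no_harmonics":
        lc = replace(lc, spectral=replace(lc.spectral, include_harmonics="never"))

    res = run_pipeline(dataset, lc)
    feats = res.model_features.copy()
    if arm == "no_coherence":
        feats["coherence"] = 0.0
    elif arm == "no_circadian_filter":
        feats["s_circ"] = feats["activity"]

    data = make_sequences(feats, res.hourly_labels, horizon=horizon, stride=stride)
    if split_fraction is not None:
        # time-quantile split for records shorter than a calendar year
        cut = np.quantile(data.anchors.astype("int64"), split_fraction)
        train_mask = data.anchors.astype("int64") <= cut
        test_mask = ~train_mask
    else:
        split = chronological_split(
            pd.DataFrame({"cow_id": data.cow_ids, "date": pd.DatetimeIndex(data.anchors).date})
        )
        train_mask, test_mask = split["train_mask"], split["test_mask"]
    train, test = data.subset(train_mask), data.subset(test_mask)
    model = train_lstm(train, model_config)
    pred = predict(model, test)
    report = compute_metrics(test.y, pred["labels"], pred["probabilities"])
    out = {
        "arm": arm,
        "f1_macro": report.f1_macro,
        "accuracy": report.accuracy,
        "roc_auc": report.roc_auc_ovr_macro,
        "pr_auc": report.pr_auc_macro,
        "n_test": report.n,
    }
    if arm != "full":
        if full_result is None:
            full_result = run_ablation(
                "full", dataset, seed=seed, labeling_config=labeling_config,
                model_config=model_config, horizon=horizon, stride=stride,
                split_fraction=split_fraction,
            )
        for key in ("f1_macro", "accuracy", "roc_auc", "pr_auc"):
            if out[key] is not None and full_result.get(key) is not None:
                out[f"delta_{key}"] = out[key] - full_result[key]
    return out


def power_simulation(
    class_mix: tuple[float, float, float] = (0.72, 0.21, 0.07),
    n_sims: int = 200,
    alpha: float = 0.05,
    delta_f1: float = 0.05,
    n_cows: int = 10,
    base_f1: float = 0.75,
    per_cow_sd: float = 0.05,
    seed: int = 0,
) -> dict:
    """Monte Carlo power of the paired LOCO comparison (indicative utility).

    The generative model is declared, not derived: each cow contributes a
    paired (baseline, improved) macro-F1 drawn from correlated Gaussians
    with the stated per-cow spread; the improved model is shifted by
    ``delta_f1``. The minority-class share of the mix inflates the per-cow
    spread (rarer positives make per-cow F1 noisier). Each simulation
    applies a paired t-test at ``alpha``; power is the rejection rate.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    minority = min(class_mix)
    sd = per_cow_sd * (1.0 + (0.07 / max(minority, 1e-6) - 1.0) * 0.1)
    rejections = 0
    for _ in range(n_sims):
        base = rng.normal(base_f1, sd, size=n_cows)
        improved = base + delta_f1 + rng.normal(0.0, sd * 0.5, size=n_cows)
        stat = stats.ttest_rel(improved, base, alternative="greater")
        if stat.pvalue < alpha:
            rejections += 1
    power = rejections / n_sims
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return {"power": power, "se": se, "n_sims": n_sims, "alpha": alpha, "delta_f1": delta_f1}
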