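"""Composite activity index.

The four hourly behavior budgets (eating, resting, rumination, other) are
condensed into one scalar activity level

    A_t = w1*eat_t + w2*rest_t + w3*ruminate_t + w4*other_t

where the inputs are z-scored with herd-level calibration statistics and
the weights are the first-principal-component loadings of the standardized
behaviors on a calibration subset (default: each cow's chronologically
first 14 days), sign-aligned and normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .synthetic import BEHAVIOR_COLUMNS

__all__ = ["ActivityWeights", "CalibrationError", "calibrate_weights", "compute_activity"]


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ActivityWeights:
    """PC1-derived behavior weights plus the z-transform statistics.

    In the default (positive-factor) mode all weights are nonnegative and
    sum to one. In contrast mode (``contrast=True``) the weights are a
    signed PC1 contrast with unit L1 norm: exactly compositional budgets
    (minutes summing to 60) force each principal axis to oppose at least
    one behavior to the others, so a signed contrast is the only
    projection that can carry the diurnal activity signal for such data.
    """

    w_eat: float
    w_rest: float
    w_ruminate: float
    w_other: float
    pc1_variance_fraction: float
    calibration_means: dict[str, float]
    calibration_sds: dict[str, float]
    contrast: bool = False

    @property
    def as_array(self) -> np.ndarray:
        return np.array([self.w_eat, self.w_rest, self.w_ruminate, self.w_other])

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "weights": {
                "eat": self.w_eat,
                "rest": self.w_rest,
                "ruminate": self.w_ruminate,
                "other": self.w_other,
            },
            "pc1_variance_fraction": self.pc1_variance_fraction,
            "calibration_means": self.calibration_means,
            "calibration_sds": self.calibration_sds,
            "contrast": self.contrast,
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ActivityWeights":
        payload = yaml.safe_load(Path(path).read_text())
        w = payload["weights"]
        return cls(
            w_eat=float(w["eat"]),
            w_rest=float(w["rest"]),
            w_ruminate=float(w["ruminate"]),
            w_other=float(w["other"]),
            pc1_variance_fraction=float(payload["pc1_variance_fraction"]),
            calibration_means={k: float(v) for k, v in payload["calibration_means"].items()},
            calibration_sds={k: float(v) for k, v in payload["calibration_sds"].items()},
            contrast=bool(payload.get("contrast", False)),
        )


def _calibration_subset(behavior: pd.DataFrame, calibration_days: int) -> pd.DataFrame:
    parts = []
    for _, grp in behavior.groupby("cow_id", sort=True):
        grp = grp.sort_values("timestamp")
        dates = grp["timestamp"].dt.normalize()
        keep = dates.isin(dates.drop_duplicates().iloc[:calibration_days])
        parts.append(grp[keep])
    return pd.concat(parts, ignore_index=True)


def calibrate_weights(
    behavior: pd.DataFrame,
    calibration_days: int = 14,
    min_variance_fraction: float | None = None,
    mode: str = "positive",
) -> ActivityWeights:
    """Fit PC1 weights on the calibration subset.

    Standardizes the four behaviors with pooled (herd-level) means/sds and
    extracts the first principal component of the correlation structure.

    In ``mode="positive"`` (default) the component is flipped so the
    majority of loadings are positive and the loadings are normalized to
    sum to one; mixed-sign loadings after the flip mean the behaviors do
    not share a single latent activity factor and raise
    :class:`CalibrationError`. Note that budgets summing to exactly 60
    minutes always trigger this error: the standardized behaviors then
    satisfy ``sum_i sd_i z_i = 0``, so every principal axis is orthogonal
    to a positive vector and must mix signs.

    In ``mode="contrast"`` the signed component is kept (flipped so the
    eating loading is positive) and normalized to unit L1 norm — the
    appropriate projection for exactly compositional budgets, where the
    activity factor necessarily appears as an active-vs-rest contrast.

    ``min_variance_fraction``, when given, rejects calibrations whose PC1
    explains less variance than the threshold (off by default).
    """
    if mode not in ("positive", "contrast"):
        raise ValueError("mode must be 'positive' or 'contrast'")
    subset = _calibration_subset(behavior, calibration_days)
    x = subset[BEHAVIOR_COLUMNS].to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise CalibrationError("need at least 2 calibration observations")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        bad = [c for c, s in zip(BEHAVIOR_COLUMNS, sds) if s <= 0]
        raise CalibrationError(f"zero variance in behavior column(s): {bad}")
    z = (x - means) / sds

    pca = PCA(n_components=1, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_[0]
    if mode == "positive":
        if np.sum(loadings > 0) < np.sum(loadings < 0):
            loadings = -loadings
        if np.any(loadings <= 0):
            raise CalibrationError(
                "no single latent activity factor: PC1 loadings are not all positive"
            )
        weights = loadings / loadings.sum()
    else:
        if loadings[0] < 0:
            loadings = -loadings
        weights = loadings / np.abs(loadings).sum()
    return ActivityWeights(
        w_eat=float(weights[0]),
        w_rest=float(weights[1]),
        w_ruminate=float(weights[2]),
        w_other=float(weights[3]),
        pc1_variance_fraction=_check_variance(
            float(pca.explained_variance_ratio_[0]), min_variance_fraction
        ),
        calibration_means=dict(zip(BEHAVIOR_COLUMNS, means.tolist())),
        calibration_sds=dict(zip(BEHAVIOR_COLUMNS, sds.tolist())),
        contrast=(mode == "contrast"),
    )


def _check_variance(fraction: float, minimum: float | None) -> float:
    if minimum is not None and fraction < minimum:
        raise CalibrationError(
            f"PC1 explains {fraction:.1%} of variance, below the required {minimum:.1%}"
        )
    return fraction


def _assert_gap_free(grp: pd.DataFrame, cow: str) -> None:
    ts = grp["timestamp"]
    deltas = ts.diff().iloc[1:]
    bad = deltas != pd.Timedelta(hours=1)
    if bad.any():
        starts = ts.shift()[1:][bad]
        missing = [
            f"{cow}: {a + pd.Timedelta(hours=1)} .. {b - pd.Timedelta(hours=1)}"
            for a, b in zip(starts, ts.iloc[1:][bad])
        ]
        raise ValueError("behavior series has gaps: " + "; ".join(missing[:10]))


def compute_activity(behavior: pd.DataFrame, weights: ActivityWeights) -> pd.DataFrame:
    """Hourly composite activity per cow.

    Applies the calibration z-transform (not per-window statistics) and the
    normalized PC1 weights. Returns columns ``cow_id, timestamp, activity``.
    Gaps in any cow's hourly grid raise an error naming the missing hours.
    """
    parts = []
    w = weights.as_array
    means = np.array([weights.calibration_means[c] for c in BEHAVIOR_COLUMNS])
    sds = np.array([weights.calibration_sds[c] for c in BEHAVIOR_COLUMNS])
    for cow, grp in behavior.groupby("cow_id", sort=True):
        grp = grp.sort_values("timestamp")
        _assert_gap_free(grp, str(cow))
        z = (grp[BEHAVIOR_COLUMNS].to_numpy(dtype=float) - means) / sds
        parts.append(
            pd.DataFrame(
                {"cow_id": cow, "timestamp": grp["timestamp"].to_numpy(), "activity": z @ w}
            )
        )
    if not parts:
        return pd.DataFrame(columns=["cow_id", "timestamp", "activity"])
    return pd.concat(parts, ignore_index=True)
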